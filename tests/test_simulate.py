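"""Synthetic-data generator: determinism, feasibility, planted structure."""

import numpy as np
import pandas as pd
import pytest

from cutrun_delta.genome import gene_body, promoter_window
from cutrun_delta.simulate import (
    SimulationConfig,
    assign_truth,
    simulate_annotation,
    simulate_cutrun,
    simulate_rnaseq,
    simulate_tf_peaks,
    write_dataset,
)

SMALL = dict(n_genes=40, chrom_sizes={"chr1": 1_000_000}, fragments_per_sample=40_000)


class TestAnnotation:
    def test_packing_and_gaps(self):
        ann = simulate_annotation(SimulationConfig(seed=0, **SMALL))
        bodies = sorted((gene_body(g).start, gene_body(g).end) for g in ann)
        assert len(bodies) == 40
        for (s1, e1), (s2, e2) in zip(bodies, bodies[1:]):
            assert s2 - e1 >= 1000  # intergenic gap
        for s, e in bodies:
            assert 2000 <= e - s <= 20000

    def test_determinism(self):
        a = simulate_annotation(SimulationConfig(seed=5, **SMALL))
        b = simulate_annotation(SimulationConfig(seed=5, **SMALL))
        assert [(g.gene_id, g.strand, g.tss, g.tes) for g in a] == [
            (g.gene_id, g.strand, g.tss, g.tes) for g in b
        ]

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="pack"):
            simulate_annotation(
                SimulationConfig(seed=0, n_genes=200, chrom_sizes={"chr1": 100_000})
            )


class TestTruth:
    def test_partition_and_planted_effects(self):
        cfg = SimulationConfig(seed=2, **SMALL)
        ann = simulate_annotation(cfg)
        truth = assign_truth(cfg, ann)
        assert len(truth) == 40
        assert set(truth["cluster"]) <= {"C1", "C2", "C3", "C4", "C5"}
        loss = -np.log2(cfg.knockout_loss_factor)
        assert (truth.loc[truth["cluster"] == "C1", "lfc_k4"] == loss).all()
        assert (truth.loc[truth["cluster"] == "C1", "lfc_k36"] == loss).all()
        assert (truth.loc[truth["cluster"] == "C2", "lfc_k36"] == 0).all()
        assert (truth.loc[truth["cluster"] == "C4", "lfc_k4"] > 0).all()
        # rna_down planted on every C1-C3 gene
        marked = truth["cluster"].isin(["C1", "C2", "C3"])
        assert (truth.loc[marked, "rna_lfc"] == cfg.rnaseq_lfc).all()


@pytest.fixture(scope="module")
def setup():
    cfg = SimulationConfig(seed=3, **SMALL)
    ann = simulate_annotation(cfg)
    truth = assign_truth(cfg, ann)
    return cfg, ann, truth


class TestCutrun:
    def test_determinism(self, setup):
        cfg, ann, truth = setup
        t1, s1 = simulate_cutrun(cfg, ann, truth, "H3K4me3")
        t2, s2 = simulate_cutrun(cfg, ann, truth, "H3K4me3")
        for sid in t1:
            assert t1[sid].fragments.equals(t2[sid].fragments)
            assert s1[sid].fragments.equals(s2[sid].fragments)

    def test_expected_sample_roster(self, setup):
        cfg, ann, truth = setup
        targets, spikes = simulate_cutrun(cfg, ann, truth, "H3K4me3")
        mark = [s for s in targets if s.startswith("H3K4me3")]
        assert len(mark) == 4  # 2 conditions x 2 replicates
        assert {"igg_control", "igg_knockout", "input_control", "input_knockout"} <= set(targets)
        for sid in mark:
            assert len(targets[sid]) == cfg.fragments_per_sample

    def test_planted_promoter_loss_ratio(self):
        """The planted/unaffected promoter-count ratio across conditions
        recovers the allocation-weight loss factor. The within-sample double
        ratio cancels both the fixed-depth renormalization and (at high
        enrichment) the uniform background."""
        cfg = SimulationConfig(seed=3, **SMALL, enrichment_factor=200.0)
        ann = simulate_annotation(cfg)
        truth = assign_truth(cfg, ann)
        targets, _ = simulate_cutrun(cfg, ann, truth, "H3K4me3")
        planted = truth.index[truth["lfc_k4"] < 0]
        unaffected = truth.index[truth["cluster"] == "C5"]

        def promoter_counts(frags, gene_ids):
            mids = (frags["start"] + frags["end"]) // 2
            total = 0
            for gid in gene_ids:
                w = promoter_window(ann.get(gid))
                total += int(((mids >= w.start) & (mids < w.end)).sum())
            return total

        ctrl = pd.concat([targets[f"H3K4me3_control_r{i}"].fragments for i in (1, 2)])
        ko = pd.concat([targets[f"H3K4me3_knockout_r{i}"].fragments for i in (1, 2)])
        rel_ctrl = promoter_counts(ctrl, planted) / promoter_counts(ctrl, unaffected)
        rel_ko = promoter_counts(ko, planted) / promoter_counts(ko, unaffected)
        assert rel_ctrl / rel_ko == pytest.approx(cfg.knockout_loss_factor, rel=0.2)

    def test_k36_signal_ramps_toward_tes(self, setup):
        """H3K36me3 density in the TES-proximal third of a body exceeds the
        TSS-proximal third."""
        cfg, ann, truth = setup
        targets, _ = simulate_cutrun(cfg, ann, truth, "H3K36me3")
        frags = targets["H3K36me3_control_r1"].fragments
        mids = ((frags["start"] + frags["end"]) // 2).to_numpy()
        tss_third = tes_third = 0
        for g in ann:
            body = gene_body(g)
            t = (mids - g.tss) / (g.tes - g.tss)  # 0 at TSS, 1 at TES
            inside = (mids >= body.start) & (mids < body.end)
            tss_third += int((inside & (t < 1 / 3)).sum())
            tes_third += int((inside & (t > 2 / 3)).sum())
        assert tes_third > 1.5 * tss_third

    def test_spikein_rises_when_target_signal_falls(self):
        """Constant per-cell spike-in: a global mark loss inflates the
        spike-in count of a fixed-depth knockout library (loss-only truth)."""
        cfg = SimulationConfig(seed=3, **SMALL, class_fractions={"C2": 0.5})
        ann = simulate_annotation(cfg)
        truth = assign_truth(cfg, ann)
        _, spikes = simulate_cutrun(cfg, ann, truth, "H3K4me3")
        n_ctrl = spikes["H3K4me3_control_r1"].n_fragments
        n_ko = spikes["H3K4me3_knockout_r1"].n_fragments
        assert n_ko > n_ctrl

    def test_igg_is_uniform_background(self, setup):
        cfg, ann, truth = setup
        targets, _ = simulate_cutrun(cfg, ann, truth, "H3K4me3")
        mids = targets["igg_control"].midpoints("chr1")
        # chi-square on 20 equal genome bins
        counts, _ = np.histogram(mids, bins=20, range=(0, 1_000_000))
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        from scipy import stats as ss
        assert ss.chi2.sf(chi2, df=19) > 1e-4


class TestRnaseq:
    def test_determinism_and_shape(self):
        cfg = SimulationConfig(seed=4, **SMALL)
        ann = simulate_annotation(cfg)
        truth = assign_truth(cfg, ann)
        t1, cond1 = simulate_rnaseq(cfg, truth)
        t2, _ = simulate_rnaseq(cfg, truth)
        assert t1.counts.equals(t2.counts)
        assert t1.counts.shape == (40, 9)
        assert set(cond1.values()) == {"ctrl", "sg2", "sg3"}

    def test_poisson_limit(self):
        """dispersion -> 0 with lfc 0: variance ~ mean across genes."""
        cfg = SimulationConfig(seed=6, **SMALL, rnaseq_dispersion=0.0,
                               class_fractions={}, rna_down_extra_fraction=0.0)
        ann = simulate_annotation(cfg)
        truth = assign_truth(cfg, ann)
        counts, cond = simulate_rnaseq(cfg, truth)
        # with no planted effects all nine samples share the per-gene mean;
        # scale out size factors and pool. For Poisson(s_j mu) counts the
        # normalized variance/mean ratio has expectation E[1/s] (~1.08 for
        # log-uniform s on [0.5, 2]).
        from cutrun_delta.differential import median_of_ratios_size_factors
        sf = median_of_ratios_size_factors(counts.counts)
        norm = counts.counts / sf
        ratio = (norm.var(axis=1) / norm.mean(axis=1)).mean()
        assert ratio == pytest.approx(1.08, rel=0.25)

    def test_planted_lfc_recovered_in_means(self):
        cfg = SimulationConfig(seed=7, **SMALL)
        ann = simulate_annotation(cfg)
        truth = assign_truth(cfg, ann)
        counts, cond = simulate_rnaseq(cfg, truth)
        from cutrun_delta.differential import median_of_ratios_size_factors
        sf = median_of_ratios_size_factors(counts.counts)
        norm = counts.counts / sf
        ctrl_cols = [s for s, c in cond.items() if c == "ctrl"]
        ko_cols = [s for s, c in cond.items() if c != "ctrl"]
        planted = truth.index[truth["rna_lfc"] != 0]
        ratio = (
            norm.loc[planted, ko_cols].mean(axis=1)
            / norm.loc[planted, ctrl_cols].mean(axis=1)
        ).mean()
        assert ratio == pytest.approx(2.0 ** cfg.rnaseq_lfc, rel=0.25)


class TestWriteDataset:
    def test_manifest_and_files(self, tmp_path):
        cfg = SimulationConfig(seed=1, n_genes=10, chrom_sizes={"chr1": 300_000},
                               fragments_per_sample=2_000)
        manifest = write_dataset(cfg, tmp_path)
        assert (tmp_path / "manifest.yaml").exists()
        assert (tmp_path / "genes.bed").exists()
        assert (tmp_path / "rnaseq_counts.tsv").exists()
        # every listed sample file exists
        for sid, files in manifest["samples"].items():
            for f in files.values():
                assert (tmp_path / f).exists()

    def test_tf_peaks_cover_bound_genes(self):
        cfg = SimulationConfig(seed=9, **SMALL)
        ann = simulate_annotation(cfg)
        truth = assign_truth(cfg, ann)
        peaks = simulate_tf_peaks(cfg, ann, truth)
        assert len(peaks) == int(truth["tf_bound"].sum())
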