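"""Synthetic CUT&RUN and RNA-seq data with planted ground truth.

The generator emulates the statistical structure the analysis assumes:

* a compact genome of non-overlapping genes (bodies 2-20 kb, >= 1 kb gaps);
* per-sample paired-end fragment sets: a uniform background plus an
  enriched fraction allocated to genes in proportion to per-gene weights.
  H3K4me3 fragments centre on the TSS (Normal, sigma 200 bp); H3K36me3
  fragments spread over the gene body with density rising linearly from the
  TSS to the TES. Knockout divides the weight of affected genes by the loss
  factor; IgG and input samples are background-only;
* spike-in fragments from an exogenous genome at a constant amount per cell,
  so the sequenced spike-in count scales inversely with the per-cell target
  signal and a global signal loss is visible only under spike-in
  normalization;
* an RNA-seq negative-binomial count matrix (3 replicates x control + two
  knockout guides) whose planted fold changes are linked to the planted
  mark losses.

Every draw flows from ``SimulationConfig.seed``; identical configs produce
identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .genome import GeneModel, GenomeAnnotation, gene_body
from .io_formats import CountTable, FragmentSet

MARKS = ("H3K4me3", "H3K36me3")
CONDITIONS = ("control", "knockout")

# stage tags mixed into the seed so each stage has an independent stream
_STAGE = {"annotation": 1, "truth": 2, "cutrun": 3, "rnaseq": 4, "tf": 5}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the experimental design being emulated: two CUT&RUN
    replicates per mark and condition with IgG/input controls and a yeast-
    like spike-in, three RNA-seq replicates for a control and two knockout
    guides, 8-fold mark enrichment over background, and a 4-fold knockout
    loss at affected genes.
    """

    seed: int = 0
    n_genes: int = 300
    chrom_sizes: dict[str, int] = field(default_factory=lambda: {"chr1": 5_000_000})
    spike_chrom_sizes: dict[str, int] = field(default_factory=lambda: {"spike_I": 500_000})
    replicates_cutrun: int = 2
    replicates_rnaseq: int = 3
    fragments_per_sample: int = 200_000
    spikein_fraction: dict[str, float] = field(
        default_factory=lambda: {"control": 0.05, "knockout": 0.05}
    )
    enrichment_factor: float = 8.0
    knockout_loss_factor: float = 4.0
    class_fractions: dict[str, float] = field(
        default_factory=lambda: {"C1": 0.05, "C2": 0.05, "C3": 0.05, "C4": 0.05}
    )
    fragment_length_mean: float = 180.0
    fragment_length_sd: float = 30.0
    promoter_sigma: float = 200.0
    k4_footprint: int = 1500
    rnaseq_dispersion: float = 0.1
    rnaseq_lfc: float = -2.0
    rna_down_extra_fraction: float = 0.02  # C5 genes downregulated without mark loss
    tf_bound_fraction_targets: float = 0.8
    tf_bound_fraction_background: float = 0.2

    def __post_init__(self) -> None:
        fracs = list(self.class_fractions.values()) + list(self.spikein_fraction.values())
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        if sum(self.class_fractions.values()) > 1:
            raise ValueError("class fractions sum to more than 1")
        if self.enrichment_factor <= 1 or self.knockout_loss_factor <= 1:
            raise ValueError("enrichment and loss factors must exceed 1")

    def rng(self, stage: str, extra: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STAGE[stage], extra])


def simulate_annotation(config: SimulationConfig) -> GenomeAnnotation:
    """Non-overlapping genes, random strand, bodies uniform in [2, 20] kb,
    at least 1 kb between neighbours."""
    rng = config.rng("annotation")
    chroms = list(config.chrom_sizes.items())
    total_len = sum(L for _, L in chroms)
    # apportion genes across chromosomes by length
    quotas = [int(round(config.n_genes * L / total_len)) for _, L in chroms]
    quotas[-1] = config.n_genes - sum(quotas[:-1])
    genes: list[GeneModel] = []
    idx = 0
    for (chrom, L), n in zip(chroms, quotas):
        if n <= 0:
            continue
        lengths = rng.integers(2000, 20001, size=n)
        min_gap = 1000
        slack = L - int(lengths.sum()) - min_gap * (n + 1)
        if slack < 0:
            raise ValueError(
                f"cannot pack {n} genes into {chrom} ({L} bp): "
                f"need {int(lengths.sum()) + min_gap * (n + 1)} bp"
            )
        extra = np.floor(rng.dirichlet(np.ones(n + 1)) * slack).astype(int)
        pos = min_gap + extra[0]
        for i in range(n):
            start = int(pos)
            end = start + int(lengths[i])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GeneModel.from_transcripts(f"gene_{idx:04d}", chrom, strand, [(start, end)])
            )
            idx += 1
            pos = end + min_gap + extra[i + 1]
    return GenomeAnnotation(genes, dict(config.chrom_sizes))


def assign_truth(config: SimulationConfig, annotation: GenomeAnnotation) -> pd.DataFrame:
    """Plant per-gene truth: cluster, mark log2FCs, RNA log2FC, TF binding.

    C1 genes lose both marks, C2 only H3K4me3, C3 only H3K36me3, C4 gains
    both, C5 is unchanged. RNA downregulation is planted on every C1-C3
    gene plus a small fraction of C5 genes (downregulation without a mark
    change, so the planted direct-target set is a strict subset of rna_down).
    """
    rng = config.rng("truth")
    ids = np.array(annotation.gene_ids)
    perm = rng.permutation(len(ids))
    n = len(ids)
    counts = {c: int(round(f * n)) for c, f in config.class_fractions.items()}
    truth = pd.DataFrame(
        index=pd.Index(ids, name="gene_id"),
        data={
            "cluster": "C5",
            "lfc_k4": 0.0,
            "lfc_k36": 0.0,
            "rna_lfc": 0.0,
            "tf_bound": False,
        },
    )
    loss = -np.log2(config.knockout_loss_factor)
    gain = np.log2(config.knockout_loss_factor)
    start = 0
    for cluster in ("C1", "C2", "C3", "C4"):
        take = ids[perm[start : start + counts.get(cluster, 0)]]
        start += counts.get(cluster, 0)
        truth.loc[take, "cluster"] = cluster
        if cluster in ("C1", "C2"):
            truth.loc[take, "lfc_k4"] = loss
        if cluster in ("C1", "C3"):
            truth.loc[take, "lfc_k36"] = loss
        if cluster == "C4":
            truth.loc[take, "lfc_k4"] = gain
            truth.loc[take, "lfc_k36"] = gain
    affected = truth["cluster"].isin(["C1", "C2", "C3"])
    truth.loc[affected, "rna_lfc"] = config.rnaseq_lfc
    c5_ids = truth.index[truth["cluster"] == "C5"].to_numpy()
    n_extra = int(round(config.rna_down_extra_fraction * n))
    extra = rng.choice(c5_ids, size=min(n_extra, len(c5_ids)), replace=False)
    truth.loc[extra, "rna_lfc"] = config.rnaseq_lfc
    p_bound = np.where(
        affected,
        config.tf_bound_fraction_targets,
        config.tf_bound_fraction_background,
    )
    truth["tf_bound"] = rng.random(n) < p_bound
    return truth


def _gene_weights(
    config: SimulationConfig,
    annotation: GenomeAnnotation,
    truth: pd.DataFrame,
    mark: str,
    condition: str,
) -> pd.Series:
    """Relative allocation weight per gene (background has weight 1 total)."""
    genome_length = annotation.genome_length
    lfc_col = "lfc_k4" if mark == "H3K4me3" else "lfc_k36"
    weights = {}
    for g in annotation:
        body = gene_body(g)
        if body.length < 2 * config.promoter_sigma:
            warnings.warn(f"{g.gene_id}: body shorter than 2 sigma, skipped")
            weights[g.gene_id] = 0.0
            continue
        footprint = config.k4_footprint if mark == "H3K4me3" else body.length
        w = config.enrichment_factor * footprint / genome_length
        if condition == "knockout":
            w *= 2.0 ** truth.loc[g.gene_id, lfc_col]
        weights[g.gene_id] = w
    return pd.Series(weights)


def _draw_fragments(
    rng: np.random.Generator,
    midpoints: np.ndarray,
    chroms: np.ndarray,
    config: SimulationConfig,
    chrom_sizes: Mapping[str, int],
) -> pd.DataFrame:
    lengths = np.clip(
        np.rint(rng.normal(config.fragment_length_mean, config.fragment_length_sd, midpoints.size)),
        50,
        500,
    ).astype(np.int64)
    starts = midpoints - lengths // 2
    ends = starts + lengths
    sizes = pd.Series(chrom_sizes)
    lims = sizes.loc[chroms].to_numpy()
    starts = np.clip(starts, 0, lims - 1)
    ends = np.clip(ends, starts + 1, lims)
    df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends})
    return df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


def _sample_positions_k4(rng, gene: GeneModel, n: int, sigma: float) -> np.ndarray:
    return np.rint(rng.normal(gene.tss, sigma, size=n)).astype(np.int64)


def _sample_positions_k36(rng, gene: GeneModel, n: int) -> np.ndarray:
    # density rises linearly from TSS (0) to TES: inverse-CDF is sqrt(U)
    t = np.sqrt(rng.random(n))
    return np.rint(gene.tss + t * (gene.tes - gene.tss)).astype(np.int64)


def _uniform_positions(rng, chrom_sizes: Mapping[str, int], n: int):
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    pick = rng.choice(len(chroms), size=n, p=sizes / sizes.sum())
    pos = (rng.random(n) * sizes[pick]).astype(np.int64)
    return np.array(chroms, dtype=object)[pick], pos


def simulate_cutrun(
    config: SimulationConfig,
    annotation: GenomeAnnotation,
    truth: pd.DataFrame,
    mark: str,
) -> tuple[dict[str, FragmentSet], dict[str, FragmentSet]]:
    """Simulate target and spike-in fragment sets for one mark.

    Returns (target_sets, spike_sets), keyed by sample id. Sample ids are
    ``{mark}_{condition}_r{i}`` for the mark samples and ``igg_{condition}``
    / ``input_{condition}`` for the background-only controls (controls are
    shared between marks in a real experiment; callers may reuse them).
    """
    if mark not in MARKS:
        raise ValueError(f"unknown mark {mark}")
    N = config.fragments_per_sample
    target_sets: dict[str, FragmentSet] = {}
    spike_sets: dict[str, FragmentSet] = {}
    w_ctrl = _gene_weights(config, annotation, truth, mark, "control")
    W_ctrl = 1.0 + w_ctrl.sum()
    genes = list(annotation)
    mark_tag = MARKS.index(mark)
    sample_idx = 0
    for condition in CONDITIONS:
        w = _gene_weights(config, annotation, truth, mark, condition)
        W = 1.0 + w.sum()
        probs = np.concatenate([[1.0 / W], w.to_numpy() / W])
        spike_frac = config.spikein_fraction[condition]
        # constant spike-in per cell: sequencing N target fragments samples
        # N / (per-cell signal) cell equivalents
        n_spike = int(round(spike_frac * N * W_ctrl / W))
        for rep in range(1, config.replicates_cutrun + 1):
            sid = f"{mark}_{condition}_r{rep}"
            rng = config.rng("cutrun", extra=mark_tag * 1000 + sample_idx)
            sample_idx += 1
            alloc = rng.multinomial(N, probs)
            chrom_list = [np.empty(0, dtype=object)]
            pos_list = [np.empty(0, dtype=np.int64)]
            bg_chroms, bg_pos = _uniform_positions(rng, config.chrom_sizes, alloc[0])
            chrom_list.append(bg_chroms)
            pos_list.append(bg_pos)
            for g, n_g in zip(genes, alloc[1:]):
                if n_g == 0:
                    continue
                if mark == "H3K4me3":
                    pos = _sample_positions_k4(rng, g, n_g, config.promoter_sigma)
                else:
                    pos = _sample_positions_k36(rng, g, n_g)
                pos = np.clip(pos, 0, annotation.chrom_length(g.chrom) - 1)
                chrom_list.append(np.full(n_g, g.chrom, dtype=object))
                pos_list.append(pos)
            frags = _draw_fragments(
                rng, np.concatenate(pos_list), np.concatenate(chrom_list), config, config.chrom_sizes
            )
            target_sets[sid] = FragmentSet(sid, "target", frags)
            sp_chroms, sp_pos = _uniform_positions(rng, config.spike_chrom_sizes, n_spike)
            spike = _draw_fragments(rng, sp_pos, sp_chroms, config, config.spike_chrom_sizes)
            spike_sets[sid] = FragmentSet(sid, "spikein", spike)
    # background-only controls, one IgG and one input per condition; seeding
    # is mark-independent so both marks see the same control fragments
    ctrl_samples = [(k, c) for k in ("igg", "input") for c in CONDITIONS]
    for k, (kind, condition) in enumerate(ctrl_samples):
        sid = f"{kind}_{condition}"
        rng = config.rng("cutrun", extra=9000 + k)
        chroms, pos = _uniform_positions(rng, config.chrom_sizes, N)
        frags = _draw_fragments(rng, pos, chroms, config, config.chrom_sizes)
        target_sets[sid] = FragmentSet(sid, "target", frags)
        n_spike = int(round(config.spikein_fraction[condition] * N))
        sp_chroms, sp_pos = _uniform_positions(rng, config.spike_chrom_sizes, n_spike)
        spike = _draw_fragments(rng, sp_pos, sp_chroms, config, config.spike_chrom_sizes)
        spike_sets[sid] = FragmentSet(sid, "spikein", spike)
    return target_sets, spike_sets


def simulate_rnaseq(
    config: SimulationConfig, truth: pd.DataFrame
) -> tuple[CountTable, dict[str, str]]:
    """NB gene counts for control plus two knockout guides (shared planted lfc).

    counts ~ NB(mean = s_j * mu_g * 2^(lfc_g * I[knockout]), dispersion phi);
    per-sample size factors s_j are log-uniform in [0.5, 2]. Returns the raw
    CountTable (library sizes = column totals) and the sample -> condition map.
    """
    rng = config.rng("rnaseq")
    conditions = ["ctrl", "sg2", "sg3"]
    samples = [f"{c}_r{i}" for c in conditions for i in range(1, config.replicates_rnaseq + 1)]
    condition_map = {s: s.rsplit("_", 1)[0] for s in samples}
    genes = truth.index.to_numpy()
    mu = 2.0 ** rng.uniform(3, 10, size=len(genes))
    s_j = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=len(samples)))
    lfc = truth["rna_lfc"].to_numpy()
    phi = config.rnaseq_dispersion
    mat = np.zeros((len(genes), len(samples)), dtype=np.int64)
    for j, sample in enumerate(samples):
        is_ko = condition_map[sample] != "ctrl"
        mean = s_j[j] * mu * (2.0 ** (lfc * is_ko))
        if phi < 1e-12:
            mat[:, j] = rng.poisson(mean)
        else:
            shape = 1.0 / phi
            lam = rng.gamma(shape, mean / shape)
            mat[:, j] = rng.poisson(lam)
    counts = pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"), columns=samples)
    return CountTable(counts), condition_map


def simulate_tf_peaks(
    config: SimulationConfig, annotation: GenomeAnnotation, truth: pd.DataFrame
) -> pd.DataFrame:
    """TF ChIP peaks: a 400-bp peak near the TSS of every tf_bound gene."""
    rng = config.rng("tf")
    rows = []
    for g in annotation:
        if not truth.loc[g.gene_id, "tf_bound"]:
            continue
        offset = int(rng.integers(-1000, 501))
        center = g.tss + offset
        L = annotation.chrom_length(g.chrom)
        start = int(np.clip(center - 200, 0, L - 1))
        end = int(np.clip(center + 200, start + 1, L))
        rows.append((g.chrom, start, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def write_dataset(
    config: SimulationConfig,
    outdir: str | Path,
    marks: tuple[str, ...] = MARKS,
) -> dict:
    """Simulate everything and write it under ``outdir`` with a manifest."""
    from .genome import write_chrom_sizes, write_gene_bed
    from .io_formats import write_counts, write_fragments_bedpe

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation = simulate_annotation(config)
    truth = assign_truth(config, annotation)
    manifest: dict = {"seed": config.seed, "samples": {}, "files": {}}
    write_gene_bed(annotation, outdir / "genes.bed")
    write_chrom_sizes(annotation.chrom_sizes, outdir / "chrom_sizes.tsv")
    write_chrom_sizes(config.spike_chrom_sizes, outdir / "spike_chrom_sizes.tsv")
    truth.to_csv(outdir / "truth.tsv", sep="\t")
    manifest["files"].update(
        genes="genes.bed", chrom_sizes="chrom_sizes.tsv", truth="truth.tsv"
    )
    for mark in marks:
        targets, spikes = simulate_cutrun(config, annotation, truth, mark)
        for sid, fs in targets.items():
            path = outdir / f"{sid}.target.bedpe"
            write_fragments_bedpe(fs, path)
            manifest["samples"].setdefault(sid, {})["target"] = path.name
        for sid, fs in spikes.items():
            path = outdir / f"{sid}.spikein.bedpe"
            write_fragments_bedpe(fs, path)
            manifest["samples"].setdefault(sid, {})["spikein"] = path.name
    rna, condition_map = simulate_rnaseq(config, truth)
    write_counts(rna, outdir / "rnaseq_counts.tsv")
    manifest["files"]["rnaseq_counts"] = "rnaseq_counts.tsv"
    manifest["rnaseq_conditions"] = condition_map
    tf = simulate_tf_peaks(config, annotation, truth)
    tf.to_csv(outdir / "tf_peaks.bed", sep="\t", header=False, index=False)
    manifest["files"]["tf_peaks"] = "tf_peaks.bed"
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
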