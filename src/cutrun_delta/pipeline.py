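"""End-to-end orchestration: simulate -> peaks -> counts -> tests -> clusters.

``run_all`` runs the whole differential CUT&RUN + RNA-seq integration on a
simulated dataset and returns every intermediate product. The H3K4me3 arm
follows the promoter/peak route with spike-in library sizes; the H3K36me3
arm quantifies gene bodies and derives library sizes from binomially
enriched gene bodies (the low-spike-in fallback). RNA-seq is tested per
knockout guide with median-of-ratios size factors and the both-guides DEG
rule. All randomness flows from the config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import differential as diff
from . import integrate, peaks, quantify, simulate
from .genome import GenomeAnnotation
from .io_formats import CountTable, FragmentSet, deduplicate

logger = logging.getLogger("cutrun_delta")


@dataclass
class PipelineResult:
    annotation: GenomeAnnotation
    truth: pd.DataFrame
    merged_peaks: pd.DataFrame
    k4_diff: pd.DataFrame
    k36_diff: pd.DataFrame
    dec_k4: set
    inc_k4: set
    dec_k36: set
    inc_k36: set
    rna: dict
    rna_down: set
    rna_up: set
    cluster_table: pd.DataFrame
    direct: set
    tf_targets: set
    overlaps: dict
    report: dict
    extras: dict = field(default_factory=dict)


def differential_mark_k4(
    target_sets: dict[str, FragmentSet],
    spike_sets: dict[str, FragmentSet],
    annotation: GenomeAnnotation,
    mark_samples: list[str],
    conditions: dict[str, str],
    blacklist: pd.DataFrame | None = None,
    pcut: float = peaks.PCUT,
) -> tuple[pd.DataFrame, pd.DataFrame, diff.NormalizationSpec]:
    """Promoter-mark arm: peaks vs IgG and input, merge, count, spike-in test."""
    chrom_sizes = annotation.chrom_sizes
    per_sample = []
    for sid in mark_samples:
        cond = conditions[sid]
        vs_igg = peaks.call_peaks(target_sets[sid], target_sets[f"igg_{cond}"],
                                  chrom_sizes, pcut=pcut)
        vs_input = peaks.call_peaks(target_sets[sid], target_sets[f"input_{cond}"],
                                    chrom_sizes, pcut=pcut)
        both = peaks.intersect_peak_sets(vs_igg, vs_input)
        both = peaks.filter_blacklist(both, blacklist)
        logger.info("%s: %d peaks vs IgG, %d vs input, %d retained",
                    sid, len(vs_igg), len(vs_input), len(both))
        per_sample.append(both)
    merged = peaks.merge_peaks_across_samples(per_sample)
    table = quantify.count_table([target_sets[s] for s in mark_samples], merged)
    spike_counts = {s: spike_sets[s].n_fragments for s in mark_samples}
    norm = diff.spikein_library_sizes(spike_counts)
    group_a = [s for s in mark_samples if conditions[s] == "control"]
    group_b = [s for s in mark_samples if conditions[s] == "knockout"]
    result = diff.exact_count_test(table, group_a, group_b, norm)
    return result, merged, norm


def differential_mark_k36(
    target_sets: dict[str, FragmentSet],
    annotation: GenomeAnnotation,
    mark_samples: list[str],
    conditions: dict[str, str],
    fdr_cut: float = 0.05,
) -> tuple[pd.DataFrame, diff.NormalizationSpec, list[str]]:
    """Body-mark arm: gene-body counts, binomial-enrichment library sizes."""
    bodies = annotation.gene_bodies()
    controls = [s for s in target_sets if s.startswith(("igg_", "input_"))]
    all_samples = mark_samples + controls
    table = quantify.count_table(
        [target_sets[s] for s in all_samples],
        bodies,
        library_sizes={s: target_sets[s].n_fragments for s in all_samples},
    )
    norm, common = diff.binomial_enrichment_library_sizes(
        table, mark_samples, controls, fdr_cut=fdr_cut
    )
    logger.info("binomial enrichment: %d common significant gene bodies", len(common))
    group_a = [s for s in mark_samples if conditions[s] == "control"]
    group_b = [s for s in mark_samples if conditions[s] == "knockout"]
    mark_table = CountTable(table.counts[mark_samples], norm.library_sizes)
    result = diff.exact_count_test(mark_table, group_a, group_b, norm)
    return result, norm, common


def run_all(
    config: simulate.SimulationConfig,
    fdr_cut: float = 0.05,
    fc_cut_marks: float = 1.5,
    fc_cut_rna_degs: float = 2.0,
    fc_cut_rna_down: float = 1.5,
    pcut: float = peaks.PCUT,
    blacklist: pd.DataFrame | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Simulate a full study and run the integrated differential analysis.

    ``fc_cut_rna_degs`` is the DEG definition (FC >= 2 in both guides);
    ``fc_cut_rna_down`` is the looser downregulation rule feeding the
    direct-target intersection (FC >= 1.5 in both guides).
    """
    annotation = simulate.simulate_annotation(config)
    truth = simulate.assign_truth(config, annotation)
    logger.info("simulated %d genes on %d bp", len(annotation), annotation.genome_length)

    results_extra: dict = {}
    dec, inc, diffs, norms = {}, {}, {}, {}
    merged_peaks = pd.DataFrame()
    for mark in simulate.MARKS:
        targets, spikes = simulate.simulate_cutrun(config, annotation, truth, mark)
        targets = {sid: deduplicate(fs) for sid, fs in targets.items()}
        spikes = {sid: deduplicate(fs) for sid, fs in spikes.items()}
        mark_samples = sorted(s for s in targets if s.startswith(mark))
        conditions = {s: ("knockout" if "_knockout_" in s else "control") for s in mark_samples}
        if mark == "H3K4me3":
            res, merged_peaks, norm = differential_mark_k4(
                targets, spikes, annotation, mark_samples, conditions,
                blacklist=blacklist, pcut=pcut,
            )
            d, i = diff.call_differential_genes(
                res, merged_peaks, annotation, mode="promoter",
                fdr_cut=fdr_cut, fc_cut=fc_cut_marks,
            )
        else:
            res, norm, common = differential_mark_k36(
                targets, annotation, mark_samples, conditions, fdr_cut=fdr_cut
            )
            results_extra["k36_common_bodies"] = common
            d, i = diff.call_differential_genes(
                res, None, annotation, mode="body",
                fdr_cut=fdr_cut, fc_cut=fc_cut_marks,
            )
        diffs[mark], norms[mark], dec[mark], inc[mark] = res, norm, d, i
        logger.info("%s: %d decreased, %d increased genes", mark, len(d), len(i))

    rna_table, condition_map = simulate.simulate_rnaseq(config, truth)
    rna = diff.rnaseq_de(rna_table, condition_map, control="ctrl",
                         knockouts=["sg2", "sg3"], fdr_cut=fdr_cut,
                         fc_cut=fc_cut_rna_degs)
    rna_loose = diff.rnaseq_de(rna_table, condition_map, control="ctrl",
                               knockouts=["sg2", "sg3"], fdr_cut=fdr_cut,
                               fc_cut=fc_cut_rna_down)
    rna_down, rna_up = rna_loose["deg_down"], rna_loose["deg_up"]
    logger.info("RNA-seq: %d down / %d up DEGs (FC>=%.1f both guides)",
                len(rna["deg_down"]), len(rna["deg_up"]), fc_cut_rna_degs)

    universe = list(annotation.gene_ids)
    clusters = integrate.classify_genes(
        dec["H3K4me3"], dec["H3K36me3"], inc["H3K4me3"], inc["H3K36me3"], universe
    )
    rna_universe = set(rna_loose["filtered"].feature_ids)
    overlap_universe = set(universe) & rna_universe
    direct = integrate.direct_targets(rna_down, dec["H3K4me3"], dec["H3K36me3"])
    overlaps = {
        "rna_down_vs_dec_k4": integrate.fisher_overlap(
            rna_down & overlap_universe, dec["H3K4me3"] & overlap_universe, overlap_universe
        ),
        "rna_down_vs_dec_k36": integrate.fisher_overlap(
            rna_down & overlap_universe, dec["H3K36me3"] & overlap_universe, overlap_universe
        ),
    }
    tf_peaks = simulate.simulate_tf_peaks(config, annotation, truth)
    tf_targets = integrate.annotate_tf_targets(tf_peaks, annotation)
    cluster_sizes = clusters["cluster"].value_counts().to_dict()
    report = integrate.summary_report(
        cluster_sizes, direct_target_ids=direct, tf_target_ids=tf_targets,
        overlaps=overlaps,
    )
    result = PipelineResult(
        annotation=annotation, truth=truth, merged_peaks=merged_peaks,
        k4_diff=diffs["H3K4me3"], k36_diff=diffs["H3K36me3"],
        dec_k4=dec["H3K4me3"], inc_k4=inc["H3K4me3"],
        dec_k36=dec["H3K36me3"], inc_k36=inc["H3K36me3"],
        rna=rna, rna_down=rna_down, rna_up=rna_up,
        cluster_table=clusters, direct=direct, tf_targets=tf_targets,
        overlaps=overlaps, report=report, extras=results_extra,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.merged_peaks.to_csv(outdir / "merged_peaks.tsv", sep="\t", index=False)
    diff.write_diff(result.k4_diff, outdir / "diff_h3k4me3.tsv")
    diff.write_diff(result.k36_diff, outdir / "diff_h3k36me3.tsv")
    result.cluster_table.to_csv(outdir / "clusters.tsv", sep="\t")
    pd.Series(sorted(result.direct)).to_csv(
        outdir / "direct_targets.txt", index=False, header=False
    )
    integrate.write_report(result.report, outdir / "report.json")
    integrate.report_to_tsv(result.report, outdir / "report.tsv")


def recovery_stats(result: PipelineResult) -> dict:
    """Planted-vs-recovered cluster agreement of a pipeline run."""
    truth = result.truth
    called = result.cluster_table["cluster"]
    stats: dict = {}
    for c in integrate.CLUSTERS:
        planted = truth.index[truth["cluster"] == c]
        if len(planted) == 0:
            continue
        stats[c] = {
            "n_planted": int(len(planted)),
            "n_recovered": int((called.loc[planted] == c).sum()),
        }
        stats[c]["recovery"] = stats[c]["n_recovered"] / stats[c]["n_planted"]
    planted_123 = truth.index[truth["cluster"].isin(["C1", "C2", "C3"])]
    stats["C1_C3"] = {
        "n_planted": int(len(planted_123)),
        "n_recovered": int((called.loc[planted_123] == truth.loc[planted_123, "cluster"]).sum()),
    }
    stats["C1_C3"]["recovery"] = (
        stats["C1_C3"]["n_recovered"] / stats["C1_C3"]["n_planted"]
        if len(planted_123)
        else float("nan")
    )
    return stats
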