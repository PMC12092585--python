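"""Synthesis layer: C1-C5 gene classification, direct targets, overlaps.

Genes are partitioned by the direction of change of the two marks upon
knockout: C1 both marks decreased, C2 H3K4me3 only, C3 H3K36me3 only,
C4 increased in either mark (and decreased in neither), C5 unchanged.
A gene decreased in one mark and increased in the other is assigned by the
decrease (C2/C3): the decreased clusters drive every downstream claim, so
"decreased" takes precedence over "increased".

Direct targets are transcriptionally downregulated genes that also lose at
least one mark: rna_down INTERSECT (dec_k4 UNION dec_k36).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeAnnotation, overlaps_any

CLUSTERS = ("C1", "C2", "C3", "C4", "C5")


def classify_genes(
    dec_k4: set[str],
    dec_k36: set[str],
    inc_k4: set[str],
    inc_k36: set[str],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Assign every gene in the universe to exactly one of C1..C5.

    Returns a frame indexed by gene_id with boolean flag columns and a
    ``cluster`` column.
    """
    universe = list(universe)
    uni = set(universe)
    for name, s in [("dec_k4", dec_k4), ("dec_k36", dec_k36),
                    ("inc_k4", inc_k4), ("inc_k36", inc_k36)]:
        extra = s - uni
        if extra:
            raise ValueError(f"{name} contains genes outside the universe: {sorted(extra)[:5]}")
    df = pd.DataFrame(index=pd.Index(universe, name="gene_id"))
    df["dec_k4"] = df.index.isin(dec_k4)
    df["dec_k36"] = df.index.isin(dec_k36)
    df["inc_k4"] = df.index.isin(inc_k4)
    df["inc_k36"] = df.index.isin(inc_k36)
    cluster = np.full(len(df), "C5", dtype=object)
    inc_any = df["inc_k4"] | df["inc_k36"]
    cluster[inc_any.to_numpy()] = "C4"
    cluster[(~df["dec_k4"] & df["dec_k36"]).to_numpy()] = "C3"
    cluster[(df["dec_k4"] & ~df["dec_k36"]).to_numpy()] = "C2"
    cluster[(df["dec_k4"] & df["dec_k36"]).to_numpy()] = "C1"
    df["cluster"] = cluster
    return df


def direct_targets(
    rna_down: set[str], dec_k4: set[str], dec_k36: set[str]
) -> set[str]:
    """Downregulated genes losing H3K4me3 and/or H3K36me3."""
    return rna_down & (dec_k4 | dec_k36)


@dataclass(frozen=True)
class OverlapStats:
    n_a: int
    n_b: int
    n_universe: int
    n_intersection: int
    expected: float
    fold_enrichment: float
    pvalue: float


def fisher_overlap(A: set[str], B: set[str], universe: set[str]) -> OverlapStats:
    """Two-sided Fisher's exact test of the overlap of two gene sets."""
    if not A <= universe or not B <= universe:
        raise ValueError("A and B must be subsets of the universe")
    M = len(universe)
    inter = len(A & B)
    a_only = len(A) - inter
    b_only = len(B) - inter
    rest = M - len(A | B)
    _, p = stats.fisher_exact([[inter, a_only], [b_only, rest]], alternative="two-sided")
    expected = len(A) * len(B) / M if M else 0.0
    fold = inter / expected if expected > 0 else np.nan
    return OverlapStats(len(A), len(B), M, inter, expected, fold, float(p))


def annotate_tf_targets(peaks: pd.DataFrame, annotation: GenomeAnnotation) -> set[str]:
    """Genes whose -5 kb/+1 kb TSS window overlaps any TF peak."""
    if peaks is None or len(peaks) == 0:
        return set()
    windows = annotation.target_windows()
    hit = overlaps_any(windows, peaks)
    return set(windows.loc[hit, "gene_id"])


def round_percent(x: float) -> float:
    """Percentage rounding used in the report: one decimal, trailing .0 kept
    as an integer-valued float (printed without the decimal)."""
    return float(np.round(x, 1))


def format_percent(x: float) -> str:
    r = round_percent(x)
    return f"{r:.0f}%" if float(r).is_integer() else f"{r:.1f}%"


def fraction_pct(num: int, den: int) -> float:
    if den == 0:
        return float("nan")
    return round_percent(100.0 * num / den)


def summary_report(
    cluster_sizes: Mapping[str, int],
    direct_target_ids: set[str] | None = None,
    tf_target_ids: set[str] | None = None,
    overlaps: Mapping[str, OverlapStats] | None = None,
) -> dict:
    """Counts-and-percentages summary of the integrated analysis.

    Percentages of cluster sizes are over the full gene universe (the sum of
    the cluster sizes, since C1..C5 partition it). Decreased-H3K4me3 genes
    are C1+C2; decreased-H3K36me3 genes are C1+C3.
    """
    sizes = {c: int(cluster_sizes.get(c, 0)) for c in CLUSTERS}
    universe = sum(sizes.values())
    report: dict = {
        "universe_size": universe,
        "clusters": {
            c: {
                "n": sizes[c],
                "pct": fraction_pct(sizes[c], universe),
                "pct_str": format_percent(100.0 * sizes[c] / universe) if universe else "0%",
            }
            for c in CLUSTERS
        },
    }
    dec_k4 = sizes["C1"] + sizes["C2"]
    dec_k36 = sizes["C1"] + sizes["C3"]
    report["decreased_h3k4me3"] = {
        "n": dec_k4,
        "pct": fraction_pct(dec_k4, universe),
    }
    report["decreased_h3k36me3"] = {
        "n": dec_k36,
        "pct": fraction_pct(dec_k36, universe),
    }
    if direct_target_ids is not None:
        report["direct_targets"] = {"n": len(direct_target_ids)}
        if tf_target_ids is not None:
            bound = len(direct_target_ids & tf_target_ids)
            report["direct_targets"]["tf_bound_n"] = bound
            report["direct_targets"]["tf_bound_pct"] = fraction_pct(
                bound, len(direct_target_ids)
            )
    if overlaps:
        report["overlaps"] = {
            name: asdict(ov) for name, ov in overlaps.items()
        }
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
        fh.write("\n")


def report_to_tsv(report: dict, path) -> None:
    rows = []
    for c, d in report["clusters"].items():
        rows.append((f"cluster_{c}_n", d["n"]))
        rows.append((f"cluster_{c}_pct", d["pct"]))
    for key in ("decreased_h3k4me3", "decreased_h3k36me3"):
        rows.append((f"{key}_n", report[key]["n"]))
        rows.append((f"{key}_pct", report[key]["pct"]))
    if "direct_targets" in report:
        for k, v in report["direct_targets"].items():
            rows.append((f"direct_targets_{k}", v))
    pd.DataFrame(rows, columns=["metric", "value"]).to_csv(path, sep="\t", index=False)
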