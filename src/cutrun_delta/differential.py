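"""Exact conditional count tests with pluggable library sizes.

The differential engine is a conditional exact test on summed group counts.
For a feature with group sums (y_A, y_B) and summed library sizes
(L_A, L_B), the null distribution of y_A given n = y_A + y_B is
Beta-Binomial(n, pi0, rho) with pi0 = L_A / (L_A + L_B); with no biological
overdispersion (rho = 0) this is the classic conditional binomial test. The
two-sided p-value sums every outcome whose likelihood does not exceed the
observed one (minimum-likelihood rule, ties included).

Overdispersion is estimated once, pooled over features, from within-group
replicate pairs by method of moments on conditional proportions, then
rescaled to the group-sum level (summing m i.i.d. gamma-Poisson counts
scales the Beta-Binomial precision a+b by m).

Library sizes come from one of three front-ends mirroring the analysis
design: spike-in fragment counts, fragment totals over binomially enriched
gene bodies, or median-of-ratios size factors for RNA-seq.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GenomeAnnotation, overlaps_any
from .io_formats import CountTable

DIFF_COLUMNS = ["feature_id", "log2fc", "pvalue", "fdr", "mean_norm"]
PSEUDOCOUNT = 0.5
_TIE_REL_TOL = 1e-8


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class NormalizationSpec:
    """A resolved normalization: mode label plus per-sample library sizes."""

    mode: str  # spikein | enriched_regions | total | size_factors
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        self.library_sizes = pd.Series(self.library_sizes, dtype=float)
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")


def spikein_library_sizes(spike_counts: Mapping[str, int]) -> NormalizationSpec:
    """Library sizes = deduplicated spike-in fragment counts per sample."""
    sizes = pd.Series(spike_counts, dtype=float)
    if (sizes <= 0).any():
        bad = list(sizes.index[sizes <= 0])
        raise ValueError(
            f"zero spike-in fragments for {bad}; spike-in normalization is "
            "unusable — use the enriched-regions (binomial) mode instead"
        )
    return NormalizationSpec("spikein", sizes)


def binomial_enrichment_library_sizes(
    genebody_counts: CountTable,
    mark_samples: Sequence[str],
    control_samples: Sequence[str],
    fdr_cut: float = 0.05,
) -> tuple[NormalizationSpec, list[str]]:
    """Library sizes from gene bodies enriched over both controls.

    Per mark sample s and control c, gene g is tested with an upper-tail
    binomial: p0 = (k_gc + 0.5) / (N_c + 0.5), p = P(Bin(N_s, p0) >= k_gs),
    BH-adjusted across genes. N_s / N_c are the samples' total (genome-wide)
    fragment counts — ``genebody_counts.library_sizes`` — so the test asks
    whether the mark concentrates a larger share of its library in the body
    than the control does. A gene is significant in s iff FDR <= cut against
    BOTH controls; the common set intersects all mark samples and each
    sample's library size is its fragment total over that set.
    """
    counts = genebody_counts.counts
    totals = genebody_counts.library_sizes.astype(float)
    sig_per_sample: dict[str, set[str]] = {}
    for s in mark_samples:
        sig_sets = []
        for c in control_samples:
            p0 = (counts[c].to_numpy() + PSEUDOCOUNT) / (totals[c] + PSEUDOCOUNT)
            p = stats.binom.sf(counts[s].to_numpy() - 1, int(round(totals[s])), p0)
            fdr = bh_fdr(p)
            sig_sets.append(set(counts.index[fdr <= fdr_cut]))
        sig_per_sample[s] = set.intersection(*sig_sets)
    common = sorted(set.intersection(*sig_per_sample.values()))
    if not common:
        diag = {s: len(v) for s, v in sig_per_sample.items()}
        raise ValueError(
            f"no gene body is significantly enriched in every sample "
            f"(per-sample significant counts: {diag})"
        )
    sizes = counts.loc[common, list(mark_samples)].sum(axis=0).astype(float)
    return NormalizationSpec("enriched_regions", sizes), common


def estimate_overdispersion(
    counts: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    library_sizes: pd.Series,
) -> float:
    """Pooled method-of-moments rho from within-group replicate pairs.

    For a replicate pair (a, b) with sizes (L_a, L_b) and per-feature totals
    n = k_a + k_b, E[(k_a - n*pi)^2] = n*pi*(1-pi)*(1 + (n-1)*rho) under the
    Beta-Binomial model; rho pools the moment equation over all features and
    pairs. Returns the PAIR-level rho, floored at 0.
    """
    num = 0.0
    den = 0.0
    n_pairs = 0
    for members in groups.values():
        for a, b in combinations(members, 2):
            n_pairs += 1
            la, lb = library_sizes[a], library_sizes[b]
            pi = la / (la + lb)
            ka = counts[a].to_numpy(dtype=float)
            n = ka + counts[b].to_numpy(dtype=float)
            mask = n > 1
            ka, n = ka[mask], n[mask]
            base = n * pi * (1 - pi)
            num += float(((ka - n * pi) ** 2 - base).sum())
            den += float((base * (n - 1)).sum())
    if n_pairs == 0:
        warnings.warn("single replicate per group: overdispersion set to 0")
        return 0.0
    if den <= 0:
        return 0.0
    return float(np.clip(num / den, 0.0, 0.95))


def _sum_rho(rho_pair: float, m_a: int, m_b: int) -> float:
    """Rescale a pair-level rho to the rho of m_a + m_b summed counts."""
    if rho_pair <= 0:
        return 0.0
    a_tot_pair = (1.0 - rho_pair) / rho_pair  # a+b of the pair model
    a_tot = a_tot_pair * (m_a + m_b) / 2.0
    return 1.0 / (a_tot + 1.0)


def _two_sided_exact_p(y_a: int, n: int, pi0: float, rho: float) -> float:
    if n == 0:
        return 1.0
    j = np.arange(n + 1)
    if rho <= 0:
        pmf = stats.binom.pmf(j, n, pi0)
    else:
        a = pi0 * (1.0 - rho) / rho
        b = (1.0 - pi0) * (1.0 - rho) / rho
        pmf = stats.betabinom.pmf(j, n, a, b)
    obs = pmf[y_a]
    include = pmf <= obs * (1.0 + _TIE_REL_TOL)
    if include.all():
        return 1.0
    return min(float(pmf[include].sum()), 1.0)


def exact_count_test(
    table: CountTable,
    group_a: Sequence[str],
    group_b: Sequence[str],
    norm: NormalizationSpec | None = None,
    rho: float | None = None,
) -> pd.DataFrame:
    """Two-sided exact conditional test, group B (knockout) vs group A (control).

    Returns a frame with feature_id, log2fc (B minus A on normalized scale),
    pvalue, BH fdr, and mean_norm (mean library-size-normalized count scaled
    to the mean library size).
    """
    counts = table.counts
    sizes = (norm.library_sizes if norm is not None else table.library_sizes).astype(float)
    missing = [s for s in list(group_a) + list(group_b) if s not in sizes.index]
    if missing:
        raise ValueError(f"no library size for samples {missing}")
    if rho is None:
        rho_pair = estimate_overdispersion(
            counts, {"A": group_a, "B": group_b}, sizes
        )
        rho_use = _sum_rho(rho_pair, len(group_a), len(group_b))
    else:
        rho_use = float(rho)
    y_a = counts[list(group_a)].sum(axis=1).to_numpy(dtype=np.int64)
    y_b = counts[list(group_b)].sum(axis=1).to_numpy(dtype=np.int64)
    L_a = float(sizes[list(group_a)].sum())
    L_b = float(sizes[list(group_b)].sum())
    pi0 = L_a / (L_a + L_b)
    pvals = np.array(
        [_two_sided_exact_p(int(a), int(a + b), pi0, rho_use) for a, b in zip(y_a, y_b)]
    )
    log2fc = np.log2((y_b + PSEUDOCOUNT) / L_b) - np.log2((y_a + PSEUDOCOUNT) / L_a)
    log2fc[(y_a + y_b) == 0] = 0.0
    all_samples = list(group_a) + list(group_b)
    norm_counts = counts[all_samples] / sizes[all_samples]
    mean_norm = norm_counts.mean(axis=1).to_numpy() * sizes[all_samples].mean()
    return pd.DataFrame(
        {
            "feature_id": counts.index.astype(str),
            "log2fc": log2fc,
            "pvalue": pvals,
            "fdr": bh_fdr(pvals),
            "mean_norm": mean_norm,
        }
    ).reset_index(drop=True)


def call_differential_genes(
    diff: pd.DataFrame,
    features: pd.DataFrame | None,
    annotation: GenomeAnnotation,
    mode: str = "promoter",
    fdr_cut: float = 0.05,
    fc_cut: float = 1.5,
) -> tuple[set[str], set[str]]:
    """Map significant differential features to (decreased, increased) genes.

    ``mode='promoter'``: features are peak intervals (frame with feature_id/
    chrom/start/end); a gene is affected when a significant peak overlaps its
    promoter window (>= 1 bp). ``mode='body'``: feature ids ARE gene ids.
    """
    lfc_cut = np.log2(fc_cut)
    dec_feats = diff.loc[(diff["fdr"] <= fdr_cut) & (diff["log2fc"] <= -lfc_cut), "feature_id"]
    inc_feats = diff.loc[(diff["fdr"] <= fdr_cut) & (diff["log2fc"] >= lfc_cut), "feature_id"]
    if mode == "body":
        universe = set(annotation.gene_ids)
        return set(dec_feats) & universe, set(inc_feats) & universe
    if features is None:
        raise ValueError("promoter mode needs the peak interval frame")
    promoters = annotation.promoters()

    def genes_hit(feat_ids) -> set[str]:
        sub = features[features["feature_id"].isin(set(feat_ids))]
        if len(sub) == 0:
            return set()
        hit = overlaps_any(promoters, sub)
        return set(promoters.loc[hit, "gene_id"])

    return genes_hit(dec_feats), genes_hit(inc_feats)


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors; genes with any zero count are excluded."""
    positive = counts[(counts > 0).all(axis=1)]
    if len(positive) == 0:
        raise ValueError("no gene has positive counts in every sample")
    log_geomean = np.log(positive).mean(axis=1)
    ratios = np.log(positive).sub(log_geomean, axis=0)
    return np.exp(ratios.median(axis=0)).astype(float)


def rnaseq_de(
    table: CountTable,
    condition_map: Mapping[str, str],
    control: str,
    knockouts: Sequence[str],
    min_count: int = 10,
    fdr_cut: float = 0.05,
    fc_cut: float = 2.0,
) -> dict:
    """RNA-seq differential expression with the both-contrasts DEG rule.

    Genes with fewer than ``min_count`` fragments in every sample are
    dropped; size factors are median-of-ratios; each knockout condition is
    tested against the control with the exact conditional test; a DEG must
    pass (FDR, FC) in every knockout contrast with a shared direction.

    Returns dict with keys: contrasts (condition -> diff frame), deg_down,
    deg_up (sets), size_factors, filtered (CountTable).
    """
    counts = table.counts
    keep = (counts >= min_count).any(axis=1)
    if not keep.any():
        raise ValueError("all genes removed by the low-count filter")
    counts = counts[keep]
    size_factors = median_of_ratios_size_factors(counts)
    filtered = CountTable(counts, size_factors)
    by_cond: dict[str, list[str]] = {}
    for sample, cond in condition_map.items():
        by_cond.setdefault(cond, []).append(sample)
    lfc_cut = np.log2(fc_cut)
    contrasts: dict[str, pd.DataFrame] = {}
    down_sets, up_sets = [], []
    for ko in knockouts:
        res = exact_count_test(
            filtered,
            by_cond[control],
            by_cond[ko],
            NormalizationSpec("size_factors", size_factors),
        )
        contrasts[ko] = res
        sig = res["fdr"] <= fdr_cut
        down_sets.append(set(res.loc[sig & (res["log2fc"] <= -lfc_cut), "feature_id"]))
        up_sets.append(set(res.loc[sig & (res["log2fc"] >= lfc_cut), "feature_id"]))
    return {
        "contrasts": contrasts,
        "deg_down": set.intersection(*down_sets) if down_sets else set(),
        "deg_up": set.intersection(*up_sets) if up_sets else set(),
        "size_factors": size_factors,
        "filtered": filtered,
    }


def write_diff(diff: pd.DataFrame, path) -> None:
    diff.to_csv(path, sep="\t", index=False)


def read_diff(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"feature_id": str})
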