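"""Sliding-window Poisson peak calling against a control sample.

The caller tiles each chromosome with 500-bp windows at a 100-bp step and
counts fragment midpoints per window. The null rate for a window is the
larger of the genome-wide background (N_sample * width / genome length) and
the control count in the same window scaled to the sample depth, floored at
``LAMBDA_FLOOR`` — the local-lambda logic of window-based callers. Windows
with an upper-tail Poisson probability below the cutoff are merged when
separated by at most ``merge_gap`` bp; a merged peak keeps its most
significant window p-value and the summed observed/expected enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome import merge_interval_frame, overlaps_any
from .io_formats import FragmentSet

WINDOW = 500
STEP = 100
PCUT = 1e-5
MERGE_GAP = 100
LAMBDA_FLOOR = 0.25

PEAK_COLUMNS = ["chrom", "start", "end", "pvalue", "fold_enrichment", "control_id"]


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    pvalue: float
    fold_enrichment: float
    control_id: str


def _window_counts(mids_sorted: np.ndarray, starts: np.ndarray, width: np.ndarray) -> np.ndarray:
    lo = np.searchsorted(mids_sorted, starts, side="left")
    hi = np.searchsorted(mids_sorted, starts + width, side="left")
    return hi - lo


def call_peaks(
    sample: FragmentSet,
    control: FragmentSet,
    chrom_sizes: dict[str, int],
    window: int = WINDOW,
    step: int = STEP,
    pcut: float = PCUT,
    merge_gap: int = MERGE_GAP,
    lambda_floor: float = LAMBDA_FLOOR,
) -> pd.DataFrame:
    """Call enriched windows in ``sample`` against ``control``.

    Both fragment sets should be deduplicated. Returns a frame with
    ``PEAK_COLUMNS``, sorted by chrom/start.
    """
    for fs in (sample, control):
        if not fs.deduplicated:
            warnings.warn(f"{fs.sample_id}: fragments not marked deduplicated")
    n_s = sample.n_fragments
    n_c = control.n_fragments
    genome_length = float(sum(chrom_sizes.values()))
    if n_s == 0:
        return pd.DataFrame(columns=PEAK_COLUMNS)
    if n_c == 0:
        warnings.warn(f"{control.sample_id}: empty control, using background rate only")
    peaks: list[tuple] = []
    for chrom, L in chrom_sizes.items():
        L = int(L)
        starts = np.arange(0, L, step, dtype=np.int64)
        width = np.minimum(starts + window, L) - starts
        s_mids = np.sort(sample.midpoints(chrom))
        c_mids = np.sort(control.midpoints(chrom))
        k = _window_counts(s_mids, starts, width)
        lam_bg = n_s * width / genome_length
        lam_ctrl = (
            _window_counts(c_mids, starts, width) * (n_s / n_c) if n_c else np.zeros_like(lam_bg)
        )
        lam = np.maximum(np.maximum(lam_bg, lam_ctrl), lambda_floor)
        p = stats.poisson.sf(k - 1, lam)
        sig = np.flatnonzero(p < pcut)
        if sig.size == 0:
            continue
        # merge significant windows gapped by <= merge_gap
        w_start = starts[sig]
        w_end = starts[sig] + width[sig]
        run_start = 0
        for i in range(1, len(sig) + 1):
            if i == len(sig) or w_start[i] - w_end[i - 1] > merge_gap:
                members = sig[run_start:i]
                peaks.append(
                    (
                        chrom,
                        int(w_start[run_start]),
                        int(w_end[i - 1]),
                        float(p[members].min()),
                        float(k[members].sum() / lam[members].sum()),
                        control.sample_id,
                    )
                )
                run_start = i
    return pd.DataFrame(peaks, columns=PEAK_COLUMNS).sort_values(
        ["chrom", "start"]
    ).reset_index(drop=True)


def intersect_peak_sets(vs_igg: pd.DataFrame, vs_input: pd.DataFrame) -> pd.DataFrame:
    """Keep vs-IgG peaks that overlap (>= 1 bp) any vs-input peak.

    The retained coordinates are the vs-IgG peak coordinates (one canonical
    coordinate set).
    """
    if len(vs_igg) == 0 or len(vs_input) == 0:
        return vs_igg.iloc[0:0]
    keep = overlaps_any(vs_igg, vs_input)
    return vs_igg[keep].reset_index(drop=True)


def filter_blacklist(peaks: pd.DataFrame, blacklist: pd.DataFrame | None) -> pd.DataFrame:
    """Drop peaks overlapping (>= 1 bp) any blacklist interval."""
    if blacklist is None or len(blacklist) == 0 or len(peaks) == 0:
        return peaks.reset_index(drop=True)
    hit = overlaps_any(peaks, blacklist)
    return peaks[~hit].reset_index(drop=True)


def merge_peaks_across_samples(peak_sets: list[pd.DataFrame]) -> pd.DataFrame:
    """Union of peak intervals across samples; abutting intervals coalesce.

    Returns chrom/start/end plus a stable ``feature_id`` per merged peak.
    """
    frames = [p[["chrom", "start", "end"]] for p in peak_sets if len(p)]
    if not frames:
        return pd.DataFrame(columns=["feature_id", "chrom", "start", "end"])
    merged = merge_interval_frame(pd.concat(frames, ignore_index=True), gap=0)
    merged.insert(0, "feature_id", [f"peak_{i:05d}" for i in range(len(merged))])
    return merged


def write_peaks_bed(peaks: pd.DataFrame, path) -> None:
    """BED6+2: name=index, score=0, strand='.', then p-value and enrichment."""
    out = peaks.copy()
    out.insert(3, "name", [f"peak_{i:05d}" for i in range(len(out))])
    out.insert(4, "score", 0)
    out.insert(5, "strand", ".")
    cols = ["chrom", "start", "end", "name", "score", "strand", "pvalue", "fold_enrichment"]
    out[[c for c in cols if c in out.columns]].to_csv(path, sep="\t", header=False, index=False)


def read_peaks_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    if df.shape[1] >= 8:
        df = df.rename(columns={6: "pvalue", 7: "fold_enrichment"})
    keep = [c for c in ["chrom", "start", "end", "pvalue", "fold_enrichment"] if c in df.columns]
    return df[keep]
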