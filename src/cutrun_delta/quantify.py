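"""Fragment counting, scaled signal tracks, and metagene matrices.

Signal tracks follow the CUT&RUN display convention: each fragment is
resized to 151 bp around its midpoint (-75 to +75 bp), per-base coverage is
multiplied by 1e6 / library size, and values are averaged within 10-bp bins.

Metagene matrices use a fixed 100-column layout: 20 upstream 100-bp bins,
60 gene-body bins (length-scaled, mean coverage per bin so the profile
height is length-invariant), and 20 downstream 100-bp bins. Minus-strand
genes are orientation-flipped so column 0 is always the 5' upstream end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeAnnotation, gene_body
from .io_formats import FragmentSet

RESIZE_LENGTH = 151
RESIZE_FLANK = 75  # fragment midpoint -75 .. +75 inclusive
BIN_SIZE = 10
SCALE = 1e6

META_UPSTREAM_BINS = 20
META_BODY_BINS = 60
META_DOWNSTREAM_BINS = 20
META_FLANK_BIN_BP = 100
META_COLUMNS = META_UPSTREAM_BINS + META_BODY_BINS + META_DOWNSTREAM_BINS


@dataclass
class SignalTrack:
    """Binned, library-size-scaled coverage; one array of 10-bp bins per chrom."""

    values: dict[str, np.ndarray]
    chrom_sizes: dict[str, int]
    library_size: float
    bin_size: int = BIN_SIZE

    def __post_init__(self) -> None:
        if self.bin_size != BIN_SIZE:
            raise ValueError(f"bin width is fixed at {BIN_SIZE} bp")
        for chrom, vals in self.values.items():
            if (vals < 0).any():
                raise ValueError(f"{chrom}: negative track values")

    def per_bp(self, chrom: str) -> np.ndarray:
        """Expand the binned values back to per-bp resolution."""
        L = self.chrom_sizes[chrom]
        return np.repeat(self.values[chrom], self.bin_size)[:L]

    def total_mass(self) -> float:
        """Sum over all bins of value x bin width (bp x signal units)."""
        total = 0.0
        for chrom, vals in self.values.items():
            L = self.chrom_sizes[chrom]
            widths = np.full(len(vals), self.bin_size, dtype=float)
            if L % self.bin_size:
                widths[-1] = L % self.bin_size
            total += float((vals * widths).sum())
        return total


def count_fragments(frags: FragmentSet, features: pd.DataFrame) -> pd.Series:
    """Count fragment midpoints per feature (half-open containment).

    ``features`` needs chrom/start/end columns and a ``feature_id`` (or
    ``gene_id``) column. A midpoint landing in several overlapping features
    is counted once per containing feature, with a warning.
    """
    id_col = "feature_id" if "feature_id" in features.columns else "gene_id"
    counts = pd.Series(0, index=features[id_col].astype(str), dtype=np.int64)
    if _features_overlap(features):
        warnings.warn("feature set has overlapping intervals; midpoints may be counted in several features")
    for chrom, sub in features.groupby("chrom"):
        mids = np.sort(frags.midpoints(str(chrom)))
        if mids.size == 0:
            continue
        lo = np.searchsorted(mids, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(mids, sub["end"].to_numpy(), side="left")
        counts.loc[sub[id_col].astype(str)] = hi - lo
    return counts


def _features_overlap(features: pd.DataFrame) -> bool:
    for _, sub in features.groupby("chrom"):
        sub = sub.sort_values("start")
        if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
            return True
    return False


def count_table(
    frag_sets: Sequence[FragmentSet],
    features: pd.DataFrame,
    library_sizes: Mapping[str, float] | None = None,
):
    """Stack per-sample midpoint counts into a CountTable."""
    from .io_formats import CountTable

    cols = {fs.sample_id: count_fragments(fs, features) for fs in frag_sets}
    counts = pd.DataFrame(cols)
    sizes = pd.Series(library_sizes, dtype=float) if library_sizes is not None else None
    return CountTable(counts, sizes)


def make_track(
    frags: FragmentSet,
    library_size: float,
    chrom_sizes: Mapping[str, int],
    resize_length: int = RESIZE_LENGTH,
) -> SignalTrack:
    """Midpoint-resized, CPM-scaled, 10-bp-binned coverage track."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    flank = (resize_length - 1) // 2
    scale = SCALE / float(library_size)
    values: dict[str, np.ndarray] = {}
    for chrom, L in chrom_sizes.items():
        L = int(L)
        df = frags.fragments
        sub = df[df["chrom"] == chrom]
        mids = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
        starts = np.clip(mids - flank, 0, L).astype(np.int64)
        ends = np.clip(mids + flank + 1, 0, L).astype(np.int64)
        delta = np.zeros(L + 1, dtype=np.float64)
        np.add.at(delta, starts, 1.0)
        np.add.at(delta, ends, -1.0)
        cov = np.cumsum(delta[:-1]) * scale
        n_bins = int(np.ceil(L / BIN_SIZE))
        padded = np.zeros(n_bins * BIN_SIZE)
        padded[:L] = cov
        binned = padded.reshape(n_bins, BIN_SIZE).sum(axis=1)
        widths = np.full(n_bins, BIN_SIZE, dtype=float)
        if L % BIN_SIZE:
            widths[-1] = L % BIN_SIZE
        values[chrom] = binned / widths
    return SignalTrack(values=values, chrom_sizes={c: int(v) for c, v in chrom_sizes.items()},
                       library_size=float(library_size))


def average_tracks(tracks: Sequence[SignalTrack]) -> SignalTrack:
    """Per-bin mean across replicate tracks (already individually scaled)."""
    first = tracks[0]
    values = {
        chrom: np.mean([t.values[chrom] for t in tracks], axis=0)
        for chrom in first.values
    }
    return SignalTrack(values=values, chrom_sizes=first.chrom_sizes,
                       library_size=float(np.mean([t.library_size for t in tracks])))


def _gene_profile(per_bp: Mapping[str, np.ndarray], gene, chrom_len: int) -> np.ndarray:
    body = gene_body(gene)
    flank_bp = META_UPSTREAM_BINS * META_FLANK_BIN_BP
    lo = body.start - flank_bp
    hi = body.end + flank_bp
    seg = np.zeros(hi - lo, dtype=float)
    src_lo, src_hi = max(lo, 0), min(hi, chrom_len)
    seg[src_lo - lo : src_hi - lo] = per_bp[gene.chrom][src_lo:src_hi]
    if gene.strand == "-":
        seg = seg[::-1]
    up = seg[:flank_bp].reshape(META_UPSTREAM_BINS, META_FLANK_BIN_BP).mean(axis=1)
    down = seg[-flank_bp:].reshape(META_DOWNSTREAM_BINS, META_FLANK_BIN_BP).mean(axis=1)
    body_vals = seg[flank_bp : len(seg) - flank_bp]
    edges = np.linspace(0, len(body_vals), META_BODY_BINS + 1).astype(int)
    cum = np.concatenate([[0.0], np.cumsum(body_vals)])
    widths = np.maximum(np.diff(edges), 1)
    body_bins = (cum[edges[1:]] - cum[edges[:-1]]) / widths
    return np.concatenate([up, body_bins, down])


def meta_matrix(
    tracks: Sequence[SignalTrack],
    annotation: GenomeAnnotation,
    groups: Mapping[str, str] | pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene 100-column profiles plus per-group mean profiles.

    ``tracks`` are replicate tracks of one mark/condition; they are averaged
    per bin before profiling. Returns (matrix, group_profiles); the matrix
    carries a ``group`` column when groups are given.
    """
    avg = average_tracks(list(tracks))
    per_bp = {chrom: avg.per_bp(chrom) for chrom in avg.values}
    rows = {
        g.gene_id: _gene_profile(per_bp, g, annotation.chrom_length(g.chrom))
        for g in annotation
    }
    matrix = pd.DataFrame.from_dict(rows, orient="index")
    matrix.columns = [f"bin_{i:03d}" for i in range(META_COLUMNS)]
    if groups is None:
        return matrix, matrix.mean(axis=0).to_frame("all").T
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    matrix["group"] = groups.reindex(matrix.index)
    profiles = matrix.groupby("group", sort=True).mean(numeric_only=True)
    return matrix, profiles


def tss_region_signal(
    track: SignalTrack, annotation: GenomeAnnotation, flank: int = 1000
) -> pd.Series:
    """Mean signal in TSS +/- flank per gene (used for heatmap row ordering)."""
    out = {}
    per_bp = {chrom: track.per_bp(chrom) for chrom in track.values}
    for g in annotation:
        L = annotation.chrom_length(g.chrom)
        lo, hi = max(g.tss - flank, 0), min(g.tss + flank, L)
        out[g.gene_id] = float(per_bp[g.chrom][lo:hi].mean()) if hi > lo else 0.0
    return pd.Series(out)


def heatmap_order(
    groups: Mapping[str, str] | pd.Series,
    tss_signal: pd.Series,
    group_order: Sequence[str] = ("C1", "C2", "C3", "C4", "C5"),
) -> list[str]:
    """Row order: by cluster, then descending control TSS signal, ties by id."""
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    frame = pd.DataFrame({"group": groups, "signal": tss_signal.reindex(groups.index)})
    frame["rank"] = frame["group"].map({g: i for i, g in enumerate(group_order)})
    frame = frame.reset_index().sort_values(
        ["rank", "signal", "index"], ascending=[True, False, True], kind="mergesort"
    )
    return frame["index"].tolist()
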