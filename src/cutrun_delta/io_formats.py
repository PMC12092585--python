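"""Readers and writers for the on-disk formats the pipeline touches.

Fragments arrive as BED3 (one interval per fragment) or BEDPE (mate pair;
collapsed to the outer span). Counts travel as TSV matrices with the library
sizes embedded in a comment line so that a table round-trips losslessly.
Signal tracks are written as fixed-bin bedGraph.

Fragments are unstranded: a paired-end CUT&RUN fragment covers both strands,
so strand columns in input files are ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

FRAGMENT_COLUMNS = ["chrom", "start", "end"]


@dataclass
class FragmentSet:
    """Per-sample genomic fragments, tagged by which genome they mapped to."""

    sample_id: str
    genome_tag: str  # "target" or "spikein"
    fragments: pd.DataFrame  # columns chrom (str), start, end (int)
    deduplicated: bool = False

    def __post_init__(self) -> None:
        if self.genome_tag not in {"target", "spikein"}:
            raise ValueError(f"genome_tag must be target|spikein, got {self.genome_tag}")
        df = self.fragments
        missing = [c for c in FRAGMENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"fragments frame missing columns {missing}")
        self.fragments = df[FRAGMENT_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.fragments)

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    def midpoints(self, chrom: str | None = None) -> np.ndarray:
        df = self.fragments
        if chrom is not None:
            df = df[df["chrom"] == chrom]
        return ((df["start"].to_numpy() + df["end"].to_numpy()) // 2).astype(np.int64)


def _validate_rows(df: pd.DataFrame, lineno: np.ndarray) -> tuple[pd.DataFrame, list[str]]:
    bad = (df["start"] < 0) | (df["end"] <= df["start"])
    errors = [
        f"line {int(ln)}: invalid interval {c}:{s}-{e}"
        for ln, c, s, e in zip(
            lineno[bad.to_numpy()],
            df.loc[bad, "chrom"],
            df.loc[bad, "start"],
            df.loc[bad, "end"],
        )
    ]
    return df[~bad], errors


def read_fragments(
    path: str | Path,
    sample_id: str | None = None,
    genome_tag: str = "target",
    fmt: str = "auto",
    strict: bool = False,
) -> FragmentSet:
    """Read fragments from BED3+ or BEDPE.

    BEDPE mate pairs are collapsed to the outer span (min start, max end);
    inter-chromosomal pairs and malformed intervals are skipped with a
    warning listing line numbers (or raise when ``strict``).
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    try:
        raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame(columns=[0, 1, 2])
    if fmt == "auto":
        fmt = "bed"
        if raw.shape[1] >= 6:
            col5 = raw.iloc[:, 5].astype(str)
            # BED6 carries strand in column 6; BEDPE has the mate end there.
            if not col5.isin({"+", "-", "."}).all():
                fmt = "bedpe"
    lineno = np.arange(1, len(raw) + 1)
    errors: list[str] = []
    if fmt == "bedpe":
        df = raw.iloc[:, :6].copy()
        df.columns = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
        cross = (df["chrom1"] != df["chrom2"]).to_numpy()
        errors += [f"line {int(ln)}: inter-chromosomal pair" for ln in lineno[cross]]
        df, lineno = df[~cross], lineno[~cross]
        for c in ["start1", "end1", "start2", "end2"]:
            df[c] = df[c].astype(np.int64)
        out = pd.DataFrame(
            {
                "chrom": df["chrom1"].astype(str),
                "start": np.minimum(df["start1"], df["start2"]),
                "end": np.maximum(df["end1"], df["end2"]),
            }
        )
    else:
        out = raw.iloc[:, :3].copy()
        out.columns = FRAGMENT_COLUMNS
        if len(out):
            out["start"] = out["start"].astype(np.int64)
            out["end"] = out["end"].astype(np.int64)
            out["chrom"] = out["chrom"].astype(str)
    if len(out):
        out, row_errors = _validate_rows(out, lineno)
        errors += row_errors
    if errors:
        msg = f"{path}: skipped {len(errors)} malformed rows: " + "; ".join(errors[:10])
        if strict:
            raise ValueError(msg)
        warnings.warn(msg)
    out = out.astype({"start": np.int64, "end": np.int64})
    return FragmentSet(sample_id, genome_tag, out, deduplicated=False)


def deduplicate(frags: FragmentSet) -> FragmentSet:
    """Keep one copy per distinct (chrom, start, end); idempotent.

    PCR duplicates of a paired-end fragment share both endpoints, so "same
    genomic position" is read as identical fragment span.
    """
    unique = (
        frags.fragments.drop_duplicates(FRAGMENT_COLUMNS)
        .sort_values(FRAGMENT_COLUMNS)
        .reset_index(drop=True)
    )
    return replace(frags, fragments=unique, deduplicated=True)


def write_fragments_bed(frags: FragmentSet, path: str | Path) -> None:
    frags.fragments.to_csv(path, sep="\t", header=False, index=False)


def write_fragments_bedpe(frags: FragmentSet, path: str | Path) -> None:
    """Write each fragment as a degenerate mate pair spanning its two halves."""
    df = frags.fragments
    mid = (df["start"] + df["end"]) // 2
    out = pd.DataFrame(
        {
            "chrom1": df["chrom"],
            "start1": df["start"],
            "end1": np.maximum(mid, df["start"] + 1),
            "chrom2": df["chrom"],
            "start2": np.minimum(mid, df["end"] - 1),
            "end2": df["end"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Count tables


@dataclass
class CountTable:
    """Feature x sample matrix of non-negative integer counts.

    ``library_sizes`` are the per-sample scaling denominators (spike-in
    fragment counts, enriched-region totals, or size factors depending on
    the normalization in force); they default to column sums.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        counts = self.counts
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.library_sizes is None:
            self.library_sizes = counts.sum(axis=0).astype(float)
        else:
            self.library_sizes = pd.Series(self.library_sizes, dtype=float).reindex(
                counts.columns
            )
            if self.library_sizes.isna().any():
                raise ValueError("library_sizes missing for some samples")
        if (self.library_sizes <= 0).any():
            raise ValueError("library_sizes must be positive")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def with_library_sizes(self, sizes: Mapping[str, float]) -> "CountTable":
        return CountTable(self.counts.copy(), pd.Series(sizes, dtype=float))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.counts.equals(other.counts) and self.library_sizes.equals(
            other.library_sizes
        )


def write_counts(table: CountTable, path: str | Path) -> None:
    """TSV with a ``#library_sizes`` comment line, then header + rows."""
    with open(path, "w") as fh:
        sizes = "\t".join(repr(float(v)) for v in table.library_sizes)
        fh.write(f"#library_sizes\t{sizes}\n")
        table.counts.to_csv(fh, sep="\t", index_label="feature_id")


def read_counts(path: str | Path) -> CountTable:
    sizes = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#library_sizes"):
            sizes = [float(x) for x in first.rstrip("\n").split("\t")[1:]]
        else:
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t", index_col="feature_id")
    df = df.astype(np.int64)
    df.index = df.index.astype(str)
    lib = pd.Series(sizes, index=df.columns, dtype=float) if sizes is not None else None
    return CountTable(df, lib)


# ---------------------------------------------------------------------------
# bedGraph signal tracks


def write_bedgraph(track, path: str | Path, name: str = "track") -> None:
    """Write non-zero fixed-width bins, sorted by chrom then start.

    Values carry at most 6 significant digits.
    """
    bw = track.bin_size
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        for chrom in sorted(track.values):
            vals = track.values[chrom]
            nz = np.nonzero(vals)[0]
            L = track.chrom_sizes[chrom]
            for i in nz:
                start = int(i) * bw
                end = min(start + bw, L)
                fh.write(f"{chrom}\t{start}\t{end}\t{vals[i]:.6g}\n")


def read_bedgraph(path: str | Path, chrom_sizes: Mapping[str, int], library_size: float):
    """Reconstruct a SignalTrack written by :func:`write_bedgraph`."""
    from .quantify import SignalTrack

    rows = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "value"],
        skiprows=1,
        dtype={"chrom": str},
    )
    bin_size = 10
    values = {
        chrom: np.zeros(int(np.ceil(size / bin_size)), dtype=float)
        for chrom, size in chrom_sizes.items()
    }
    for row in rows.itertuples():
        values[row.chrom][int(row.start) // bin_size] = row.value
    return SignalTrack(values=values, chrom_sizes=dict(chrom_sizes),
                       library_size=library_size, bin_size=bin_size)
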