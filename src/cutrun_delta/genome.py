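"""Gene models, coordinate conventions, and TSS-anchored windows.

Every position in this package is 0-based, half-open ``[start, end)`` —
the BED convention. GTF input (1-based, closed) is converted on read.

The transcription start site (TSS) and transcript end site (TES) are stored
as *boundary* coordinates: for a ``+`` gene the TSS is the interval start,
for a ``-`` gene it is the interval end. This makes the span from TSS to TES
in genomic order exactly the half-open gene-body interval, and windows such
as "-1000 bp to +500 bp of the TSS" are computed strand-aware (upstream /
downstream in the direction of transcription).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 500
TARGET_UPSTREAM = 5000
TARGET_DOWNSTREAM = 1000


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (half-open semantics)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A strand-aware gene with a representative TSS/TES and its transcripts.

    ``tss``/``tes`` are boundary coordinates of the representative (longest)
    transcript: ``tss < tes`` for ``+`` genes and ``tes < tss`` for ``-``.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    transcripts: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.tss == self.tes:
            raise ValueError(f"{self.gene_id}: TSS == TES")
        if self.strand == "+" and not self.tss < self.tes:
            raise ValueError(f"{self.gene_id}: '+' gene needs tss < tes")
        if self.strand == "-" and not self.tes < self.tss:
            raise ValueError(f"{self.gene_id}: '-' gene needs tes < tss")
        for s, e in self.transcripts:
            if not (0 <= s < e):
                raise ValueError(f"{self.gene_id}: bad transcript ({s},{e})")

    @classmethod
    def from_transcripts(
        cls,
        gene_id: str,
        chrom: str,
        strand: str,
        transcripts: Iterable[tuple[int, int]],
    ) -> "GeneModel":
        """Build a gene whose TSS/TES come from its longest transcript."""
        txs = tuple(sorted(transcripts))
        if not txs:
            raise ValueError(f"{gene_id}: gene has no transcripts")
        start, end = max(txs, key=lambda t: (t[1] - t[0], -t[0]))
        tss, tes = (start, end) if strand == "+" else (end, start)
        return cls(gene_id, chrom, strand, tss, tes, txs)


def longest_transcript(gene: GeneModel) -> GenomicInterval:
    """Representative transcript: maximal length, ties to the smallest start."""
    if not gene.transcripts:
        raise ValueError(f"{gene.gene_id}: gene has no transcripts")
    start, end = max(gene.transcripts, key=lambda t: (t[1] - t[0], -t[0]))
    return GenomicInterval(gene.chrom, start, end)


def _tss_window(
    gene: GeneModel, upstream: int, downstream: int, chrom_length: int | None
) -> GenomicInterval:
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss - downstream, gene.tss + upstream
    start = max(start, 0)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GenomicInterval(gene.chrom, start, end)


def promoter_window(gene: GeneModel, chrom_length: int | None = None) -> GenomicInterval:
    """Promoter: -1000 bp to +500 bp around the TSS, strand-aware, clipped."""
    return _tss_window(gene, PROMOTER_UPSTREAM, PROMOTER_DOWNSTREAM, chrom_length)


def target_window(gene: GeneModel, chrom_length: int | None = None) -> GenomicInterval:
    """TF-target window: -5 kb to +1 kb around the TSS, strand-aware, clipped."""
    return _tss_window(gene, TARGET_UPSTREAM, TARGET_DOWNSTREAM, chrom_length)


def gene_body(gene: GeneModel) -> GenomicInterval:
    """TSS-to-TES span of the longest transcript, in genomic order."""
    if gene.transcripts:
        return longest_transcript(gene)
    lo, hi = min(gene.tss, gene.tes), max(gene.tss, gene.tes)
    return GenomicInterval(gene.chrom, lo, hi)


@dataclass
class GenomeAnnotation:
    """A set of genes plus chromosome sizes; gene ids are unique."""

    genes: list[GeneModel]
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate gene_ids in annotation")
        for g in self.genes:
            size = self.chrom_sizes.get(g.chrom)
            if size is None:
                raise ValueError(f"{g.gene_id}: unknown chromosome {g.chrom}")
            if max(g.tss, g.tes) > size:
                raise ValueError(f"{g.gene_id}: extends past end of {g.chrom}")
        self._by_id = {g.gene_id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def get(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_sizes.values()))

    def chrom_length(self, chrom: str) -> int:
        return self.chrom_sizes[chrom]

    def promoters(self) -> pd.DataFrame:
        """Promoter windows of all genes as a (gene_id, chrom, start, end) frame."""
        return self._window_frame(promoter_window)

    def target_windows(self) -> pd.DataFrame:
        return self._window_frame(target_window)

    def gene_bodies(self) -> pd.DataFrame:
        rows = [
            (g.gene_id, g.chrom, iv.start, iv.end, g.strand)
            for g in self.genes
            for iv in [gene_body(g)]
        ]
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])

    def _window_frame(self, fn) -> pd.DataFrame:
        rows = []
        for g in self.genes:
            iv = fn(g, self.chrom_sizes[g.chrom])
            rows.append((g.gene_id, g.chrom, iv.start, iv.end, g.strand))
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


# ---------------------------------------------------------------------------
# Readers / writers


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length in bp."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"], comment="#")
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def write_chrom_sizes(chrom_sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{int(size)}\n")


def read_gene_bed(path: str | Path, chrom_sizes: Mapping[str, int]) -> GenomeAnnotation:
    """6-column gene BED: chrom, start, end, gene_id, score, strand.

    Each row is treated as a single-transcript gene.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str, "gene_id": str, "strand": str},
    )
    genes = [
        GeneModel.from_transcripts(
            row.gene_id, row.chrom, row.strand, [(int(row.start), int(row.end))]
        )
        for row in df.itertuples()
    ]
    return GenomeAnnotation(genes, dict(chrom_sizes))


def write_gene_bed(annotation: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in annotation.genes:
            iv = gene_body(g)
            fh.write(f"{g.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_gtf(path: str | Path, chrom_sizes: Mapping[str, int]) -> GenomeAnnotation:
    """Read gene models from a GTF with gene/transcript features.

    GTF coordinates are 1-based closed; they are converted to 0-based
    half-open here. Transcript features are grouped under their gene_id;
    the longest transcript becomes the representative.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        txs = [
            (t.start - 1, t.end)
            for t in db.children(gene, featuretype="transcript")
        ]
        if not txs:
            txs = [(gene.start - 1, gene.end)]
        gid = gene.attributes.get("gene_id", [gene.id])[0]
        genes.append(GeneModel.from_transcripts(gid, gene.seqid, gene.strand, txs))
    if not genes:
        raise ValueError(f"no gene features found in {path}")
    return GenomeAnnotation(genes, dict(chrom_sizes))


def read_annotation(
    path: str | Path, chrom_sizes_path: str | Path
) -> GenomeAnnotation:
    """Dispatch on extension: .gtf/.gff -> GTF reader, otherwise gene BED."""
    chrom_sizes = read_chrom_sizes(chrom_sizes_path)
    suffix = Path(path).suffix.lower()
    if suffix in {".gtf", ".gff", ".gff3"}:
        return read_gtf(path, chrom_sizes)
    return read_gene_bed(path, chrom_sizes)


# ---------------------------------------------------------------------------
# Vectorised interval helpers shared by peaks/quantify/integrate.
#
# These operate on frames with chrom/start/end columns and implement the exact
# half-open semantics used throughout: intervals overlap iff they share >= 1 bp;
# merging coalesces overlapping AND abutting intervals.


def merge_interval_frame(df: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Coalesce intervals whose gap is <= ``gap`` bp (0 merges abutting)."""
    if len(df) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    out = []
    for chrom, sub in df.sort_values(["chrom", "start", "end"]).groupby(
        "chrom", sort=True
    ):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = int(starts[0]), int(ends[0])
        for s, e in zip(starts[1:], ends[1:]):
            if s - cur_e <= gap:
                cur_e = max(cur_e, int(e))
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def overlaps_any(query: pd.DataFrame, subject: pd.DataFrame) -> "pd.Series":
    """Boolean per query row: does it overlap (>=1 bp) any subject interval?"""
    import numpy as np

    result = pd.Series(False, index=query.index)
    if len(query) == 0 or len(subject) == 0:
        return result
    merged = merge_interval_frame(subject[["chrom", "start", "end"]], gap=-1)
    for chrom, sub in merged.groupby("chrom"):
        mask = query["chrom"] == chrom
        if not mask.any():
            continue
        s_starts = sub["start"].to_numpy()
        s_ends = sub["end"].to_numpy()
        q_start = query.loc[mask, "start"].to_numpy()
        q_end = query.loc[mask, "end"].to_numpy()
        # subject intervals are disjoint & sorted: the only candidate is the
        # last subject starting before q_end.
        idx = np.searchsorted(s_starts, q_end, side="left") - 1
        hit = (idx >= 0) & (s_ends[np.clip(idx, 0, None)] > q_start)
        result.loc[mask] = hit
    return result
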