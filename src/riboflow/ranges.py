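"""Spliced transcript-coordinate arithmetic and coverage.

This is the in-memory layer everything else builds on: contiguous genomic
intervals, spliced ranges (ordered exon blocks), transcript models with a CDS
expressed in transcript coordinates, collapsed read tables, and strand-aware
coverage over spliced regions.

Conventions
-----------
* All coordinates are 0-based half-open.  GTF input (1-based inclusive) is
  converted at the I/O boundary (:mod:`riboflow.io`).
* Transcript coordinates run 5'->3' along the mature transcript; position 0
  is the TSS.  On the '-' strand, exon blocks are stored in decreasing
  genomic order so that block order always matches transcript order.
* A collapsed read stores ``pos5``, the genomic coordinate of its biological
  5' end.  On '-' strand reads this is the *larger* genomic coordinate: a
  read of length L occupies ``[pos5 - L + 1, pos5]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "SplicedRange",
    "TranscriptModel",
    "Annotation",
    "CollapsedRead",
    "ReadTable",
    "CoverageVector",
    "to_transcript_coord",
    "to_genomic_coords",
    "extract_region",
    "coverage",
    "coverage_by_length",
]

READ_COLUMNS = ["chrom", "strand", "pos5", "length", "weight"]


@dataclass(frozen=True)
class GenomicInterval:
    """Contiguous 0-based half-open genomic interval on one strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SplicedRange:
    """Ordered exon-like blocks forming one spliced region.

    Blocks share chrom and strand and are ordered 5'->3' in transcript
    orientation: ascending genomic coordinates on '+', descending on '-'.
    ``truncated`` is metadata set by window-extraction helpers when the
    requested window had to be clipped at the transcript bounds.
    """

    blocks: Tuple[GenomicInterval, ...]
    truncated: bool = False

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("SplicedRange needs at least one block")
        chroms = {b.chrom for b in self.blocks}
        strands = {b.strand for b in self.blocks}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError("all blocks must share chrom and strand")
        if self.strand == "+":
            ok = all(a.end <= b.start for a, b in zip(self.blocks, self.blocks[1:]))
        else:
            ok = all(a.start >= b.end for a, b in zip(self.blocks, self.blocks[1:]))
        if not ok:
            raise ValueError("blocks must be non-overlapping and in transcript order")

    @property
    def chrom(self) -> str:
        return self.blocks[0].chrom

    @property
    def strand(self) -> str:
        return self.blocks[0].strand

    @property
    def width(self) -> int:
        return sum(b.width for b in self.blocks)

    @property
    def genomic_start(self) -> int:
        return min(b.start for b in self.blocks)

    @property
    def genomic_end(self) -> int:
        return max(b.end for b in self.blocks)

    def genomic_positions(self) -> np.ndarray:
        """Genomic coordinate of every base, in transcript order."""
        parts = []
        for b in self.blocks:
            if self.strand == "+":
                parts.append(np.arange(b.start, b.end))
            else:
                parts.append(np.arange(b.end - 1, b.start - 1, -1))
        return np.concatenate(parts)

    def genomic_to_local(self, g_pos: int) -> Optional[int]:
        """Local (transcript-orientation) offset of a genomic position, or None."""
        acc = 0
        for b in self.blocks:
            if b.start <= g_pos < b.end:
                if self.strand == "+":
                    return acc + (g_pos - b.start)
                return acc + (b.end - 1 - g_pos)
            acc += b.width
        return None

    def local_to_genomic(self, pos: int) -> int:
        if not (0 <= pos < self.width):
            raise IndexError(f"position {pos} out of range [0, {self.width})")
        acc = 0
        for b in self.blocks:
            if pos < acc + b.width:
                off = pos - acc
                if self.strand == "+":
                    return b.start + off
                return b.end - 1 - off
            acc += b.width
        raise AssertionError("unreachable")

    def subrange(self, start: int, end: int, truncated: bool = False) -> "SplicedRange":
        """Blocks covering local interval [start, end)."""
        if not (0 <= start < end <= self.width):
            raise IndexError(f"[{start}, {end}) outside [0, {self.width})")
        out: List[GenomicInterval] = []
        acc = 0
        for b in self.blocks:
            lo = max(start, acc)
            hi = min(end, acc + b.width)
            if lo < hi:
                if self.strand == "+":
                    out.append(GenomicInterval(b.chrom, b.start + (lo - acc), b.start + (hi - acc), "+"))
                else:
                    out.append(GenomicInterval(b.chrom, b.end - (hi - acc), b.end - (lo - acc), "-"))
            acc += b.width
        return SplicedRange(tuple(out), truncated=truncated)


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript: ordered exons plus an optional CDS in transcript coords.

    ``cds`` is a half-open interval ``[cds_start, cds_end)`` along the spliced
    transcript (stop codon included).  CDS widths that are not divisible by 3
    are tolerated (annotation may be imperfect) but flagged via
    :attr:`cds_frame_ok`.
    """

    tx_id: str
    gene_id: str
    exons: SplicedRange
    cds: Optional[Tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.cds is not None:
            s, e = self.cds
            if not (0 <= s < e <= self.exons.width):
                raise ValueError(f"{self.tx_id}: CDS [{s}, {e}) outside transcript [0, {self.exons.width})")

    @property
    def length(self) -> int:
        return self.exons.width

    @property
    def chrom(self) -> str:
        return self.exons.chrom

    @property
    def strand(self) -> str:
        return self.exons.strand

    @property
    def cds_frame_ok(self) -> Optional[bool]:
        if self.cds is None:
            return None
        return (self.cds[1] - self.cds[0]) % 3 == 0

    @property
    def tss_genomic(self) -> int:
        return self.exons.local_to_genomic(0)


@dataclass
class Annotation:
    """Transcript models plus a gene index and chromosome lengths."""

    transcripts: Dict[str, TranscriptModel]
    chrom_lengths: Dict[str, int]
    gene_index: Dict[str, List[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gene_index:
            idx: Dict[str, List[str]] = {}
            for tx in self.transcripts.values():
                idx.setdefault(tx.gene_id, []).append(tx.tx_id)
            self.gene_index = {g: sorted(v) for g, v in idx.items()}
        for tx in self.transcripts.values():
            clen = self.chrom_lengths.get(tx.chrom)
            if clen is not None and tx.exons.genomic_end > clen:
                raise ValueError(f"{tx.tx_id}: exon beyond chromosome end")

    def cds_transcripts(self) -> List[TranscriptModel]:
        return [t for t in sorted(self.transcripts.values(), key=lambda t: t.tx_id) if t.cds is not None]

    def gene_span(self, gene_id: str) -> GenomicInterval:
        txs = [self.transcripts[t] for t in self.gene_index[gene_id]]
        return GenomicInterval(
            txs[0].chrom,
            min(t.exons.genomic_start for t in txs),
            max(t.exons.genomic_end for t in txs),
            txs[0].strand,
        )


@dataclass(frozen=True)
class CollapsedRead:
    """One collapsed alignment: 5' end, aligned length, duplicate weight."""

    chrom: str
    strand: str
    pos5: int
    length: int
    weight: int = 1

    def __post_init__(self) -> None:
        if self.weight < 1 or self.length < 1:
            raise ValueError("weight and length must be >= 1")


class ReadTable:
    """Columnar table of collapsed reads (chrom, strand, pos5, length, weight).

    The canonical in-memory container for every read-based assay here
    (ribo-seq footprints, SSU, RNA-seq, CAGE tags, P-site tracks).  Backed by
    a pandas DataFrame; kept sorted by (chrom, strand, pos5, length).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in READ_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        df = df[READ_COLUMNS].copy()
        df["pos5"] = df["pos5"].astype(np.int64)
        df["length"] = df["length"].astype(np.int64)
        df["weight"] = df["weight"].astype(np.int64)
        df = df.sort_values(["chrom", "strand", "pos5", "length"], kind="mergesort").reset_index(drop=True)
        self.df = df

    @classmethod
    def from_reads(cls, reads: Iterable[CollapsedRead]) -> "ReadTable":
        rows = [(r.chrom, r.strand, r.pos5, r.length, r.weight) for r in reads]
        return cls(pd.DataFrame(rows, columns=READ_COLUMNS) if rows else cls.empty().df)

    @classmethod
    def empty(cls) -> "ReadTable":
        return cls(
            pd.DataFrame(
                {
                    "chrom": pd.Series(dtype=str),
                    "strand": pd.Series(dtype=str),
                    "pos5": pd.Series(dtype=np.int64),
                    "length": pd.Series(dtype=np.int64),
                    "weight": pd.Series(dtype=np.int64),
                }
            )
        )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def total_weight(self) -> int:
        return int(self.df["weight"].sum())

    def collapse(self) -> "ReadTable":
        """Merge records sharing (chrom, strand, pos5, length); weights add."""
        if len(self.df) == 0:
            return ReadTable.empty()
        g = self.df.groupby(["chrom", "strand", "pos5", "length"], as_index=False)["weight"].sum()
        return ReadTable(g)

    def subset_length(self, length: int) -> "ReadTable":
        return ReadTable(self.df[self.df["length"] == length])

    def lengths(self) -> List[int]:
        return sorted(self.df["length"].unique().tolist())

    def concat(self, other: "ReadTable") -> "ReadTable":
        return ReadTable(pd.concat([self.df, other.df], ignore_index=True))


@dataclass
class CoverageVector:
    """Per-position signal relative to a stated anchor.

    ``positions`` gives the anchor-relative coordinate of each entry (e.g.
    -30..29 for a TIS window); defaults to 0..len-1.
    """

    values: np.ndarray
    anchor: str = "region_start"
    positions: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) == 0:
            raise ValueError("values must be a non-empty 1-D array")
        if self.positions is None:
            self.positions = np.arange(len(self.values))
        else:
            self.positions = np.asarray(self.positions)
            if len(self.positions) != len(self.values):
                raise ValueError("positions and values must have equal length")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# coordinate mapping


def to_transcript_coord(g_pos: int, tx: TranscriptModel) -> Optional[int]:
    """0-based offset of a genomic position along the spliced transcript.

    Returns None (not an exception) when the position is intronic or outside
    the exons.
    """
    return tx.exons.genomic_to_local(g_pos)


def to_genomic_coords(tx_interval: Tuple[int, int], tx: TranscriptModel) -> SplicedRange:
    """Exon-clipped genomic blocks covering a transcript interval.

    Round-trips with :func:`to_transcript_coord` for every covered base.
    """
    start, end = tx_interval
    if not (0 <= start < end <= tx.length):
        raise IndexError(f"transcript interval [{start}, {end}) outside [0, {tx.length})")
    return tx.exons.subrange(start, end)


def extract_region(
    tx: TranscriptModel,
    kind: str,
    upstream: int = 0,
    downstream: int = 0,
) -> SplicedRange:
    """Extract a named transcript region as a genomic SplicedRange.

    kinds: leader, cds, trailer, start_codon, stop_codon, tss_window,
    tis_window.  Window kinds span ``[anchor - upstream, anchor + downstream)``
    in transcript coordinates, clipped at the transcript bounds with the
    result's ``truncated`` flag set.  CDS-dependent kinds require a CDS.
    """
    cds_kinds = {"cds", "leader", "trailer", "start_codon", "stop_codon", "tis_window"}
    if kind in cds_kinds and tx.cds is None:
        raise ValueError(f"{tx.tx_id}: region {kind!r} requires a CDS")
    n = tx.length
    if kind == "leader":
        s, e = 0, tx.cds[0]
    elif kind == "cds":
        s, e = tx.cds
    elif kind == "trailer":
        s, e = tx.cds[1], n
    elif kind == "start_codon":
        s, e = tx.cds[0], tx.cds[0] + 3
    elif kind == "stop_codon":
        s, e = tx.cds[1] - 3, tx.cds[1]
    elif kind in ("tss_window", "tis_window"):
        anchor = 0 if kind == "tss_window" else tx.cds[0]
        s, e = anchor - upstream, anchor + downstream
        cs, ce = max(s, 0), min(e, n)
        if ce <= cs:
            raise ValueError(f"{tx.tx_id}: window [{s}, {e}) empty after clipping")
        return tx.exons.subrange(cs, ce, truncated=(cs != s or ce != e))
    else:
        raise ValueError(f"unknown region kind {kind!r}")
    if e <= s:
        raise ValueError(f"{tx.tx_id}: region {kind!r} is empty")
    return tx.exons.subrange(s, e)


# ---------------------------------------------------------------------------
# coverage


def _strand_reads(reads: ReadTable, region: SplicedRange) -> pd.DataFrame:
    df = reads.df
    return df[(df["chrom"] == region.chrom) & (df["strand"] == region.strand)]


def coverage(reads: ReadTable, region: SplicedRange, mode: str = "five_prime") -> CoverageVector:
    """Weighted read coverage over a spliced region, in region coordinates.

    mode='five_prime' anchors each read at its 5' end; mode='whole_read'
    increments every genomic base the read covers that falls in the region.
    Reads on the opposite strand or outside the region contribute nothing.
    """
    if mode not in ("five_prime", "whole_read"):
        raise ValueError(f"unknown coverage mode {mode!r}")
    pos = region.genomic_positions()
    index = {int(g): i for i, g in enumerate(pos)}
    v = np.zeros(region.width, dtype=float)
    df = _strand_reads(reads, region)
    if len(df) == 0:
        return CoverageVector(v)
    pos5 = df["pos5"].to_numpy()
    lengths = df["length"].to_numpy()
    weights = df["weight"].to_numpy()
    if mode == "five_prime":
        for p, w in zip(pos5, weights):
            i = index.get(int(p))
            if i is not None:
                v[i] += w
    else:
        minus = region.strand == "-"
        for p, L, w in zip(pos5, lengths, weights):
            if minus:
                span = range(int(p), int(p) - int(L), -1)
            else:
                span = range(int(p), int(p) + int(L))
            for g in span:
                i = index.get(g)
                if i is not None:
                    v[i] += w
    return CoverageVector(v)


def coverage_by_length(
    reads: ReadTable, region: SplicedRange, mode: str = "five_prime"
) -> pd.DataFrame:
    """Coverage split by read length: rows = length, columns = region position.

    Row L equals ``coverage()`` of the length-L subset; rows sum to the
    unrestricted coverage.
    """
    lengths = sorted(_strand_reads(reads, region)["length"].unique().tolist())
    mat = np.zeros((len(lengths), region.width), dtype=float)
    for i, L in enumerate(lengths):
        mat[i] = coverage(reads.subset_length(int(L)), region, mode=mode).values
    return pd.DataFrame(mat, index=pd.Index(lengths, name="length"))


def count_in_region(reads: ReadTable, region: SplicedRange) -> float:
    """Count weight in a region under the standard counting rule.

    Width-1 records (P-sites, CAGE tags) count iff their position lies in the
    region; longer reads count on >= 1 nt genomic overlap with any block.
    """
    df = _strand_reads(reads, region)
    if len(df) == 0:
        return 0.0
    pos5 = df["pos5"].to_numpy()
    lengths = df["length"].to_numpy()
    weights = df["weight"].to_numpy()
    if region.strand == "-":
        lo = pos5 - lengths + 1
        hi = pos5 + 1
    else:
        lo = pos5
        hi = pos5 + lengths
    total = 0.0
    width1 = lengths == 1
    blocks = [(b.start, b.end) for b in region.blocks]
    for l, h, w, is1 in zip(lo, hi, weights, width1):
        for bs, be in blocks:
            if l < be and h > bs:
                total += w
                break
    return total
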