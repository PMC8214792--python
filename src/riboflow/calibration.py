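"""Ribo-seq read-length selection and P-site offset calibration.

Bona-fide ribosome footprints translocate three nucleotides per elongation
step, so their 5'-end coverage over coding regions carries a triplet
periodicity.  Read lengths are kept when the discrete Fourier transform of
their 5'-end profile over the first 150 CDS nucleotides (top-covered genes)
peaks at the period-3 bin and the profile holds at least ``min_reads`` reads.

Per kept length, the P-site offset (distance from the 5' end to the decoded
codon) is estimated by change-point analysis over a window spanning the
translation initiation site: initiating footprints pile up with their 5' ends
a fixed distance upstream of the start codon, producing a step in the profile
whose location is the offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .ranges import (
    Annotation,
    CoverageVector,
    ReadTable,
    SplicedRange,
    coverage,
    count_in_region,
    extract_region,
    to_transcript_coord,
)

DEFAULT_TIS_UPSTREAM = 30
DEFAULT_TIS_DOWNSTREAM = 29
DEFAULT_CHANGEPOINT_WINDOW = 5
CANONICAL_OFFSET = 12


@dataclass
class PeriodicityResult:
    read_length: int
    n_reads: float
    dominant_period: Optional[float]
    passes: bool


@dataclass
class OffsetTable:
    """Read length -> P-site offset, with the TIS profiles kept for QC."""

    offsets: Dict[int, int]
    profiles: Dict[int, CoverageVector] = field(default_factory=dict)

    def __getitem__(self, length: int) -> int:
        return self.offsets[length]

    def __contains__(self, length: int) -> bool:
        return length in self.offsets


class NoSignalError(ValueError):
    """Raised when a profile carries no reads."""


def top_covered_cds(reads: ReadTable, annotation: Annotation, fraction: float = 0.10) -> Set[str]:
    """Transcript ids of the top ``fraction`` of CDSs ranked by read coverage.

    Ranking is by total read weight overlapping the CDS; ties at the cutoff
    break deterministically toward the lexicographically smaller tx_id.
    """
    txs = annotation.cds_transcripts()
    if not txs:
        raise ValueError("no CDS-bearing transcripts in annotation")
    scores = []
    for tx in txs:
        region = extract_region(tx, "cds")
        scores.append((-count_in_region(reads, region), tx.tx_id))
    scores.sort()
    k = max(1, math.ceil(fraction * len(scores)))
    return {tx_id for _, tx_id in scores[:k]}


def cds_start_profile(
    reads: ReadTable,
    annotation: Annotation,
    tx_set: Iterable[str],
    read_length: int,
    first_n: int = 150,
) -> CoverageVector:
    """Summed 5'-end counts over the first ``first_n`` CDS nucleotides.

    Aggregated across ``tx_set`` for reads of the given length; CDSs shorter
    than ``first_n`` contribute their truncated prefix.
    """
    sub = reads.subset_length(read_length)
    v = np.zeros(first_n, dtype=float)
    for tx_id in sorted(tx_set):
        tx = annotation.transcripts[tx_id]
        if tx.cds is None:
            continue
        s, e = tx.cds
        n = min(first_n, e - s)
        region = tx.exons.subrange(s, s + n)
        v[:n] += coverage(sub, region, mode="five_prime").values
    return CoverageVector(v, anchor="CDS_start")


def periodicity_test(v: CoverageVector, min_reads: float = 1000) -> "PeriodicityResult":
    """Triplet-periodicity test on a 5'-end profile via the DFT.

    The mean-centered profile's DFT magnitudes over frequencies k=1..N/2 are
    examined; the test passes iff the profile holds at least ``min_reads``
    reads AND the maximal magnitude falls on the bin whose period N/k is
    closest to 3.  Read length is attached by the caller.
    """
    x = np.asarray(v.values, dtype=float)
    n_reads = float(x.sum())
    N = len(x)
    if N < 6 or n_reads == 0:
        return PeriodicityResult(0, n_reads, None, False)
    mags = np.abs(np.fft.rfft(x - x.mean()))[1:]  # drop DC
    k = np.arange(1, len(mags) + 1)
    periods = N / k
    k_best = int(np.argmax(mags))
    k_period3 = int(np.argmin(np.abs(periods - 3.0)))
    dominant = float(periods[k_best])
    passes = (n_reads >= min_reads) and (k_best == k_period3)
    return PeriodicityResult(0, n_reads, dominant, passes)


def select_lengths(
    reads: ReadTable,
    annotation: Annotation,
    fraction: float = 0.10,
    first_n: int = 150,
    min_reads: float = 1000,
    tx_set: Optional[Set[str]] = None,
) -> List[PeriodicityResult]:
    """Run the periodicity filter for every observed read length.

    Returns one result per length; downstream consumers use the passing
    lengths only.
    """
    if len(reads) == 0:
        return []
    if tx_set is None:
        tx_set = top_covered_cds(reads, annotation, fraction)
    out = []
    for L in reads.lengths():
        prof = cds_start_profile(reads, annotation, tx_set, int(L), first_n)
        res = periodicity_test(prof, min_reads=min_reads)
        res.read_length = int(L)
        out.append(res)
    return out


def tis_profile(
    reads: ReadTable,
    annotation: Annotation,
    read_length: int,
    upstream: int = DEFAULT_TIS_UPSTREAM,
    downstream: int = DEFAULT_TIS_DOWNSTREAM,
) -> CoverageVector:
    """Summed 5'-end counts at positions -upstream..+downstream around the TIS.

    Transcripts whose window would truncate (leader shorter than ``upstream``
    or CDS-to-end shorter than ``downstream``+1) are excluded entirely.
    """
    sub = reads.subset_length(read_length)
    n = upstream + downstream + 1
    v = np.zeros(n, dtype=float)
    for tx in annotation.cds_transcripts():
        s = tx.cds[0]
        if s < upstream or s + downstream + 1 > tx.length:
            continue
        region = tx.exons.subrange(s - upstream, s + downstream + 1)
        v += coverage(sub, region, mode="five_prime").values
    return CoverageVector(v, anchor="TIS", positions=np.arange(-upstream, downstream + 1))


def changepoint_offset(
    profile: CoverageVector,
    window: int = DEFAULT_CHANGEPOINT_WINDOW,
    canonical: int = CANONICAL_OFFSET,
) -> int:
    """P-site offset from the step in a TIS-anchored 5'-end profile.

    For each candidate changepoint c in [-upstream + window, 0], the mean of
    the ``window`` positions from c is compared against the mean of the
    ``window`` positions before c; the maximizing c gives offset = -c.  Ties
    prefer the offset closest to ``canonical`` (default 12, the canonical
    ribosome 5'-to-P-site distance), then the smaller offset.
    """
    v = np.asarray(profile.values, dtype=float)
    pos = np.asarray(profile.positions)
    if v.sum() <= 0:
        raise NoSignalError("TIS profile holds no reads")
    upstream = -int(pos[0])
    idx0 = upstream  # index of position 0
    best: Optional[Tuple[float, int]] = None
    candidates = []
    for c in range(-upstream + window, 1):
        i = idx0 + c
        down = v[i : i + window]
        up = v[max(0, i - window) : i]
        if len(up) == 0 or len(down) == 0:
            continue
        diff = float(down.mean() - up.mean())
        candidates.append((diff, -c))
    if not candidates:
        raise NoSignalError("no valid changepoint candidates")
    top = max(d for d, _ in candidates)
    tied = [o for d, o in candidates if abs(d - top) < 1e-12]
    tied.sort(key=lambda o: (abs(o - canonical), o))
    return tied[0]


def estimate_offsets(
    reads: ReadTable,
    annotation: Annotation,
    lengths: Iterable[int],
    upstream: int = DEFAULT_TIS_UPSTREAM,
    downstream: int = DEFAULT_TIS_DOWNSTREAM,
    window: int = DEFAULT_CHANGEPOINT_WINDOW,
    overrides: Optional[Dict[int, int]] = None,
) -> OffsetTable:
    """Per-length P-site offsets from TIS change-point analysis.

    ``overrides`` lets the user replace the suggestion for any length.
    Lengths whose profile has no signal fall back to the canonical offset 12.
    """
    offsets: Dict[int, int] = {}
    profiles: Dict[int, CoverageVector] = {}
    for L in sorted(set(int(x) for x in lengths)):
        prof = tis_profile(reads, annotation, L, upstream, downstream)
        profiles[L] = prof
        if overrides and L in overrides:
            offsets[L] = int(overrides[L])
            continue
        try:
            offsets[L] = changepoint_offset(prof, window=window)
        except NoSignalError:
            offsets[L] = CANONICAL_OFFSET
    return OffsetTable(offsets, profiles)


def shift_to_psites(
    reads: ReadTable,
    offsets: OffsetTable,
    annotation: Optional[Annotation] = None,
) -> Tuple[ReadTable, Dict[str, int]]:
    """Shift 5' ends by the per-length offset into width-1 P-site records.

    '+' reads move to pos5 + offset, '-' reads to pos5 - offset (transcript
    orientation); weights are preserved.  Reads of lengths absent from the
    offset table, or pushed off the chromosome, are dropped and counted.
    """
    df = reads.df
    keep = df["length"].isin(list(offsets.offsets))
    dropped_length = int(df.loc[~keep, "weight"].sum())
    df = df[keep].copy()
    off = df["length"].map(offsets.offsets).astype(np.int64)
    new_pos = np.where(df["strand"] == "+", df["pos5"] + off, df["pos5"] - off)
    df["pos5"] = new_pos
    in_bounds = df["pos5"] >= 0
    if annotation is not None:
        clen = df["chrom"].map(annotation.chrom_lengths)
        in_bounds &= df["pos5"] < clen.fillna(np.inf)
    dropped_bounds = int(df.loc[~in_bounds, "weight"].sum())
    df = df[in_bounds].copy()
    df["length"] = 1
    psites = ReadTable(df).collapse()
    return psites, {"dropped_unknown_length": dropped_length, "dropped_out_of_bounds": dropped_bounds}


def psites_by_length(
    reads: ReadTable,
    offsets: OffsetTable,
    annotation: Optional[Annotation] = None,
) -> ReadTable:
    """P-site records whose ``length`` column retains the footprint length.

    The records are positionally width-1 (P-site positions); the length
    column is kept as stratum metadata for per-length frame QC.
    """
    parts = []
    for L in sorted(offsets.offsets):
        shifted, _ = shift_to_psites(reads.subset_length(L), offsets, annotation)
        df = shifted.df.copy()
        df["length"] = L
        parts.append(df)
    if not parts:
        return ReadTable.empty()
    return ReadTable(pd.concat(parts, ignore_index=True))


def frame_usage(
    psites: ReadTable,
    annotation: Annotation,
    by_length: bool = False,
) -> pd.DataFrame:
    """Percentage of P-site weight in each translation frame over CDSs.

    Frame = (transcript position - cds_start) mod 3, aggregated over the CDS
    of every CDS-bearing transcript.  With ``by_length`` the stratification
    uses the table's ``length`` column (see :func:`psites_by_length`).
    Percentages sum to 100 within each stratum; empty strata are absent from
    the output.
    """
    rows: Dict[int, np.ndarray] = {}
    df = psites.df

    for tx in annotation.cds_transcripts():
        s, e = tx.cds
        region = tx.exons.subrange(s, e)
        index = {int(g): i for i, g in enumerate(region.genomic_positions())}
        sub = df[(df["chrom"] == tx.chrom) & (df["strand"] == tx.strand)]
        for p, L, w in zip(sub["pos5"], sub["length"], sub["weight"]):
            i = index.get(int(p))
            if i is None:
                continue
            key = int(L) if by_length else 0
            rows.setdefault(key, np.zeros(3))[i % 3] += w

    out = []
    for key in sorted(rows):
        counts = rows[key]
        tot = counts.sum()
        pct = counts / tot * 100.0 if tot > 0 else counts
        out.append({"length": key, "frame0": pct[0], "frame1": pct[1], "frame2": pct[2]})
    res = pd.DataFrame(out, columns=["length", "frame0", "frame1", "frame2"])
    if not by_length and len(res):
        res = res.drop(columns=["length"])
    return res
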