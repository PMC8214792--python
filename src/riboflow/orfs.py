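"""ORF discovery in sequences and transcript regions.

Finds open reading frames in nucleotide sequences (linear or circular
topology), upstream-ORF candidates in transcript leaders, and length-matched
negative regions sampled from 3' UTRs for classifier training.

Conventions fixed here (they differ between tools, so stated prominently):

* The stop codon is PART of the reported ORF interval.
* ORFs without a downstream in-frame stop are not reported.
* ``min_length`` includes the stop codon (the minimum useful value is 6:
  one start codon plus one stop codon).
* The default near-cognate start set is ATG plus every single-substitution
  variant that is not itself a stop codon.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .io import region_sequence, transcript_sequence
from .ranges import Annotation, SplicedRange, TranscriptModel, to_genomic_coords

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_BASES = "ACGT"


def near_cognate_starts(include_atg: bool = True) -> FrozenSet[str]:
    """ATG plus all single-mismatch ATG variants that are not stop codons."""
    out: Set[str] = {"ATG"} if include_atg else set()
    for i in range(3):
        for b in _BASES:
            cand = "ATG"[:i] + b + "ATG"[i + 1 :]
            if cand != "ATG" and cand not in STOP_CODONS:
                out.add(cand)
    return frozenset(out)


@dataclass(frozen=True)
class OrfInterval:
    """Half-open interval of one ORF in sequence coordinates.

    For wrapped circular ORFs, ``start < L <= end`` with positions understood
    modulo the sequence length, and ``wrapped`` is set.
    """

    start: int
    end: int
    wrapped: bool = False

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class OrfRecord:
    """An ORF anchored on a transcript, with its spliced genomic projection."""

    tx_id: str
    start: int  # transcript coordinate, inclusive
    end: int  # transcript coordinate, exclusive; includes the stop codon
    genomic: SplicedRange
    start_codon: str
    stop_codon: str
    kind: str = "candidate"  # candidate | uORF | CDS | negative_region
    frame_vs_cds: Optional[int] = None
    overlaps_cds: bool = False

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"{self.tx_id}:{self.start}-{self.end}:{self.kind}"


def _codon_positions(seq: str, codons: FrozenSet[str]) -> List[int]:
    """All positions i where seq[i:i+3] is in the codon set (any frame).

    Sequence codons containing a non-ACGT base (e.g. N) match nothing.
    """
    out = []
    for i in range(len(seq) - 2):
        c = seq[i : i + 3]
        if c in codons and "N" not in c:
            out.append(i)
    return out


def find_orfs(
    seq: str,
    starts: Iterable[str] = ("ATG",),
    stops: Iterable[str] = STOP_CODONS,
    longest_only: bool = False,
    min_length: int = 6,
    circular: bool = False,
) -> List[OrfInterval]:
    """Find ORFs: start codon .. first in-frame stop (stop included).

    Every reported interval begins at a start codon and ends immediately
    after the first in-frame stop downstream, so no ORF contains an internal
    in-frame stop.  ``longest_only`` keeps only the 5'-most start per
    (frame, stop).  ``circular`` additionally reports ORFs whose codons wrap
    the origin (found on the doubled sequence, reported once with the start
    position inside [0, L) and ``wrapped=True``).  Codons containing N match
    nothing.  Results are sorted by start position.
    """
    starts = frozenset(s.upper() for s in starts)
    stops = frozenset(s.upper() for s in stops)
    if starts & stops:
        raise ValueError("start and stop codon sets must be disjoint")
    seq = seq.upper()
    L = len(seq)
    if L == 0:
        return []

    def _scan(s: str, min_start: int, max_start: int) -> List[Tuple[int, int]]:
        start_pos = [p for p in _codon_positions(s, starts) if min_start <= p < max_start]
        stop_pos = _codon_positions(s, stops)
        by_frame: Dict[int, List[int]] = {0: [], 1: [], 2: []}
        for p in stop_pos:
            by_frame[p % 3].append(p)
        found: List[Tuple[int, int]] = []
        for p in start_pos:
            frame_stops = by_frame[p % 3]
            i = bisect_left(frame_stops, p + 3)
            if i < len(frame_stops):
                found.append((p, frame_stops[i] + 3))
        return found

    results: List[OrfInterval] = []
    linear = _scan(seq, 0, L)
    results.extend(OrfInterval(a, b) for a, b in linear)
    if circular:
        doubled = _scan(seq + seq, 0, L)
        for a, b in doubled:
            if b > L and b - a <= L:
                results.append(OrfInterval(a, b, wrapped=True))

    results = [o for o in results if o.width >= min_length]
    if longest_only:
        best: Dict[Tuple[int, bool], OrfInterval] = {}
        for o in results:
            # same stop & frame <=> same (end mod L for wrapped grouping)
            key = (o.end if not o.wrapped else o.end - len(seq), o.wrapped)
            if key not in best or o.start < best[key].start:
                best[key] = o
        results = list(best.values())
    return sorted(results, key=lambda o: (o.start, o.end))


# ---------------------------------------------------------------------------
# transcript-level searches


def _make_record(
    tx: TranscriptModel,
    seq: str,
    start: int,
    end: int,
    kind: str,
) -> OrfRecord:
    frame = None
    if tx.cds is not None:
        frame = (start - tx.cds[0]) % 3
    return OrfRecord(
        tx_id=tx.tx_id,
        start=start,
        end=end,
        genomic=to_genomic_coords((start, end), tx),
        start_codon=seq[start : start + 3],
        stop_codon=seq[end - 3 : end],
        kind=kind,
        frame_vs_cds=frame,
        overlaps_cds=tx.cds is not None and end > tx.cds[0],
    )


def uorf_candidates(
    annotation: Annotation,
    genome,
    starts: Iterable[str] = ("ATG",),
    stops: Iterable[str] = STOP_CODONS,
    max_downstream_overlap: bool = True,
    longest_only: bool = False,
    min_length: int = 6,
) -> Tuple[List[OrfRecord], int]:
    """Upstream-ORF candidates: start codon fully within the leader.

    When ``max_downstream_overlap`` is true, ORFs whose stop falls inside the
    CDS are kept and flagged ``overlaps_cds``; otherwise they are excluded.
    Returns (records, number of transcripts skipped for lacking a leader of
    at least one codon).
    """
    records: List[OrfRecord] = []
    skipped = 0
    for tx in annotation.cds_transcripts():
        cds_start = tx.cds[0]
        if cds_start < 3:
            skipped += 1
            continue
        seq = transcript_sequence(tx, genome)
        for orf in find_orfs(seq, starts, stops, longest_only=longest_only, min_length=min_length):
            if orf.start + 3 > cds_start:
                continue  # start codon not fully in the leader
            if orf.end > cds_start and not max_downstream_overlap:
                continue
            rec = _make_record(tx, seq, orf.start, orf.end, "uORF")
            records.append(rec)
    return records, skipped


def cds_records(annotation: Annotation, genome) -> List[OrfRecord]:
    """Annotated CDSs as OrfRecords (kind='CDS'), for positive training sets."""
    out = []
    for tx in annotation.cds_transcripts():
        seq = transcript_sequence(tx, genome)
        s, e = tx.cds
        rec = _make_record(tx, seq, s, e, "CDS")
        rec.overlaps_cds = False
        out.append(rec)
    return out


def negative_regions(
    annotation: Annotation,
    genome,
    lengths: Sequence[int],
    n: Optional[int] = None,
    seed: int = 0,
) -> List[OrfRecord]:
    """Uniformly sampled 3'-UTR sub-intervals, length-matched to ``lengths``.

    Widths are drawn from the supplied length distribution (rounded down to a
    multiple of 3, minimum 6); starts are uniform within the trailer.
    Reproducible under ``seed``; when trailer space is insufficient for a
    draw it is skipped, so fewer than ``n`` regions may be returned.
    """
    rng = np.random.default_rng(seed)
    lengths = [max(6, (int(L) // 3) * 3) for L in lengths]
    if n is None:
        n = len(lengths)
    txs = [t for t in annotation.cds_transcripts() if t.length - t.cds[1] >= 6]
    out: List[OrfRecord] = []
    if not txs:
        return out
    for _ in range(n):
        width = int(rng.choice(lengths))
        tx = txs[int(rng.integers(len(txs)))]
        trailer_start, trailer_end = tx.cds[1], tx.length
        # truncate the draw when the trailer is shorter than the requested width
        width = min(width, ((trailer_end - trailer_start) // 3) * 3)
        space = trailer_end - trailer_start - width
        s = trailer_start + int(rng.integers(space + 1))
        seq = transcript_sequence(tx, genome)
        rec = _make_record(tx, seq, s, s + width, "negative_region")
        rec.overlaps_cds = False
        out.append(rec)
    return out
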