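"""Translation features and metrics over ORFs and regions.

Implements the metric family used to characterize candidate ORFs from
ribosome profiling: FPKM-based ratios (translational efficiency TE,
initiation rate IR, scanning efficiency SE), frame-bias statistics
(ORFscore), fragment-length similarity (FLOSS), positional entropy, the
region-ratio scores (disengagement, ribosome release, inside/outside, start
region enrichment), Kozak-context similarity, and the ``compute_features``
wrapper assembling one row per ORF.

Every ratio adds a pseudocount of one read to numerator and denominator
counts before FPKM conversion, so all scores are finite for any input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import transcript_sequence
from .orfs import OrfRecord, cds_records, negative_regions
from .ranges import (
    Annotation,
    CoverageVector,
    ReadTable,
    SplicedRange,
    coverage,
    count_in_region,
    extract_region,
)

PSEUDOCOUNT = 1.0

#: Default Kozak position-weight table for TIS positions -4..-1, reflecting
#: the vertebrate consensus gccRccATG (purine at -3, pyrimidine elsewhere).
#: Rows sum to 1 per position; user-overridable wherever a PWM is accepted.
DEFAULT_KOZAK_PWM: Dict[int, Dict[str, float]] = {
    -4: {"A": 0.21, "C": 0.32, "G": 0.30, "T": 0.17},
    -3: {"A": 0.46, "C": 0.07, "G": 0.39, "T": 0.08},
    -2: {"A": 0.24, "C": 0.38, "G": 0.23, "T": 0.15},
    -1: {"A": 0.20, "C": 0.44, "G": 0.22, "T": 0.14},
}

FEATURE_COLUMNS = [
    "tx_id",
    "kind",
    "start_codon",
    "length",
    "distance_to_cds",
    "uorf_rank",
    "overlaps_cds",
    "count_rfp",
    "te",
    "ir",
    "se",
    "orfscore",
    "floss",
    "entropy",
    "disengagement",
    "release",
    "inside_outside",
    "start_region_relative",
    "start_codon_coverage",
    "kozak",
]


@dataclass
class LibrarySet:
    """Named read tables by assay role; totals are per-library mapped weight."""

    rfp: Optional[ReadTable] = None
    ssu: Optional[ReadTable] = None
    rna: Optional[ReadTable] = None
    cage: Optional[ReadTable] = None
    #: raw (un-shifted) footprints for length-based metrics; defaults to rfp
    rfp_raw: Optional[ReadTable] = None

    def total(self, role: str) -> float:
        table = getattr(self, role)
        return float(table.total_weight) if table is not None else float("nan")

    @property
    def rfp_lengths(self) -> Optional[ReadTable]:
        return self.rfp_raw if self.rfp_raw is not None else self.rfp


def fpkm(count: float, region_len: int, lib_total: float) -> float:
    """Fragments per kilobase of region per million mapped reads."""
    if region_len <= 0 or lib_total <= 0:
        raise ValueError("region length and library total must be positive")
    return count * 1e9 / (region_len * lib_total)


def _ratio(
    num_count: float,
    num_len: int,
    num_total: float,
    den_count: float,
    den_len: int,
    den_total: float,
    pseudocount: float = PSEUDOCOUNT,
) -> float:
    return fpkm(num_count + pseudocount, num_len, num_total) / fpkm(
        den_count + pseudocount, den_len, den_total
    )


def te(orf: OrfRecord, libs: LibrarySet, annotation: Annotation) -> float:
    """Translational efficiency: footprint FPKM over the ORF / RNA FPKM over the transcript."""
    if libs.rfp is None or libs.rna is None:
        return float("nan")
    tx = annotation.transcripts[orf.tx_id]
    return _ratio(
        count_in_region(libs.rfp, orf.genomic), orf.width, libs.total("rfp"),
        count_in_region(libs.rna, tx.exons), tx.length, libs.total("rna"),
    )


def ir(orf: OrfRecord, libs: LibrarySet, annotation: Annotation) -> float:
    """Initiation rate: elongating 80S over the ORF relative to SSU scanning on the leader."""
    if libs.rfp is None or libs.ssu is None:
        return float("nan")
    tx = annotation.transcripts[orf.tx_id]
    if tx.cds is None or tx.cds[0] == 0:
        return float("nan")
    leader = extract_region(tx, "leader")
    return _ratio(
        count_in_region(libs.rfp, orf.genomic), orf.width, libs.total("rfp"),
        count_in_region(libs.ssu, leader), leader.width, libs.total("ssu"),
    )


def se(tx_id: str, libs: LibrarySet, annotation: Annotation) -> float:
    """Scanning efficiency: SSU on the leader relative to RNA abundance."""
    if libs.ssu is None or libs.rna is None:
        return float("nan")
    tx = annotation.transcripts[tx_id]
    if tx.cds is None or tx.cds[0] == 0:
        return float("nan")
    leader = extract_region(tx, "leader")
    return _ratio(
        count_in_region(libs.ssu, leader), leader.width, libs.total("ssu"),
        count_in_region(libs.rna, tx.exons), tx.length, libs.total("rna"),
    )


def orfscore(frame_counts: Sequence[float]) -> float:
    """Signed frame-bias statistic over an ORF's P-site codon frames.

    With F0, F1, F2 the P-site counts in the three codon frames and
    Fbar their mean: log2(1 + sum((Fi - Fbar)^2 / Fbar)), negated when the
    maximal frame is not frame 0.  Zero when all counts are zero.
    """
    f = np.asarray(frame_counts, dtype=float)
    if f.shape != (3,):
        raise ValueError("expected three frame counts")
    fbar = f.mean()
    if fbar == 0:
        return 0.0
    s = math.log2(1.0 + float(((f - fbar) ** 2 / fbar).sum()))
    return -s if int(np.argmax(f)) != 0 else s


def frame_counts_over_orf(orf: OrfRecord, psites: ReadTable) -> Tuple[float, float, float]:
    """P-site weight per codon frame over the ORF (frame 0 = the ORF's own frame)."""
    v = coverage(psites, orf.genomic, mode="five_prime").values
    return tuple(float(v[i::3].sum()) for i in range(3))


def floss(orf_dist: Mapping[int, float], ref_dist: Mapping[int, float]) -> float:
    """Fragment length organization similarity score: half L1 distance.

    Both arguments are proportion-by-read-length distributions (each summing
    to 1); 0 = identical, 1 = disjoint supports.
    """
    support = set(orf_dist) | set(ref_dist)
    return 0.5 * sum(abs(orf_dist.get(L, 0.0) - ref_dist.get(L, 0.0)) for L in support)


def length_distribution(reads: ReadTable, region: SplicedRange) -> Dict[int, float]:
    """Read-length proportions among reads anchored (5' end) in a region."""
    pos = set(int(g) for g in region.genomic_positions())
    df = reads.df
    df = df[(df["chrom"] == region.chrom) & (df["strand"] == region.strand)]
    df = df[df["pos5"].isin(pos)]
    total = df["weight"].sum()
    if total == 0:
        return {}
    g = df.groupby("length")["weight"].sum() / total
    return {int(k): float(v) for k, v in g.items()}


def positional_entropy(cov: CoverageVector) -> float:
    """Shannon entropy of the coverage distribution, normalized to [0, 1].

    1 = uniform coverage, 0 = a single occupied position.  NaN when the
    region holds no reads; single-position regions return 0 by convention.
    """
    v = np.asarray(cov.values, dtype=float)
    total = v.sum()
    if total <= 0:
        return float("nan")
    if len(v) == 1:
        return 0.0
    p = v / total
    nz = p[p > 0]
    h = -(nz * np.log2(nz)).sum()
    return float(h / math.log2(len(v)))


def region_ratio_scores(
    orf: OrfRecord,
    libs: LibrarySet,
    annotation: Annotation,
    pseudocount: float = PSEUDOCOUNT,
) -> Dict[str, float]:
    """Ratio scores of footprint weight between an ORF and its flanking regions.

    disengagement: log2 ORF count vs count downstream of the ORF to the
    transcript end; release: log2 of length-normalized ORF vs 3'-UTR density;
    inside_outside: log2 ORF vs rest-of-transcript; start_codon_coverage:
    raw count over the start codon +/- one codon; start_region_relative:
    first-5-codon count relative to the whole ORF.  Pseudocounts keep every
    ratio finite; scores whose flanking region is empty are NaN.
    """
    nan = float("nan")
    out = {
        "disengagement": nan,
        "release": nan,
        "inside_outside": nan,
        "start_region_relative": nan,
        "start_codon_coverage": nan,
    }
    if libs.rfp is None:
        return out
    tx = annotation.transcripts[orf.tx_id]
    rfp = libs.rfp
    c_orf = count_in_region(rfp, orf.genomic)

    if orf.end < tx.length:
        down = tx.exons.subrange(orf.end, tx.length)
        out["disengagement"] = math.log2((c_orf + pseudocount) / (count_in_region(rfp, down) + pseudocount))
    if tx.cds is not None and tx.cds[1] < tx.length:
        trailer = extract_region(tx, "trailer")
        c_tr = count_in_region(rfp, trailer)
        out["release"] = math.log2(
            ((c_orf + pseudocount) / orf.width) / ((c_tr + pseudocount) / trailer.width)
        )
    c_tx = count_in_region(rfp, tx.exons)
    if tx.length > orf.width:
        c_rest = c_tx - c_orf
        out["inside_outside"] = math.log2((c_orf + pseudocount) / (max(c_rest, 0) + pseudocount))

    sc_lo = max(0, orf.start - 3)
    sc_hi = min(tx.length, orf.start + 6)
    out["start_codon_coverage"] = count_in_region(rfp, tx.exons.subrange(sc_lo, sc_hi))
    first5_hi = min(orf.end, orf.start + 15)
    c_first5 = count_in_region(rfp, tx.exons.subrange(orf.start, first5_hi))
    out["start_region_relative"] = (c_first5 + pseudocount) / (c_orf + pseudocount)
    return out


def kozak_similarity(
    context: str,
    pwm: Optional[Mapping[int, Mapping[str, float]]] = None,
) -> float:
    """Similarity of a TIS context (positions -4..-1) to the Kozak consensus.

    Sum of per-position weights for the observed bases divided by the sum of
    per-position maxima, in [0, 1].  NaN when the context contains N.
    """
    if pwm is None:
        pwm = DEFAULT_KOZAK_PWM
    context = context.upper()
    positions = sorted(pwm)
    if len(context) != len(positions):
        raise ValueError(f"context length {len(context)} != PWM positions {len(positions)}")
    num = 0.0
    den = 0.0
    for base, pos in zip(context, positions):
        row = pwm[pos]
        den += max(row.values())
        if base not in row:
            return float("nan")
        num += row[base]
    return num / den


def tis_context(orf: OrfRecord, annotation: Annotation, genome, n_upstream: int = 4) -> Optional[str]:
    """Bases at transcript positions -n_upstream..-1 relative to the ORF start."""
    if orf.start < n_upstream:
        return None
    tx = annotation.transcripts[orf.tx_id]
    seq = transcript_sequence(tx, genome)
    return seq[orf.start - n_upstream : orf.start]


def pseudo_log2(score: float) -> float:
    """Symmetric pseudo-log2 used for displaying signed scores.

    abs(log2(score)) for score > 0.01, -log2(-score) for score < -0.01,
    0 when |score| < 0.01.
    """
    if score > 0.01:
        return abs(math.log2(score))
    if score < -0.01:
        return -math.log2(-score)
    return 0.0


def reference_length_distribution(annotation: Annotation, libs: LibrarySet) -> Dict[int, float]:
    """Footprint length distribution over annotated CDSs (the FLOSS reference)."""
    reads = libs.rfp_lengths
    if reads is None:
        return {}
    agg: Dict[int, float] = {}
    for tx in annotation.cds_transcripts():
        region = extract_region(tx, "cds")
        pos = set(int(g) for g in region.genomic_positions())
        df = reads.df
        df = df[(df["chrom"] == tx.chrom) & (df["strand"] == tx.strand)]
        df = df[df["pos5"].isin(pos)]
        for L, w in df.groupby("length")["weight"].sum().items():
            agg[int(L)] = agg.get(int(L), 0.0) + float(w)
    total = sum(agg.values())
    return {L: w / total for L, w in agg.items()} if total else {}


def compute_features(
    orfs: Sequence[OrfRecord],
    libs: LibrarySet,
    annotation: Annotation,
    genome=None,
    kozak_pwm: Optional[Mapping[int, Mapping[str, float]]] = None,
) -> pd.DataFrame:
    """Assemble the full feature matrix: one row per ORF, one column per metric.

    Structural columns (length, start codon, distance to the CDS start, rank
    among uORFs of the same transcript, overlap flag) are always present;
    metric columns are NaN where the required library is absent.  The result
    is a pure function of its inputs, invariant to the order of ``orfs`` up
    to row order.
    """
    ref_dist = reference_length_distribution(annotation, libs) if libs.rfp_lengths is not None else {}

    # rank uORFs 5'->3' within each transcript
    ranks: Dict[int, int] = {}
    by_tx: Dict[str, List[int]] = {}
    for i, orf in enumerate(orfs):
        if orf.kind == "uORF":
            by_tx.setdefault(orf.tx_id, []).append(i)
    for tx_id, idxs in by_tx.items():
        for rank, i in enumerate(sorted(idxs, key=lambda j: (orfs[j].start, orfs[j].end)), start=1):
            ranks[i] = rank

    rows = []
    for i, orf in enumerate(orfs):
        tx = annotation.transcripts[orf.tx_id]
        row: Dict[str, object] = {
            "tx_id": orf.tx_id,
            "kind": orf.kind,
            "start_codon": orf.start_codon,
            "length": orf.width,
            "distance_to_cds": (tx.cds[0] - orf.start) if tx.cds is not None else np.nan,
            "uorf_rank": ranks.get(i, np.nan),
            "overlaps_cds": orf.overlaps_cds,
        }
        row["count_rfp"] = count_in_region(libs.rfp, orf.genomic) if libs.rfp is not None else np.nan
        row["te"] = te(orf, libs, annotation)
        row["ir"] = ir(orf, libs, annotation)
        row["se"] = se(orf.tx_id, libs, annotation)
        if libs.rfp is not None:
            row["orfscore"] = orfscore(frame_counts_over_orf(orf, libs.rfp))
            od = length_distribution(libs.rfp_lengths, orf.genomic) if libs.rfp_lengths is not None else {}
            row["floss"] = floss(od, ref_dist) if od and ref_dist else np.nan
            row["entropy"] = positional_entropy(coverage(libs.rfp, orf.genomic))
        else:
            row["orfscore"] = np.nan
            row["floss"] = np.nan
            row["entropy"] = np.nan
        row.update(region_ratio_scores(orf, libs, annotation))
        if genome is not None:
            ctx = tis_context(orf, annotation, genome)
            row["kozak"] = kozak_similarity(ctx, kozak_pwm) if ctx else np.nan
        else:
            row["kozak"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def training_sets(
    annotation: Annotation,
    libs: LibrarySet,
    genome,
    n_negatives: Optional[int] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Labeled feature matrix: CDSs as positives (1), 3'-UTR regions as negatives (0).

    Intended for export to any external classifier.  Negative regions are
    length-matched to the CDS length distribution by sampling.
    """
    pos = cds_records(annotation, genome)
    lengths = [p.width for p in pos]
    if n_negatives is None:
        n_negatives = len(pos)
    neg = negative_regions(annotation, genome, lengths, n=n_negatives, seed=seed)
    mat = compute_features(list(pos) + list(neg), libs, annotation, genome)
    mat["label"] = [1] * len(pos) + [0] * len(neg)
    return mat


def initiation_context_table(
    annotation: Annotation,
    genome,
    libs: LibrarySet,
    min_group: int = 10,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Initiation-rate statistics grouped by TIS sequence context.

    Returns (per-position table, per-4-mer table).  The first reports the
    median IR of CDSs carrying each base at each TIS-relative position -4..-1;
    the second the mean IR per full -4..-1 context.  Groups smaller than
    ``min_group`` are suppressed.
    """
    recs = cds_records(annotation, genome)
    entries = []
    for rec in recs:
        ctx = tis_context(rec, annotation, genome)
        if ctx is None or "N" in ctx:
            continue
        value = ir(rec, libs, annotation)
        if math.isnan(value):
            continue
        entries.append((ctx, value))

    pos_rows = []
    for offset, pos_label in enumerate(range(-4, 0)):
        groups: Dict[str, List[float]] = {}
        for ctx, value in entries:
            groups.setdefault(ctx[offset], []).append(value)
        for base in "ACGT":
            vals = groups.get(base, [])
            if len(vals) >= min_group:
                pos_rows.append(
                    {"position": pos_label, "base": base, "median_ir": float(np.median(vals)), "n": len(vals)}
                )
    mer_groups: Dict[str, List[float]] = {}
    for ctx, value in entries:
        mer_groups.setdefault(ctx, []).append(value)
    mer_rows = [
        {"context": ctx, "mean_ir": float(np.mean(vals)), "n": len(vals)}
        for ctx, vals in sorted(mer_groups.items())
        if len(vals) >= min_group
    ]
    per_pos = pd.DataFrame(pos_rows, columns=["position", "base", "median_ir", "n"])
    per_mer = pd.DataFrame(mer_rows, columns=["context", "mean_ir", "n"])
    if len(per_mer):
        per_mer = per_mer.sort_values("mean_ir", ascending=False).reset_index(drop=True)
    return per_pos, per_mer
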