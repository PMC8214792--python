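"""Metagene coverage transformations, anchored heatmaps and library QC.

Meta-coverage aggregates read signal over the same relative region across
many transcripts.  Regions (leader / CDS / trailer) are scaled to fixed bin
counts; per-transcript vectors can be transformed before aggregation:

* ``sum`` / ``mean`` / ``median`` — cross-transcript aggregators on raw bins
* ``zscore`` — (value - region mean) / region sample sd
* ``position_norm`` — value / total over the region
* ``transcript_norm`` — value / total over the transcript (sums to 1)
* ``mrna_norm`` — value / the transcript's RNA-seq FPKM
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .features import LibrarySet, fpkm
from .ranges import (
    Annotation,
    CoverageVector,
    GenomicInterval,
    ReadTable,
    SplicedRange,
    count_in_region,
    coverage,
    coverage_by_length,
    extract_region,
)

PER_TRANSCRIPT_TRANSFORMS = {"zscore", "position_norm", "transcript_norm", "mrna_norm"}
AGGREGATORS = {"sum", "mean", "median"}


@dataclass
class MetaProfile:
    transform: str
    values: np.ndarray
    segments: Tuple[int, int, int]
    n_transcripts: int
    skipped: int = 0

    @property
    def positions(self) -> np.ndarray:
        return np.arange(len(self.values))


def apply_transform(v: CoverageVector, transform: str, scale: Optional[float] = None) -> CoverageVector:
    """Apply one of the per-vector normalizations to a coverage vector.

    ``scale`` supplies the denominator for ``transcript_norm`` (transcript
    total; defaults to the vector's own total) and ``mrna_norm`` (the
    transcript's RNA FPKM, required).  A constant vector z-scores to zeros;
    all-zero vectors normalize to all-zero.
    """
    x = np.asarray(v.values, dtype=float)
    if transform == "zscore":
        sd = x.std(ddof=1) if len(x) > 1 else 0.0
        out = np.zeros_like(x) if sd == 0 else (x - x.mean()) / sd
    elif transform == "position_norm":
        tot = x.sum()
        out = x / tot if tot > 0 else np.zeros_like(x)
    elif transform == "transcript_norm":
        tot = scale if scale is not None else x.sum()
        out = x / tot if tot and tot > 0 else np.zeros_like(x)
    elif transform == "mrna_norm":
        if scale is None or scale <= 0:
            raise ValueError("mrna_norm requires a positive RNA FPKM scale")
        out = x / scale
    elif transform in AGGREGATORS:
        out = x.copy()  # aggregators act across transcripts, not within
    else:
        raise ValueError(f"unknown transform {transform!r}")
    return CoverageVector(out, anchor=v.anchor, positions=v.positions)


def _bin_vector(x: np.ndarray, bins: int) -> np.ndarray:
    """Mean within each of ``bins`` near-equal chunks."""
    return np.array([c.mean() for c in np.array_split(x, bins)])


def scaled_region_profile(
    reads: ReadTable,
    annotation: Annotation,
    bins: Tuple[int, int, int] = (25, 50, 25),
    transform: str = "sum",
    mode: str = "five_prime",
    libs: Optional[LibrarySet] = None,
    peak_cap_quantile: Optional[float] = None,
) -> MetaProfile:
    """Meta-coverage over leader / CDS / trailer scaled to fixed bin counts.

    Per transcript, each region's coverage is binned to its fixed bin count
    (mean within bin); per-transcript transforms are applied to the binned
    75-length vector; transcripts are then aggregated (sum, or mean/median
    when those are the requested transform).  Transcripts missing any region,
    or with a region shorter than its bin count, are skipped and counted.
    ``peak_cap_quantile`` optionally caps per-position counts at that
    quantile of the transcript's nonzero coverage before binning (outlier
    damping for contaminant peaks).
    """
    b_leader, b_cds, b_trailer = bins
    collected: List[np.ndarray] = []
    skipped = 0
    rna_fpkm: Dict[str, float] = {}
    if transform == "mrna_norm":
        if libs is None or libs.rna is None:
            raise ValueError("mrna_norm requires an RNA library")
        for tx in annotation.cds_transcripts():
            rna_fpkm[tx.tx_id] = fpkm(
                count_in_region(libs.rna, tx.exons), tx.length, libs.total("rna")
            )

    for tx in annotation.cds_transcripts():
        s, e = tx.cds
        if s == 0 or e == tx.length:
            skipped += 1
            continue
        if s < b_leader or (e - s) < b_cds or (tx.length - e) < b_trailer:
            skipped += 1
            continue
        full = coverage(reads, tx.exons, mode=mode).values
        if peak_cap_quantile is not None:
            nz = full[full > 0]
            if len(nz):
                full = np.minimum(full, np.quantile(nz, peak_cap_quantile))
        parts = [
            _bin_vector(full[:s], b_leader),
            _bin_vector(full[s:e], b_cds),
            _bin_vector(full[e:], b_trailer),
        ]
        vec = np.concatenate(parts)
        if transform in PER_TRANSCRIPT_TRANSFORMS:
            scale = None
            if transform == "transcript_norm":
                scale = float(full.sum())
            elif transform == "mrna_norm":
                scale = rna_fpkm.get(tx.tx_id)
                if not scale or scale <= 0:
                    skipped += 1
                    continue
            vec = apply_transform(CoverageVector(vec), transform, scale=scale).values
        collected.append(vec)

    if not collected:
        raise ValueError("no transcripts eligible for the scaled profile")
    stack = np.vstack(collected)
    if transform == "mean":
        agg = stack.mean(axis=0)
    elif transform == "median":
        agg = np.median(stack, axis=0)
    else:
        agg = stack.sum(axis=0)
    return MetaProfile(transform, agg, bins, len(collected), skipped)


def _anchor_window(
    tx, anchor: str, upstream: int, downstream: int, chrom_len: Optional[int]
) -> Optional[SplicedRange]:
    """Window around an anchor; TSS upstream extends into the genomic flank."""
    n = upstream + downstream + 1
    if anchor == "TSS":
        if tx.length < downstream + 1:
            return None
        down = tx.exons.subrange(0, downstream + 1)
        b0 = tx.exons.blocks[0]
        if tx.strand == "+":
            lo = b0.start - upstream
            if lo < 0:
                return None
            flank = GenomicInterval(tx.chrom, lo, b0.start, "+")
        else:
            hi = b0.end + upstream
            if chrom_len is not None and hi > chrom_len:
                return None
            flank = GenomicInterval(tx.chrom, b0.end, hi, "-")
        return SplicedRange((flank,) + down.blocks)
    if tx.cds is None:
        return None
    pivot = tx.cds[0] if anchor == "TIS" else tx.cds[1] - 3  # TTS: first stop-codon base
    lo, hi = pivot - upstream, pivot + downstream + 1
    if lo < 0 or hi > tx.length:
        return None
    return tx.exons.subrange(lo, hi)


def anchored_heatmap(
    reads: ReadTable,
    annotation: Annotation,
    anchor: str = "TSS",
    upstream: int = 30,
    downstream: int = 29,
    per_transcript_transform: Optional[str] = None,
) -> pd.DataFrame:
    """Per-read-length 5'-end count matrix around an anchor (TSS/TIS/TTS).

    Rows = read length, columns = anchor-relative position.  With
    ``per_transcript_transform='transcript_norm'`` each transcript's window
    counts are normalized to sum to 1 (per length) before summation, weighing
    transcripts equally.  Truncated windows are excluded.
    """
    if anchor not in ("TSS", "TIS", "TTS"):
        raise ValueError(f"unknown anchor {anchor!r}")
    positions = np.arange(-upstream, downstream + 1)
    lengths = reads.lengths()
    mat = pd.DataFrame(
        np.zeros((len(lengths), len(positions))),
        index=pd.Index(lengths, name="length"),
        columns=positions,
    )
    for tx in sorted(annotation.transcripts.values(), key=lambda t: t.tx_id):
        window = _anchor_window(tx, anchor, upstream, downstream, annotation.chrom_lengths.get(tx.chrom))
        if window is None:
            continue
        sub = coverage_by_length(reads, window, mode="five_prime")
        for L in sub.index:
            row = sub.loc[L].to_numpy()
            if per_transcript_transform == "transcript_norm":
                tot = row.sum()
                if tot > 0:
                    row = row / tot
            elif per_transcript_transform is not None:
                row = apply_transform(CoverageVector(row), per_transcript_transform).values
            mat.loc[L] += row
    return mat


# ---------------------------------------------------------------------------
# QC


@dataclass
class QcReport:
    class_counts: pd.DataFrame  # libraries x classes, weights
    class_percent: pd.DataFrame
    mrna_region_percent: pd.DataFrame  # libraries x (leader, cds, trailer)
    correlations: pd.DataFrame  # libraries x libraries, Pearson of log(FPKM+1)
    totals: pd.Series


def _assign_classes(
    reads: ReadTable,
    annotation: Annotation,
    contaminants: Mapping[str, Sequence[GenomicInterval]],
) -> Tuple[Dict[str, float], Dict[str, float]]:
    """Assign read weight to classes by priority: contaminants, mRNA regions, other."""
    class_w: Dict[str, float] = {}
    region_w = {"leader": 0.0, "cds": 0.0, "trailer": 0.0}
    # precompute per-(chrom,strand) lookups for mRNA regions by 5'-end position
    region_index: Dict[Tuple[str, str], Dict[int, str]] = {}
    for tx in annotation.transcripts.values():
        key = (tx.chrom, tx.strand)
        idx = region_index.setdefault(key, {})
        positions = tx.exons.genomic_positions()
        if tx.cds is None:
            for g in positions:
                idx.setdefault(int(g), "other_tx")
            continue
        s, e = tx.cds
        for i, g in enumerate(positions):
            label = "leader" if i < s else ("cds" if i < e else "trailer")
            idx.setdefault(int(g), label)

    cont_index: List[Tuple[str, str, int, int, str]] = []
    for label, ivs in contaminants.items():
        for iv in ivs:
            cont_index.append((iv.chrom, iv.strand, iv.start, iv.end, label))

    for row in reads.df.itertuples(index=False):
        w = float(row.weight)
        assigned = None
        for chrom, strand, s, e, label in cont_index:
            if row.chrom == chrom and row.strand == strand and s <= row.pos5 < e:
                assigned = label
                break
        if assigned is None:
            label = region_index.get((row.chrom, row.strand), {}).get(int(row.pos5))
            if label in ("leader", "cds", "trailer"):
                assigned = "mRNA"
                region_w[label] += w
            elif label == "other_tx":
                assigned = "other_tx"
            else:
                assigned = "other"
        class_w[assigned] = class_w.get(assigned, 0.0) + w
    return class_w, region_w


def qc_report(
    libraries: Mapping[str, ReadTable],
    annotation: Annotation,
    contaminants: Optional[Mapping[str, Sequence[GenomicInterval]]] = None,
) -> QcReport:
    """Mapping statistics per library plus pairwise correlations.

    Each read is assigned to exactly one class by priority (contaminant
    classes in their given order, then mRNA by 5'-end region, then other);
    percentage groups sum to 100.  Pairwise correlation is the Pearson
    correlation of log10(gene FPKM + 1) across genes.
    """
    contaminants = contaminants or {}
    class_rows = {}
    region_rows = {}
    totals = {}
    for name in sorted(libraries):
        cw, rw = _assign_classes(libraries[name], annotation, contaminants)
        class_rows[name] = cw
        region_rows[name] = rw
        totals[name] = float(libraries[name].total_weight)

    class_counts = pd.DataFrame(class_rows).T.fillna(0.0).sort_index(axis=1)
    class_percent = class_counts.div(class_counts.sum(axis=1), axis=0) * 100
    region_counts = pd.DataFrame(region_rows).T[["leader", "cds", "trailer"]]
    sums = region_counts.sum(axis=1)
    region_percent = region_counts.div(sums.where(sums > 0, 1.0), axis=0) * 100

    # gene-level FPKM correlation
    genes = sorted(annotation.gene_index)
    fpkm_cols = {}
    for name in sorted(libraries):
        lib = libraries[name]
        tot = max(lib.total_weight, 1)
        vals = []
        for g in genes:
            tx = _representative_tx(annotation, g)
            vals.append(fpkm(count_in_region(lib, tx.exons), tx.length, tot))
        fpkm_cols[name] = np.log10(np.asarray(vals) + 1.0)
    fdf = pd.DataFrame(fpkm_cols, index=genes)
    corr = fdf.corr(method="pearson")
    return QcReport(class_counts, class_percent, region_percent, corr, pd.Series(totals))


def _representative_tx(annotation: Annotation, gene_id: str):
    """The gene's longest CDS-bearing transcript (falls back to longest overall)."""
    txs = [annotation.transcripts[t] for t in annotation.gene_index[gene_id]]
    with_cds = [t for t in txs if t.cds is not None]
    pool = with_cds or txs
    return max(pool, key=lambda t: (t.length, t.tx_id))
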