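"""Transcription start site reannotation from CAGE 5'-end signal.

CAGE tags locate capped 5' ends at single-base resolution.  For each
CDS-bearing transcript the promoter-proximal window around the annotated TSS
is scanned and the position with the largest CAGE tag weight becomes the new
TSS; the first exon is extended or truncated accordingly while the CDS stays
fixed in genomic coordinates (its transcript-coordinate offset shifts with
the leader length).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .ranges import Annotation, GenomicInterval, ReadTable, SplicedRange, TranscriptModel


def reassign_tss(
    annotation: Annotation,
    cage: ReadTable,
    window_up: int = 1000,
    window_down: int = 500,
    min_count: float = 1,
    respect_gene_boundaries: bool = False,
) -> Tuple[Annotation, pd.DataFrame]:
    """Reassign each transcript's TSS to its largest promoter-proximal CAGE peak.

    The search window spans ``window_up`` nt genomically upstream of the
    annotated TSS and ``window_down`` nt downstream, clipped so the new TSS
    (a) never leaves the first exon going downstream, (b) always leaves a
    leader of at least 1 nt, and (c) stays on the chromosome.  With
    ``respect_gene_boundaries`` positions overlapping another gene's
    annotated span are excluded.  Ties between equally tall peaks break
    toward the position closest to the annotated TSS, then the more upstream
    one.  Peaks below ``min_count`` leave the transcript unchanged.

    Returns the new annotation plus a per-transcript report with columns
    tx_id, old_tss, new_tss, shift (nt change in leader length, positive =
    lengthened) and status (reassigned / unchanged / no_window / no_cds).
    """
    new_tx: Dict[str, TranscriptModel] = {}
    report = []
    spans = None
    if respect_gene_boundaries:
        spans = {g: annotation.gene_span(g) for g in annotation.gene_index}

    for tx_id in sorted(annotation.transcripts):
        tx = annotation.transcripts[tx_id]
        if tx.cds is None:
            new_tx[tx_id] = tx
            report.append((tx_id, tx.tss_genomic, tx.tss_genomic, 0, "no_cds"))
            continue
        entry = _reassign_one(annotation, tx, cage, window_up, window_down, min_count, spans)
        new_tx[tx_id] = entry[0]
        report.append((tx_id,) + entry[1:])

    rep = pd.DataFrame(report, columns=["tx_id", "old_tss", "new_tss", "shift", "status"])
    new_ann = Annotation(new_tx, dict(annotation.chrom_lengths))
    return new_ann, rep


def _reassign_one(
    annotation: Annotation,
    tx: TranscriptModel,
    cage: ReadTable,
    window_up: int,
    window_down: int,
    min_count: float,
    spans: Optional[Dict[str, GenomicInterval]],
) -> Tuple[TranscriptModel, int, int, int, str]:
    tss = tx.tss_genomic
    first_exon = tx.exons.blocks[0]
    leader_len = tx.cds[0]
    chrom_len = annotation.chrom_lengths.get(tx.chrom)
    # downstream movement is capped so the leader keeps >= 1 nt and the new
    # TSS stays within the (contiguous) first exon
    down_cap = min(window_down, leader_len - 1, first_exon.width - 1)
    down_cap = max(down_cap, 0)

    if tx.strand == "+":
        lo = tss - window_up
        hi = tss + down_cap
        lo = max(lo, 0)
    else:
        lo = tss - down_cap
        hi = tss + window_up
        if chrom_len is not None:
            hi = min(hi, chrom_len - 1)
    if hi < lo:
        return tx, tss, tss, 0, "no_window"

    allowed = np.ones(hi - lo + 1, dtype=bool)
    if spans is not None:
        for g, span in spans.items():
            if g == tx.gene_id or span.chrom != tx.chrom:
                continue
            a = max(lo, span.start)
            b = min(hi, span.end - 1)
            if a <= b:
                allowed[a - lo : b - lo + 1] = False
    if not allowed.any():
        return tx, tss, tss, 0, "no_window"

    df = cage.df
    sub = df[
        (df["chrom"] == tx.chrom)
        & (df["strand"] == tx.strand)
        & (df["pos5"] >= lo)
        & (df["pos5"] <= hi)
    ]
    if len(sub) == 0:
        return tx, tss, tss, 0, "unchanged"
    weights = sub.groupby("pos5")["weight"].sum()
    weights = weights[[allowed[p - lo] for p in weights.index]]
    if len(weights) == 0 or weights.max() < min_count:
        return tx, tss, tss, 0, "unchanged"

    best_w = weights.max()
    tied = sorted(weights[weights == best_w].index)
    upstream_sign = -1 if tx.strand == "+" else 1  # direction of 'more upstream'
    tied.sort(key=lambda p: (abs(p - tss), -upstream_sign * p))
    new_pos = int(tied[0])
    if new_pos == tss:
        return tx, tss, tss, 0, "unchanged"

    # positive shift = leader lengthened
    shift = (tss - new_pos) if tx.strand == "+" else (new_pos - tss)
    blocks = list(tx.exons.blocks)
    b0 = blocks[0]
    if tx.strand == "+":
        blocks[0] = GenomicInterval(b0.chrom, new_pos, b0.end, "+")
    else:
        blocks[0] = GenomicInterval(b0.chrom, b0.start, new_pos + 1, "-")
    new_exons = SplicedRange(tuple(blocks))
    new_cds = (tx.cds[0] + shift, tx.cds[1] + shift)
    new_model = TranscriptModel(tx.tx_id, tx.gene_id, new_exons, new_cds)
    return new_model, tss, new_pos, shift, "reassigned"
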