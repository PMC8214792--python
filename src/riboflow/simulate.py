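"""Deterministic generators for genomes, annotations and reads with known truth.

These generators define the study conditions for every property and
recovery test in the package: multi-exon transcripts on both strands with
leader/CDS/trailer structure, ribo-seq footprints with per-length 5'-to-P-site
offsets and tunable frame-0 enrichment, SSU reads enriched on leaders, CAGE
5'-end tags displaced from the annotated TSS, uniform RNA-seq coverage, and
negative-binomial count matrices with condition-by-assay interaction effects.

Every generator is a pure function of (parameters, seed): a single
numpy ``default_rng`` stream keyed by the seed drives all randomness.
Read-length and frame proportions are apportioned deterministically
(largest-remainder), so generated enrichment fractions are exact by
construction rather than sampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .ranges import (
    Annotation,
    GenomicInterval,
    ReadTable,
    READ_COLUMNS,
    SplicedRange,
    TranscriptModel,
)

STOPS = ("TAA", "TAG", "TGA")
_BASES = np.array(list("ACGT"))


@dataclass
class SimulatedGenome:
    genome: Dict[str, str]
    annotation: Annotation
    truth: Dict[str, object] = field(default_factory=dict)


def _apportion(total: int, weights: Sequence[float]) -> List[int]:
    """Largest-remainder apportionment of ``total`` among ``weights``."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights must sum to a positive value")
    exact = total * w / w.sum()
    base = np.floor(exact).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(exact - base), kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return base.tolist()


def _write_tx_base(chrom_seq: List[str], tx: TranscriptModel, tpos: int, base: str) -> None:
    """Write a transcript-orientation base into the genome (complementing on '-')."""
    g = tx.exons.local_to_genomic(tpos)
    if tx.strand == "-":
        base = {"A": "T", "C": "G", "G": "C", "T": "A"}[base]
    chrom_seq[g] = base


def make_genome(
    n_genes: int = 20,
    exon_count_range: Tuple[int, int] = (1, 3),
    leader_range: Tuple[int, int] = (80, 200),
    cds_codons_range: Tuple[int, int] = (40, 120),
    trailer_range: Tuple[int, int] = (80, 200),
    intron_range: Tuple[int, int] = (40, 200),
    intergenic: int = 1000,
    strand_mix: float = 0.5,
    chrom: str = "chrS",
    plant_uorf_genes: int = 0,
    uorf_codons: int = 8,
    seed: int = 0,
) -> SimulatedGenome:
    """Random genome + annotation with in-frame CDSs and known structure.

    Each gene has one transcript with leader, CDS (ATG ... stop, no internal
    in-frame stops) and trailer, split over 1..k exons, placed on either
    strand with ``intergenic`` nt gaps.  ``plant_uorf_genes`` embeds one
    clean uORF (ATG + non-stop codons + TAA, width ``3*uorf_codons``) in the
    leader of each of the first genes, recorded in the ground truth.
    Deterministic under ``seed``.
    """
    if leader_range[0] < 1 or trailer_range[0] < 1 or cds_codons_range[0] < 10:
        raise ValueError("infeasible region width ranges")
    if plant_uorf_genes and leader_range[0] < 3 * uorf_codons + 9:
        raise ValueError("leaders too short for planted uORFs")
    rng = np.random.default_rng(seed)
    transcripts: Dict[str, TranscriptModel] = {}
    truth_genes = []
    planted: Dict[str, Tuple[int, int]] = {}
    cursor = intergenic
    layouts = []
    for i in range(n_genes):
        leader = int(rng.integers(leader_range[0], leader_range[1] + 1))
        codons = int(rng.integers(cds_codons_range[0], cds_codons_range[1] + 1))
        trailer = int(rng.integers(trailer_range[0], trailer_range[1] + 1))
        txlen = leader + 3 * codons + trailer
        k = int(rng.integers(exon_count_range[0], exon_count_range[1] + 1))
        k = min(k, txlen // 30)  # keep exons non-trivial
        k = max(k, 1)
        if k > 1:
            cuts = sorted(rng.choice(np.arange(1, txlen), size=k - 1, replace=False).tolist())
        else:
            cuts = []
        exon_lens = np.diff([0] + cuts + [txlen]).tolist()
        introns = [int(rng.integers(intron_range[0], intron_range[1] + 1)) for _ in range(k - 1)]
        strand = "+" if rng.random() < strand_mix else "-"
        span = txlen + sum(introns)
        gstart = cursor
        cursor += span + intergenic
        layouts.append((i, strand, gstart, span, exon_lens, introns, leader, codons, trailer))

    chrom_len = cursor
    seq = rng.choice(_BASES, size=chrom_len).tolist()

    for (i, strand, gstart, span, exon_lens, introns, leader, codons, trailer) in layouts:
        blocks: List[GenomicInterval] = []
        if strand == "+":
            g = gstart
            for j, L in enumerate(exon_lens):
                blocks.append(GenomicInterval(chrom, g, g + L, "+"))
                g += L + (introns[j] if j < len(introns) else 0)
        else:
            g = gstart + span
            for j, L in enumerate(exon_lens):
                blocks.append(GenomicInterval(chrom, g - L, g, "-"))
                g -= L + (introns[j] if j < len(introns) else 0)
        tx_id = f"tx{i + 1:04d}"
        gene_id = f"g{i + 1:04d}"
        cds = (leader, leader + 3 * codons)
        tx = TranscriptModel(tx_id, gene_id, SplicedRange(tuple(blocks)), cds)
        transcripts[tx_id] = tx
        truth_genes.append(
            {"tx_id": tx_id, "gene_id": gene_id, "strand": strand, "leader": leader,
             "cds_codons": codons, "trailer": trailer}
        )

        # enforce a clean coding sequence: ATG start, TAA stop, no internal
        # in-frame stops
        for p, b in zip(range(cds[0], cds[0] + 3), "ATG"):
            _write_tx_base(seq, tx, p, b)
        for p, b in zip(range(cds[1] - 3, cds[1]), "TAA"):
            _write_tx_base(seq, tx, p, b)
        tx_seq = _tx_seq(seq, tx)
        for c in range(1, codons - 1):
            codon = tx_seq[cds[0] + 3 * c : cds[0] + 3 * c + 3]
            if codon in STOPS:
                _write_tx_base(seq, tx, cds[0] + 3 * c + 2, "C")

        if i < plant_uorf_genes:
            width = 3 * uorf_codons
            start = leader - width - 6
            body = rng.choice(_BASES, size=width - 6).tolist()
            payload = list("ATG") + body + list("TAA")
            # scrub in-frame stops in the body
            for c in range(1, uorf_codons - 1):
                if "".join(payload[3 * c : 3 * c + 3]) in STOPS:
                    payload[3 * c + 2] = "C"
            for off, b in enumerate(payload):
                _write_tx_base(seq, tx, start + off, b)
            planted[tx_id] = (start, start + width)

    annotation = Annotation(transcripts, {chrom: chrom_len})
    truth = {"seed": seed, "genes": truth_genes, "planted_uorfs": planted}
    return SimulatedGenome({chrom: "".join(seq)}, annotation, truth)


def _tx_seq(chrom_seq: List[str], tx: TranscriptModel) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    out = []
    for g in tx.exons.genomic_positions():
        b = chrom_seq[int(g)]
        out.append(comp[b] if tx.strand == "-" else b)
    return "".join(out)


def _default_expression(annotation: Annotation, rng: np.random.Generator) -> Dict[str, float]:
    """Log-normal expression levels: realistic rank spread across genes."""
    txs = [t.tx_id for t in annotation.cds_transcripts()]
    levels = rng.lognormal(mean=0.0, sigma=1.0, size=len(txs))
    return dict(zip(txs, levels))


def simulate_riboseq(
    annotation: Annotation,
    offsets: Mapping[int, int] = None,
    frame0_frac=0.9,
    depth: int = 20000,
    length_weights: Optional[Mapping[int, float]] = None,
    expression: Optional[Mapping[str, float]] = None,
    regions: Optional[Sequence[Tuple[str, int, int]]] = None,
    contaminant_frac: float = 0.0,
    contaminant_intervals: Optional[Sequence[GenomicInterval]] = None,
    seed: int = 0,
) -> Tuple[ReadTable, Dict[str, object]]:
    """Ribo-seq footprints with known P-site offsets and frame enrichment.

    Per read: a region (default: every CDS) is drawn proportional to
    expression, a codon uniformly within it, the frame deterministically per
    ``frame0_frac`` (scalar or per-length mapping; the non-frame-0 remainder
    splits evenly), the length per ``length_weights``, and the 5' end is
    placed at P-site minus the per-length offset.  Contaminant reads are
    placed uniformly on the supplied non-mRNA intervals.  Total generated
    weight equals ``depth``.
    """
    if offsets is None:
        offsets = {28: 12, 29: 13}
    rng = np.random.default_rng(seed)
    if length_weights is None:
        length_weights = {L: 1.0 for L in offsets}
    if expression is None:
        expression = _default_expression(annotation, rng)
    if regions is None:
        regions = [
            (t.tx_id, t.cds[0], t.cds[1]) for t in annotation.cds_transcripts()
        ]
    if not (0.0 <= contaminant_frac < 1.0):
        raise ValueError("contaminant_frac must be in [0, 1)")

    n_signal = int(round(depth * (1.0 - contaminant_frac)))
    n_cont = depth - n_signal
    lengths = sorted(length_weights)
    per_length = _apportion(n_signal, [length_weights[L] for L in lengths])

    region_weights = np.array([expression.get(tx_id, 0.0) for tx_id, _, _ in regions])
    if region_weights.sum() <= 0:
        raise ValueError("no expressed regions to simulate from")
    region_p = region_weights / region_weights.sum()

    rows: List[Tuple[str, str, int, int, int]] = []
    for L, nL in zip(lengths, per_length):
        f0 = frame0_frac[L] if isinstance(frame0_frac, Mapping) else frame0_frac
        if not (1.0 / 3.0 - 1e-9 <= f0 <= 1.0):
            raise ValueError("frame0_frac must be in [1/3, 1]")
        frame_counts = _apportion(nL, [f0, (1 - f0) / 2, (1 - f0) / 2])
        offset = offsets[L]
        for frame, nf in enumerate(frame_counts):
            if nf == 0:
                continue
            ridx = rng.choice(len(regions), size=nf, p=region_p)
            for r in ridx:
                tx_id, start, end = regions[r]
                tx = annotation.transcripts[tx_id]
                n_codons = (end - start) // 3
                codon = int(rng.integers(n_codons))
                psite = start + 3 * codon + frame
                fivep = psite - offset
                if fivep < 0 or fivep >= tx.length:
                    continue
                g = tx.exons.local_to_genomic(fivep)
                rows.append((tx.chrom, tx.strand, g, L, 1))

    if n_cont:
        if not contaminant_intervals:
            raise ValueError("contaminant_frac > 0 requires contaminant_intervals")
        widths = np.array([iv.width for iv in contaminant_intervals], dtype=float)
        p = widths / widths.sum()
        for _ in range(n_cont):
            iv = contaminant_intervals[int(rng.choice(len(contaminant_intervals), p=p))]
            pos = int(rng.integers(iv.start, iv.end))
            L = lengths[int(rng.integers(len(lengths)))]
            rows.append((iv.chrom, iv.strand, pos, L, 1))

    table = ReadTable(pd.DataFrame(rows, columns=READ_COLUMNS)).collapse()
    truth = {
        "offsets": dict(offsets),
        "frame0_frac": frame0_frac,
        "expression": dict(expression),
        "depth": depth,
        "seed": seed,
    }
    return table, truth


def simulate_ssu(
    annotation: Annotation,
    depth: int = 20000,
    leader_enrichment: float = 10.0,
    length_weights: Optional[Mapping[int, float]] = None,
    expression: Optional[Mapping[str, float]] = None,
    seed: int = 0,
) -> Tuple[ReadTable, Dict[str, object]]:
    """Scanning-SSU reads with 5' ends enriched on transcript leaders.

    Within a transcript, the per-nucleotide 5'-end density on the leader is
    ``leader_enrichment`` times that on the CDS+trailer body.
    """
    rng = np.random.default_rng(seed)
    if length_weights is None:
        length_weights = {30: 1.0}
    if expression is None:
        expression = _default_expression(annotation, rng)
    txs = annotation.cds_transcripts()
    weights = np.array([expression.get(t.tx_id, 0.0) for t in txs])
    p = weights / weights.sum()
    lengths = sorted(length_weights)
    per_length = _apportion(depth, [length_weights[L] for L in lengths])
    rows = []
    for L, nL in zip(lengths, per_length):
        tidx = rng.choice(len(txs), size=nL, p=p)
        for t in tidx:
            tx = txs[t]
            leader_len = tx.cds[0]
            body_len = tx.length - leader_len
            w_leader = leader_enrichment * leader_len
            if rng.random() < w_leader / (w_leader + body_len):
                pos = int(rng.integers(leader_len))
            else:
                pos = leader_len + int(rng.integers(body_len))
            g = tx.exons.local_to_genomic(pos)
            rows.append((tx.chrom, tx.strand, g, L, 1))
    table = ReadTable(pd.DataFrame(rows, columns=READ_COLUMNS)).collapse()
    return table, {"leader_enrichment": leader_enrichment, "expression": dict(expression), "seed": seed}


def simulate_rnaseq(
    annotation: Annotation,
    depth: int = 20000,
    read_length: int = 36,
    expression: Optional[Mapping[str, float]] = None,
    seed: int = 0,
) -> Tuple[ReadTable, Dict[str, object]]:
    """RNA-seq reads with 5' ends uniform along each transcript."""
    rng = np.random.default_rng(seed)
    if expression is None:
        expression = _default_expression(annotation, rng)
    txs = sorted(annotation.transcripts.values(), key=lambda t: t.tx_id)
    weights = np.array([expression.get(t.tx_id, 0.0) for t in txs])
    keep = weights > 0
    txs = [t for t, k in zip(txs, keep) if k]
    weights = weights[keep]
    p = weights / weights.sum()
    rows = []
    tidx = rng.choice(len(txs), size=depth, p=p)
    for t in tidx:
        tx = txs[t]
        pos = int(rng.integers(tx.length))
        g = tx.exons.local_to_genomic(pos)
        rows.append((tx.chrom, tx.strand, g, read_length, 1))
    table = ReadTable(pd.DataFrame(rows, columns=READ_COLUMNS)).collapse()
    return table, {"expression": dict(expression), "seed": seed}


def simulate_cage(
    annotation: Annotation,
    shifts: Optional[Mapping[str, int]] = None,
    tags_per_tx: int = 5,
    jitter_p: float = 0.0,
    seed: int = 0,
) -> Tuple[ReadTable, Dict[str, object]]:
    """CAGE 5'-end tags at the true TSS, displaced from the annotation.

    ``shifts[tx_id]`` is the true TSS displacement in nucleotides, positive =
    upstream of the annotated TSS (leader lengthened).  ``jitter_p`` adds a
    geometric jitter of that parameter to each tag (0 = exact peaks).
    """
    rng = np.random.default_rng(seed)
    if shifts is None:
        shifts = {}
    rows = []
    for tx in annotation.cds_transcripts():
        d = int(shifts.get(tx.tx_id, 0))
        tss = tx.tss_genomic
        base = tss - d if tx.strand == "+" else tss + d
        for _ in range(tags_per_tx):
            pos = base
            if jitter_p > 0:
                j = int(rng.geometric(jitter_p)) - 1
                if rng.random() < 0.5:
                    j = -j
                pos = base + j
            clen = annotation.chrom_lengths.get(tx.chrom)
            if pos < 0 or (clen is not None and pos >= clen):
                continue
            rows.append((tx.chrom, tx.strand, pos, 1, 1))
    table = ReadTable(pd.DataFrame(rows, columns=READ_COLUMNS)).collapse()
    return table, {"shifts": dict(shifts), "seed": seed}


def simulate_counts(
    n_genes: int = 2000,
    n_reps: int = 3,
    mean: float = 200.0,
    dispersion: float = 0.05,
    log2fc_rna: Optional[Sequence[float]] = None,
    log2fc_te: Optional[Sequence[float]] = None,
    size_factors: Optional[Mapping[str, float]] = None,
    seed: int = 0,
):
    """NB count matrix for a 2-condition, 2-assay (RFP/RNA) design.

    Per gene, condition B multiplies the RNA mean by 2^log2fc_rna and the
    RFP mean by 2^(log2fc_rna + log2fc_te) — the interaction effect is a
    footprint-only change.  ``dispersion`` 0 gives Poisson counts.  Returns
    (CountTable, truth).
    """
    from .dte import CountTable

    rng = np.random.default_rng(seed)
    fc_rna = np.zeros(n_genes) if log2fc_rna is None else np.asarray(log2fc_rna, dtype=float)
    fc_te = np.zeros(n_genes) if log2fc_te is None else np.asarray(log2fc_te, dtype=float)
    if len(fc_rna) != n_genes or len(fc_te) != n_genes:
        raise ValueError("effect vectors must have length n_genes")
    base = np.full(n_genes, float(mean)) if np.isscalar(mean) else np.asarray(mean, dtype=float)

    libs = []
    for assay in ("RFP", "RNA"):
        for cond in ("A", "B"):
            for rep in range(1, n_reps + 1):
                libs.append((f"{assay}_{cond}_{rep}", assay, cond, rep))
    design = pd.DataFrame(
        [{"library": n, "assay": a, "condition": c, "replicate": r} for n, a, c, r in libs]
    ).set_index("library")

    cols = {}
    for name, assay, cond, rep in libs:
        mu = base.copy()
        if cond == "B":
            mu = mu * np.exp2(fc_rna + (fc_te if assay == "RFP" else 0.0))
        sf = 1.0 if size_factors is None else float(size_factors.get(name, 1.0))
        mu = mu * sf
        if dispersion > 0:
            r = 1.0 / dispersion
            cols[name] = rng.negative_binomial(r, r / (r + mu))
        else:
            cols[name] = rng.poisson(mu)
    counts = pd.DataFrame(cols, index=pd.Index([f"g{i + 1:05d}" for i in range(n_genes)], name="gene"))
    truth = {"log2fc_rna": fc_rna, "log2fc_te": fc_te, "mean": base, "dispersion": dispersion, "seed": seed}
    return CountTable(counts, design), truth
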