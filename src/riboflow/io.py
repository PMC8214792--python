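"""Readers and writers for the standard formats the toolkit touches.

GTF/GFF3 annotation (via gffutils), FASTA transcript sequence extraction
(via pyfaidx or a plain mapping), SAM/BAM alignments collapsed to 5'-end
records (via pysam), BED12 with per-frame colors, variableStep wiggle, and
the portable collapsed-read table format ".crt" (a parquet table with a
schema-version header; sum of weights is conserved by every round trip).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd
import pyarrow as pa
import pyarrow.parquet as pq

from .ranges import (
    Annotation,
    GenomicInterval,
    ReadTable,
    READ_COLUMNS,
    SplicedRange,
    TranscriptModel,
)

CRT_SCHEMA_VERSION = "1"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

FRAME_COLORS = {0: "230,41,55", 1: "46,125,230", 2: "60,179,113"}


class MalformedAnnotationError(ValueError):
    """Raised for structurally invalid gene models (mixed strand/chrom exons)."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# annotation


def read_annotation(
    gtf_path: Union[str, os.PathLike],
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> Annotation:
    """Assemble transcript models from a GTF/GFF3 file.

    Exon and CDS features must carry transcript and gene identifiers.  The
    1-based inclusive input coordinates become 0-based half-open; exons are
    ordered 5'->3' and the CDS (including an adjacent stop codon when
    annotated separately) is re-expressed in transcript coordinates.
    Transcripts without CDS features simply have ``cds=None``.
    """
    import gffutils

    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_transcripts=True,
        disable_infer_genes=True,
    )
    exons: Dict[str, List[Tuple[int, int, str, str]]] = {}
    cds_parts: Dict[str, List[Tuple[int, int]]] = {}
    gene_of: Dict[str, str] = {}
    for feat in db.all_features():
        ftype = feat.featuretype.lower()
        if ftype not in ("exon", "cds", "stop_codon"):
            continue
        tx_ids = feat.attributes.get("transcript_id") or feat.attributes.get("Parent")
        if not tx_ids:
            continue
        gene_ids = feat.attributes.get("gene_id") or [""]
        for tx_id in tx_ids:
            gene_of.setdefault(tx_id, gene_ids[0] or tx_id)
            iv = (feat.start - 1, feat.end, feat.seqid, feat.strand)
            if ftype == "exon":
                exons.setdefault(tx_id, []).append(iv)
            else:  # cds or stop_codon: both are coding-region bases here
                cds_parts.setdefault(tx_id, []).append((feat.start - 1, feat.end))

    transcripts: Dict[str, TranscriptModel] = {}
    for tx_id, blocks in exons.items():
        chroms = {b[2] for b in blocks}
        strands = {b[3] for b in blocks}
        if len(chroms) > 1 or len(strands) > 1:
            raise MalformedAnnotationError(f"{tx_id}: exons span multiple chroms/strands")
        chrom, strand = blocks[0][2], blocks[0][3]
        ordered = sorted(blocks, key=lambda b: b[0], reverse=(strand == "-"))
        spliced = SplicedRange(tuple(GenomicInterval(chrom, s, e, strand) for s, e, _, _ in ordered))
        cds = None
        if tx_id in cds_parts:
            # merge CDS + stop_codon genomic pieces, then map ends to tx coords
            pieces = sorted(set(cds_parts[tx_id]))
            merged: List[List[int]] = []
            for s, e in pieces:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            locs = []
            for s, e in merged:
                a = spliced.genomic_to_local(s)
                b = spliced.genomic_to_local(e - 1)
                if a is None or b is None:
                    raise MalformedAnnotationError(f"{tx_id}: CDS outside exons")
                locs.extend([a, b])
            cds = (min(locs), max(locs) + 1)
        transcripts[tx_id] = TranscriptModel(tx_id, gene_of[tx_id], spliced, cds)

    if chrom_lengths is None:
        lengths: Dict[str, int] = {}
        for tx in transcripts.values():
            lengths[tx.chrom] = max(lengths.get(tx.chrom, 0), tx.exons.genomic_end)
        chrom_lengths = lengths
    return Annotation(transcripts, dict(chrom_lengths))


def write_gtf(annotation: Annotation, path: Union[str, os.PathLike]) -> None:
    """Write transcripts back out as GTF (exon + CDS features, 1-based)."""
    lines = []
    for tx_id in sorted(annotation.transcripts):
        tx = annotation.transcripts[tx_id]
        attrs = f'gene_id "{tx.gene_id}"; transcript_id "{tx.tx_id}";'
        for b in sorted(tx.exons.blocks, key=lambda b: b.start):
            lines.append(
                f"{tx.chrom}\triboflow\texon\t{b.start + 1}\t{b.end}\t.\t{tx.strand}\t.\t{attrs}"
            )
        if tx.cds is not None:
            for b in sorted(tx.exons.subrange(*tx.cds).blocks, key=lambda b: b.start):
                lines.append(
                    f"{tx.chrom}\triboflow\tCDS\t{b.start + 1}\t{b.end}\t.\t{tx.strand}\t.\t{attrs}"
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# sequence


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    if isinstance(genome, Mapping):
        seq = genome[chrom][start:end]
        if end > len(genome[chrom]):
            raise IndexError(f"{chrom}: [{start}, {end}) beyond chrom end {len(genome[chrom])}")
        return str(seq)
    # pyfaidx.Fasta or similar
    rec = genome[chrom]
    if end > len(rec):
        raise IndexError(f"{chrom}: [{start}, {end}) beyond chrom end {len(rec)}")
    return str(rec[start:end])


def transcript_sequence(tx: TranscriptModel, genome) -> str:
    """Concatenated exon sequence in transcript orientation, uppercase.

    '-' strand transcripts are reverse-complemented.  ``genome`` is either a
    mapping chrom -> sequence string or an indexed FASTA (pyfaidx.Fasta).
    """
    parts = []
    for b in tx.exons.blocks:
        s = _fetch(genome, b.chrom, b.start, b.end).upper()
        parts.append(reverse_complement(s) if tx.strand == "-" else s)
    return "".join(parts)


def region_sequence(region: SplicedRange, genome) -> str:
    parts = []
    for b in region.blocks:
        s = _fetch(genome, b.chrom, b.start, b.end).upper()
        parts.append(reverse_complement(s) if region.strand == "-" else s)
    return "".join(parts)


def write_fasta(sequences: Mapping[str, str], path: Union[str, os.PathLike], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# alignments


@dataclass
class AlignmentStats:
    used: int = 0
    unmapped: int = 0
    secondary: int = 0
    supplementary: int = 0


def read_alignments(
    bam_path: Union[str, os.PathLike],
    collapse: bool = True,
) -> Tuple[ReadTable, AlignmentStats]:
    """Load primary alignments as collapsed 5'-end records.

    Each primary alignment contributes one unit of weight at its aligned 5'
    terminus (soft clips excluded) with its aligned query length; '-' strand
    reads anchor at the larger coordinate.  ``collapse`` merges identical
    (chrom, strand, pos5, length) records, conserving total weight.
    """
    import pysam

    stats = AlignmentStats()
    rows = []
    with pysam.AlignmentFile(str(bam_path), check_sq=False) as af:
        for aln in af.fetch(until_eof=True):
            if aln.is_unmapped:
                stats.unmapped += 1
                continue
            if aln.is_secondary:
                stats.secondary += 1
                continue
            if aln.is_supplementary:
                stats.supplementary += 1
                continue
            stats.used += 1
            strand = "-" if aln.is_reverse else "+"
            pos5 = aln.reference_end - 1 if aln.is_reverse else aln.reference_start
            rows.append((aln.reference_name, strand, pos5, aln.query_alignment_length, 1))
    table = ReadTable(pd.DataFrame(rows, columns=READ_COLUMNS)) if rows else ReadTable.empty()
    if collapse:
        table = table.collapse()
    return table, stats


# ---------------------------------------------------------------------------
# BED12


def write_bed12(orfs, path: Union[str, os.PathLike], color_by: str = "frame") -> None:
    """One BED12 line per ORF; blocks reflect the spliced genomic projection.

    ``color_by='frame'`` sets itemRgb from ``frame_vs_cds`` (gray when the
    frame is undefined); 'none' writes 0.
    """
    lines = []
    for orf in orfs:
        sr: SplicedRange = orf.genomic
        blocks = sorted(sr.blocks, key=lambda b: b.start)
        chrom_start = blocks[0].start
        chrom_end = blocks[-1].end
        sizes = ",".join(str(b.width) for b in blocks)
        starts = ",".join(str(b.start - chrom_start) for b in blocks)
        if color_by == "frame" and getattr(orf, "frame_vs_cds", None) is not None:
            rgb = FRAME_COLORS[orf.frame_vs_cds % 3]
        elif color_by == "frame":
            rgb = "128,128,128"
        else:
            rgb = "0"
        name = getattr(orf, "name", None) or f"{orf.tx_id}:{orf.start}-{orf.end}"
        lines.append(
            "\t".join(
                [
                    sr.chrom,
                    str(chrom_start),
                    str(chrom_end),
                    name,
                    "0",
                    sr.strand,
                    str(chrom_start),
                    str(chrom_end),
                    rgb,
                    str(len(blocks)),
                    sizes,
                    starts,
                ]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))


def read_bed12(path: Union[str, os.PathLike]) -> List[Tuple[str, SplicedRange, str]]:
    """Parse BED12 back to (name, SplicedRange, itemRgb) tuples."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, name, strand, rgb = f[0], int(f[1]), f[3], f[5], f[8]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = [
                GenomicInterval(chrom, start + o, start + o + s, strand)
                for o, s in zip(offsets, sizes)
            ]
            if strand == "-":
                blocks = blocks[::-1]
            out.append((name, SplicedRange(tuple(blocks)), rgb))
    return out


# ---------------------------------------------------------------------------
# wiggle


def write_wig(table: ReadTable, prefix: Union[str, os.PathLike], value: str = "weight") -> List[str]:
    """Export per-position 5'-end signal as variableStep wiggle, one file per strand.

    Positions are converted to wiggle's 1-based convention.  Returns written
    paths.  Records sharing a position have their weights summed.
    """
    paths = []
    for strand, tag in (("+", "fwd"), ("-", "rev")):
        df = table.df[table.df["strand"] == strand]
        path = f"{prefix}.{tag}.wig"
        with open(path, "w") as fh:
            for chrom in sorted(df["chrom"].unique()):
                sub = df[df["chrom"] == chrom].groupby("pos5")["weight"].sum()
                fh.write(f"variableStep chrom={chrom}\n")
                for pos, w in sub.items():
                    fh.write(f"{pos + 1} {w}\n")
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# collapsed-read format (.crt)


class CrtFormatError(ValueError):
    """Unknown or missing schema version in a collapsed-read file."""


def write_collapsed(table: ReadTable, path: Union[str, os.PathLike]) -> None:
    """Serialize a collapsed-read table as a versioned parquet file."""
    arrow = pa.Table.from_pandas(table.df, preserve_index=False)
    arrow = arrow.replace_schema_metadata({"crt_schema_version": CRT_SCHEMA_VERSION})
    pq.write_table(arrow, str(path))


def read_collapsed(path: Union[str, os.PathLike]) -> ReadTable:
    arrow = pq.read_table(str(path))
    meta = arrow.schema.metadata or {}
    version = meta.get(b"crt_schema_version")
    if version is None or version.decode() != CRT_SCHEMA_VERSION:
        raise CrtFormatError(f"unsupported crt schema version: {version!r}")
    return ReadTable(arrow.to_pandas())


def read_reads(path: Union[str, os.PathLike]) -> ReadTable:
    """Load reads from .crt, SAM or BAM based on the file extension."""
    p = str(path)
    if p.endswith(".crt"):
        return read_collapsed(p)
    table, _ = read_alignments(p)
    return table
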