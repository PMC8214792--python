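"""End-to-end workflows stitching the modules together.

Two pipelines mirror the standard analyses: footprint calibration
(read-length selection -> P-site offsets -> shifted tracks -> frame QC) and
uORF annotation (CAGE TSS reannotation -> uORF candidate search -> feature
matrix -> labeled training sets).  Both are plain functions over library
objects or an on-disk experiment configuration, write deterministic TSV
outputs, and log their parameters to a machine-readable JSON file so reruns
are byte-identical.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as rio
from .cage import reassign_tss
from .calibration import (
    OffsetTable,
    estimate_offsets,
    frame_usage,
    psites_by_length,
    select_lengths,
    shift_to_psites,
)
from .features import LibrarySet, compute_features, training_sets
from .orfs import cds_records, negative_regions, uorf_candidates
from .ranges import Annotation, ReadTable

FLOAT_FMT = "%.6g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class ExperimentConfig:
    """Declarative experiment description with relative paths.

    ``libraries`` maps a unique name to a dict with keys path, assay
    (RFP/SSU/RNA/CAGE), condition, replicate.  Paths resolve against
    ``root``.
    """

    gtf: str
    libraries: Dict[str, Dict[str, object]]
    fasta: Optional[str] = None
    root: str = "."

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        root = raw.get("root", str(Path(path).parent))
        return cls(gtf=raw["gtf"], libraries=raw["libraries"], fasta=raw.get("fasta"), root=root)

    def resolve(self, rel: str) -> str:
        return str(Path(self.root) / rel)

    def load_reads(self, role: str) -> Optional[ReadTable]:
        tables = [
            rio.read_reads(self.resolve(str(entry["path"])))
            for name, entry in sorted(self.libraries.items())
            if entry.get("assay") == role
        ]
        if not tables:
            return None
        out = tables[0]
        for t in tables[1:]:
            out = out.concat(t)
        return out.collapse()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def _write_log(outdir: Path, name: str, params: Mapping[str, object]) -> None:
    with open(outdir / name, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def run_calibration_pipeline(
    reads: ReadTable,
    annotation: Annotation,
    outdir: str,
    fraction: float = 0.10,
    min_reads: float = 1000,
    track_format: str = "crt",
) -> Dict[str, object]:
    """Length selection -> offset estimation -> P-site shifting -> frame QC.

    Writes offsets.tsv, periodicity.tsv, frame_usage.tsv, TIS profile
    matrices and a P-site track under ``outdir``.  Raises
    :class:`PipelineError` when no read length passes the periodicity
    filter.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    if len(reads) == 0:
        raise PipelineError("length-selection: input library is empty")
    results = select_lengths(reads, annotation, fraction=fraction, min_reads=min_reads)
    passing = [r.read_length for r in results if r.passes]
    per_df = pd.DataFrame(
        [
            {"length": r.read_length, "n_reads": r.n_reads,
             "dominant_period": r.dominant_period, "passes": r.passes}
            for r in results
        ]
    )
    _write_tsv(per_df, out / "periodicity.tsv")
    if not passing:
        raise PipelineError("length-selection: no read length shows triplet periodicity")

    offsets = estimate_offsets(reads, annotation, passing)
    off_df = pd.DataFrame(
        [{"length": L, "offset": offsets.offsets[L]} for L in sorted(offsets.offsets)]
    )
    _write_tsv(off_df, out / "offsets.tsv")
    tis_mat = pd.DataFrame(
        {L: offsets.profiles[L].values for L in sorted(offsets.profiles)},
        index=offsets.profiles[passing[0]].positions,
    ).T
    tis_mat.index.name = "length"
    _write_tsv(tis_mat, out / "tis_profiles.tsv", index=True)

    psites = psites_by_length(reads, offsets, annotation)
    usage = frame_usage(psites, annotation, by_length=True)
    _write_tsv(usage, out / "frame_usage.tsv")
    if track_format == "crt":
        rio.write_collapsed(psites, out / "psites.crt")
    elif track_format == "wig":
        rio.write_wig(psites, out / "psites")
    _write_log(out, "calibration_log.json", {
        "stage": "calibration", "fraction": fraction, "min_reads": min_reads,
        "passing_lengths": passing, "offsets": offsets.offsets,
    })
    return {"passing_lengths": passing, "offsets": offsets, "psites": psites, "frame_usage": usage}


def run_uorf_pipeline(
    libs: LibrarySet,
    annotation: Annotation,
    genome,
    outdir: str,
    starts: Sequence[str] = ("ATG",),
    window_up: int = 1000,
    window_down: int = 500,
    min_count: float = 1,
    n_negatives: Optional[int] = None,
    seed: int = 0,
) -> Dict[str, object]:
    """CAGE reannotation -> uORF candidates -> features -> training sets.

    Without a CAGE library the reannotation step is skipped with a warning
    flag in the log.  Writes reannotated.gtf, tss_shifts.tsv, uorfs.bed,
    features.tsv and training.tsv; reruns over the same inputs are
    byte-identical.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    reannotated = annotation
    if libs.cage is not None:
        reannotated, report = reassign_tss(
            annotation, libs.cage, window_up=window_up, window_down=window_down, min_count=min_count
        )
        _write_tsv(report, out / "tss_shifts.tsv")
    rio.write_gtf(reannotated, out / "reannotated.gtf")

    uorfs, skipped = uorf_candidates(reannotated, genome, starts=starts)
    rio.write_bed12(uorfs, out / "uorfs.bed", color_by="frame")
    cdss = cds_records(reannotated, genome)
    lengths = [c.width for c in cdss]
    negs = negative_regions(reannotated, genome, lengths, n=n_negatives or len(cdss), seed=seed)
    all_records = list(uorfs) + list(cdss) + list(negs)
    feats = compute_features(all_records, libs, reannotated, genome)
    _write_tsv(feats, out / "features.tsv")
    training = training_sets(reannotated, libs, genome, n_negatives=n_negatives, seed=seed)
    _write_tsv(training, out / "training.tsv")
    _write_log(out, "uorf_log.json", {
        "stage": "uorf", "starts": list(starts), "window_up": window_up,
        "window_down": window_down, "min_count": min_count, "seed": seed,
        "cage_reannotation": libs.cage is not None,
        "n_uorfs": len(uorfs), "n_cds": len(cdss), "n_negatives": len(negs),
        "skipped_no_leader": skipped,
    })
    return {
        "annotation": reannotated,
        "uorfs": uorfs,
        "features": feats,
        "training": training,
    }
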