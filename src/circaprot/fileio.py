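"""Readers and writers for the pipeline's on-disk formats.

Sequences travel as FASTA (wrapped lines, mixed case tolerated), transcript
models as a GFF3 subset (one feature line per transcript), tabular results as
TSV with headers, the sampling design as YAML, and every pipeline run emits a
JSON manifest recording the seed, a hash of the configuration, and the files
written — enough to reproduce a run byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .proteogenomics import GenomeSet, Transcript
from .simulate import Course, TimeCourseDesign

log = logging.getLogger(__name__)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Parse a FASTA file to {id: uppercase sequence}.

    Tolerates wrapped lines and mixed case; a malformed file (content before
    the first header) raises with the offending line number; an empty file
    returns an empty map with a warning.
    """
    path = Path(path)
    with open(path) as fh:
        seen_header = False
        for i, line in enumerate(fh, start=1):
            s = line.strip()
            if not s:
                continue
            if s.startswith(">"):
                seen_header = True
            elif not seen_header:
                raise ValueError(f"{path}: malformed FASTA at line {i}: "
                                 "sequence data before any '>' header")
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(path, "fasta")}
    if not records:
        log.warning("read_fasta: %s contains no records", path)
    return records


def write_fasta(seqs: dict[str, str], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(recs, path, "fasta")
    return path


def write_tsv(df, path: str | Path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path


def read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def write_gff3(transcripts: list[Transcript], path: str | Path,
               scaffold_lengths: dict[str, int] | None = None) -> Path:
    """Write transcript models as GFF3 (1-based inclusive coordinates)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for sid, ln in (scaffold_lengths or {}).items():
            fh.write(f"##sequence-region {sid} 1 {ln}\n")
        for t in transcripts:
            fh.write("\t".join([
                t.scaffold_id, "circaprot", "transcript", str(t.start + 1),
                str(t.end), ".", t.strand, str(t.frame), f"ID={t.transcript_id}",
            ]) + "\n")
    return path


def read_gff3(path: str | Path) -> list[Transcript]:
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}: malformed GFF3 at line {i}")
            sid, _, _, start, end, _, strand, frame, attrs = parts
            tid = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv).get("ID", f"t{i}")
            out.append(Transcript(tid, sid, int(start) - 1, int(end), strand,
                                  int(frame) if frame != "." else 0))
    return out


def write_genome(genome: GenomeSet, outdir: str | Path, prefix: str = "genome") -> list[Path]:
    outdir = Path(outdir)
    paths = [write_fasta(genome.scaffolds, outdir / f"{prefix}_scaffolds.fasta"),
             write_gff3(genome.transcripts, outdir / f"{prefix}_transcripts.gff3",
                        {sid: len(s) for sid, s in genome.scaffolds.items()})]
    if genome.truth_labels:
        truth = pd.DataFrame(sorted(genome.truth_labels.items()),
                             columns=["peptide_sequence", "truth_class"])
        paths.append(write_tsv(truth, outdir / f"{prefix}_truth.tsv", index=False))
    return paths


def design_to_yaml(design: TimeCourseDesign, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "sampling_interval_h": design.sampling_interval_h,
        "lights_on_zt": design.lights_on_zt,
        "lights_off_zt": design.lights_off_zt,
        "pool_size": design.pool_size,
        "courses": [{"course_id": c.course_id, "start_zt": c.start_zt,
                     "duration_h": c.duration_h} for c in design.courses],
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=True))
    return path


def design_from_yaml(path: str | Path) -> TimeCourseDesign:
    doc = yaml.safe_load(Path(path).read_text())
    courses = [Course(c["course_id"], float(c["start_zt"]), float(c["duration_h"]))
               for c in doc["courses"]]
    return TimeCourseDesign(courses, float(doc["sampling_interval_h"]),
                            float(doc["lights_on_zt"]), float(doc["lights_off_zt"]),
                            int(doc["pool_size"]))


def config_hash(config_doc: dict) -> str:
    return hashlib.sha256(
        json.dumps(config_doc, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_manifest(outdir: str | Path, config_doc: dict, seed: int,
                   files: list[Path]) -> Path:
    import circaprot
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "circaprot",
        "version": circaprot.__version__,
        "seed": seed,
        "config_sha256": config_hash(config_doc),
        "config": config_doc,
        "files": sorted(str(Path(f).relative_to(outdir)) for f in files),
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return path
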