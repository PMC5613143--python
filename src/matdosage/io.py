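"""Fixture readers and writers.

On-disk formats: FASTA for transcript sequences (RNA alphabet; ``T`` is
converted to ``U`` on input), a tab-separated annotation table
(transcript_id, gene_id, cds_start, stop_start, plus contig/strand/
genomic_offset so single-exon gene models round-trip), a tab-separated
log2 expression matrix whose sample columns are encoded
``stage_genotype_rep`` (with optional trailing truth-label columns),
and BED6 for peaks (handled in :mod:`matdosage.metagene`).
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    ExpressionStudy,
    GeneModel,
    PeakInterval,
    SimulatedCohort,
    TranscriptRecord,
)

_SAMPLE_RE = re.compile(r"^(GV|MII)_(CTL|mCKO)_(\d+)$")
_TRUTH_COLUMNS = ("maturation_class", "is_ko_target")

FIXTURE_FILES = {
    "fasta": "transcripts.fasta",
    "annotation": "annotation.tsv",
    "expression": "expression.tsv",
    "peaks": "peaks.bed",
}


def write_fasta(records: list[TranscriptRecord], path) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.transcript_id,
                  description=f"gene={r.gene_id}")
        for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    """Read sequences keyed by id; uppercased with T converted to U."""
    return {
        rec.id: str(rec.seq).upper().replace("T", "U")
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_annotation(
    records: list[TranscriptRecord], models: list[GeneModel], path
) -> None:
    by_gene = {m.gene_id: m for m in models}
    rows = []
    for r in records:
        m = by_gene[r.gene_id]
        rows.append(
            {
                "transcript_id": r.transcript_id,
                "gene_id": r.gene_id,
                "cds_start": r.cds_start,
                "stop_start": r.stop_start,
                "contig": m.contig,
                "strand": m.strand,
                "genomic_offset": m.exons[0][0],
            }
        )
    pd.DataFrame(
        rows,
        columns=["transcript_id", "gene_id", "cds_start", "stop_start",
                 "contig", "strand", "genomic_offset"],
    ).to_csv(path, sep="\t", index=False)


def read_annotation(
    path, sequences: dict[str, str]
) -> tuple[list[TranscriptRecord], list[GeneModel]]:
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "gene_id", "cds_start", "stop_start"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table lacks columns {sorted(missing)}")
    records, models = [], []
    for row in df.itertuples(index=False):
        if row.transcript_id not in sequences:
            raise ValueError(f"no sequence for transcript {row.transcript_id}")
        rec = TranscriptRecord(
            transcript_id=row.transcript_id,
            gene_id=row.gene_id,
            sequence=sequences[row.transcript_id],
            cds_start=int(row.cds_start),
            stop_start=int(row.stop_start),
        )
        records.append(rec)
        if {"contig", "strand", "genomic_offset"} <= set(df.columns):
            off = int(row.genomic_offset)
            models.append(
                GeneModel(
                    gene_id=row.gene_id,
                    contig=row.contig,
                    strand=row.strand,
                    exons=[(off, off + rec.length)],
                    start_codon_pos=off + rec.cds_start,
                    stop_codon_pos=off + rec.stop_start,
                )
            )
    return records, models


def write_expression(study: ExpressionStudy, path) -> None:
    out = study.matrix.copy()
    if study.truth is not None:
        for col in _TRUTH_COLUMNS:
            out[col] = study.truth[col]
    out.to_csv(path, sep="\t", index=True)


def read_expression(path) -> ExpressionStudy:
    df = pd.read_csv(path, sep="\t", index_col=0)
    sample_cols = [c for c in df.columns if _SAMPLE_RE.match(c)]
    if not sample_cols:
        raise ValueError(
            "no sample columns of the form stage_genotype_rep found in "
            f"{path}"
        )
    meta = []
    for c in sample_cols:
        stage, genotype, rep = _SAMPLE_RE.match(c).groups()
        meta.append({"stage": stage, "genotype": genotype, "replicate": int(rep)})
    samples = pd.DataFrame(meta, index=pd.Index(sample_cols, name="sample_id"))
    truth = None
    if set(_TRUTH_COLUMNS) <= set(df.columns):
        truth = df[list(_TRUTH_COLUMNS)].copy()
        truth["is_ko_target"] = truth["is_ko_target"].astype(bool)
    study = ExpressionStudy(
        matrix=df[sample_cols].astype(float), samples=samples, truth=truth
    )
    study.validate()
    return study


def write_fixture(
    study: ExpressionStudy,
    transcripts: list[TranscriptRecord],
    models: list[GeneModel],
    peaks: list[PeakInterval],
    out_dir,
    force: bool = False,
) -> dict[str, Path]:
    """Write the four-file fixture; refuses to overwrite unless ``force``."""
    from .metagene import write_peaks_bed

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {k: out_dir / v for k, v in FIXTURE_FILES.items()}
    existing = [p for p in manifest.values() if p.exists()]
    if existing and not force:
        raise FileExistsError(
            f"fixture files already present (pass force=True): "
            f"{[str(p) for p in existing]}"
        )
    write_fasta(transcripts, manifest["fasta"])
    write_annotation(transcripts, models, manifest["annotation"])
    write_expression(study, manifest["expression"])
    write_peaks_bed(peaks, manifest["peaks"])
    return manifest


def read_fixture(out_dir) -> SimulatedCohort:
    from .metagene import read_peaks_bed

    out_dir = Path(out_dir)
    sequences = read_fasta(out_dir / FIXTURE_FILES["fasta"])
    records, models = read_annotation(out_dir / FIXTURE_FILES["annotation"], sequences)
    study = read_expression(out_dir / FIXTURE_FILES["expression"])
    peaks = read_peaks_bed(out_dir / FIXTURE_FILES["peaks"])
    return SimulatedCohort(
        transcripts=records, models=models, study=study, peaks=peaks, planted={}
    )
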