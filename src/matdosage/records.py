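"""Core record types shared across the analysis stages.

Coordinate conventions used throughout the package:

* all coordinates are 0-based, half-open;
* ``cds_start`` / ``stop_start`` are transcript offsets of the *first*
  nucleotide of the start and stop codon respectively;
* genomic codon positions on a :class:`GeneModel` refer to the lowest
  genomic base of the codon (GTF-style), with strand handled explicitly
  by consumers;
* RNA alphabet (``U`` not ``T``) is canonical in memory; readers convert.
"""

from __future__ import annotations

from dataclasses import dataclass, field

STOP_CODONS = ("UAA", "UAG", "UGA")


@dataclass
class TranscriptRecord:
    """One transcript sequence with codon anchors."""

    transcript_id: str
    gene_id: str
    sequence: str
    cds_start: int
    stop_start: int

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        if not 0 <= self.cds_start < self.stop_start <= self.length - 3:
            raise ValueError(
                f"{self.transcript_id}: codon coordinates out of order "
                f"(cds_start={self.cds_start}, stop_start={self.stop_start}, "
                f"length={self.length})"
            )
        bad = set(self.sequence) - set("ACGUN")
        if bad:
            raise ValueError(
                f"{self.transcript_id}: non-RNA characters {sorted(bad)!r}"
            )


@dataclass
class GeneModel:
    """Genomic gene model; synthetic genes are single-exon on own contigs."""

    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    start_codon_pos: int
    stop_codon_pos: int

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty exon [{s}, {e})")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted")
            prev_end = e
        for name, pos in (("start_codon", self.start_codon_pos),
                          ("stop_codon", self.stop_codon_pos)):
            if not any(s <= pos < e for s, e in self.exons):
                raise ValueError(f"{self.gene_id}: {name} at {pos} outside exons")


@dataclass
class PeakInterval:
    """A scored peak interval (BED-style, 0-based half-open)."""

    contig: str
    start: int
    end: int
    score: float
    sample_id: str = "."

    def validate(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"peak on {self.contig}: start {self.start} >= end {self.end}"
            )


@dataclass
class ExpressionStudy:
    """Log2 expression matrix with sample metadata and optional truth labels.

    ``matrix`` is genes x samples (pandas DataFrame, index gene_id, columns
    sample ids encoded ``stage_genotype_rep``). ``samples`` is a DataFrame
    indexed by sample id with columns stage / genotype / replicate.
    ``truth``, when present, is indexed by gene_id with columns
    ``maturation_class`` and ``is_ko_target``.
    """

    matrix: "pandas.DataFrame"  # noqa: F821 - forward ref avoids hard import
    samples: "pandas.DataFrame"  # noqa: F821
    truth: "pandas.DataFrame | None" = None  # noqa: F821

    def validate(self) -> None:
        import numpy as np

        if list(self.matrix.columns) != list(self.samples.index):
            raise ValueError("matrix columns do not match sample metadata index")
        if not np.isfinite(self.matrix.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.truth is not None and not self.truth.index.equals(self.matrix.index):
            raise ValueError("truth index does not match matrix index")

    def columns_for(self, stage: str, genotype: str) -> list[str]:
        m = (self.samples["stage"] == stage) & (self.samples["genotype"] == genotype)
        return list(self.samples.index[m])

    def submatrix(self, stage: str, genotype: str):
        return self.matrix[self.columns_for(stage, genotype)]


@dataclass
class SimulatedCohort:
    """Bundle returned by the one-call synthetic cohort builder."""

    transcripts: list[TranscriptRecord]
    models: list[GeneModel]
    study: ExpressionStudy
    peaks: list[PeakInterval]
    planted: dict[str, list[int]] = field(default_factory=dict)
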