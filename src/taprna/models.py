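"""Core genomic value types shared across the pipeline.

All coordinates are 0-based half-open on the forward strand of a named
chromosome. Format-specific conventions (1-based GTF, MAF-style mutation
positions) are converted at the I/O boundary and never leak inward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

STRANDS = ("+", "-", ".")
DNA_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(DNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Interval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "Interval") -> bool:
        """>= 1 bp intersection, strand-agnostic."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to_point(self, pos: int) -> int:
        """bp distance from a point to this interval; 0 if inside."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - self.end + 1
        return 0


@dataclass(frozen=True)
class Loop:
    """A chromatin loop: two ordered, non-overlapping anchors on one chromosome."""

    anchor_a: Interval
    anchor_b: Interval
    score: float | None = None
    loop_id: str | None = None

    def __post_init__(self):
        if self.anchor_a.chrom != self.anchor_b.chrom:
            raise ValueError("loop anchors must share a chromosome")
        if self.anchor_a.end > self.anchor_b.start:
            raise ValueError("loop anchors must be ordered and non-overlapping")

    @property
    def chrom(self) -> str:
        return self.anchor_a.chrom


@dataclass(frozen=True)
class MutationRecord:
    """A somatic single-nucleotide variant (internal 0-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    cancer_type: str
    sample_id: str

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.ref not in "ACGT" or self.alt not in "ACGT":
            raise ValueError(f"invalid alleles {self.ref}>{self.alt}")


BASE_ORDER = "ACGT"


@dataclass
class Pwm:
    """A position probability matrix, rows A/C/G/T, columns summing to 1."""

    motif_id: str
    matrix: np.ndarray  # shape (4, L)
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.shape[1] < 1:
            raise ValueError("PWM must be 4 x L with L >= 1")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def reverse_complement(self) -> "Pwm":
        return Pwm(self.motif_id, self.matrix[::-1, ::-1].copy(), self.background)


@dataclass
class TranscriptModel:
    """A stranded, exon-structured transcript; the unit filtered and classified."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    gene_symbol: str | None = None
    source: str = "annotation"  # "annotation" | "assembled"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript strand must be +/- ({self.transcript_id})")
        exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
        self.exons = exons
        self.cds = sorted(self.cds, key=lambda c: c.start)

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, self.strand,
                        name=self.transcript_id)

    @property
    def tss(self) -> int:
        """Transcription start coordinate: span start on +, span end on -.

        On the minus strand the TSS is reported as the half-open end
        coordinate, so promoter windows mirror cleanly.
        """
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    def intron_chain(self) -> tuple:
        """(chrom, strand, intron boundaries) — the merge key for catalogues."""
        introns = tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )
        return (self.chrom, self.strand, introns)

    def spliced_sequence(self, genome: dict[str, str]) -> str:
        """Strand-oriented spliced transcript sequence from a genome dict."""
        seq = "".join(genome[self.chrom][e.start:e.end] for e in self.exons)
        return revcomp(seq) if self.strand == "-" else seq.upper()

    def transcript_to_genome(self, tpos: int) -> int:
        """Genomic coordinate of spliced-transcript position `tpos` (0-based)."""
        if not 0 <= tpos < self.spliced_length:
            raise IndexError(f"transcript position {tpos} out of range")
        if self.strand == "-":
            tpos = self.spliced_length - 1 - tpos
        for exon in self.exons:
            if tpos < exon.length:
                return exon.start + tpos
            tpos -= exon.length
        raise AssertionError("unreachable")


@dataclass
class GeneModel:
    """A gene with its member transcripts and optional cross-species ortholog."""

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    span: Interval
    transcripts: list[str] = field(default_factory=list)
    is_coding: bool = False
    ortholog_id: str | None = None

    @property
    def tss(self) -> int:
        return self.span.start if self.strand == "+" else self.span.end


ORIENTATION_CATEGORIES = ("AS", "BT", "DS-AS", "DS-S", "OLAP", "US-AS", "US-S")

#: Orientation categories on the same strand as the associated gene.
SENSE_CATEGORIES = frozenset({"OLAP", "US-S", "DS-S"})


def category_sense(category: str) -> str:
    """Collapse a seven-way category to sense/antisense relative to the gene."""
    if category not in ORIENTATION_CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    return "S" if category in SENSE_CATEGORIES else "AS"


@dataclass
class PcRNARecord:
    """A positionally conserved lncRNA matched between the two species."""

    human_transcript_id: str
    mouse_transcript_id: str
    human_gene: str
    mouse_gene: str
    category: str
    systematic_name: str
    tss_to_gene_distance: int
    promoter: Interval
    is_taprna: bool = False
    tad_boundary_distance: float | None = None
    is_novel: bool = False

    def with_taprna(self, flag: bool) -> "PcRNARecord":
        return replace(self, is_taprna=flag)


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of a pairwise alignment, with target coordinates when genomic."""

    score: float
    identity: float
    n_aligned_columns: int
    query_start: int = 0
    query_end: int = 0
    target_chrom: str | None = None
    target_start: int = 0
    target_end: int = 0
    target_strand: str = "+"

    @property
    def is_empty(self) -> bool:
        return self.n_aligned_columns == 0
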