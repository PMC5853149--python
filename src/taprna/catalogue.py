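"""Filtered spliced-lncRNA candidate catalogue and promoter intervals.

Candidates must (1) show evidence of splicing (>= ``min_exons`` exons),
(2) not overlap any coding exon (CDS) in the same transcriptional
orientation — antisense overlap is allowed, and (3) have no significant
coding potential, scored by default as the longest ATG-initiated open
reading frame across the three forward frames of the spliced sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .config import PipelineConfig
from .models import GeneModel, Interval, TranscriptModel

STOP_CODONS = {"TAA", "TAG", "TGA"}


def filter_spliced(transcripts: Sequence[TranscriptModel],
                   min_exons: int = 2) -> list[TranscriptModel]:
    """Keep transcripts with evidence of splicing (>= min_exons exons)."""
    return [tx for tx in transcripts if tx.n_exons >= min_exons]


def _cds_index(coding_transcripts) -> dict[tuple[str, str], list[Interval]]:
    index: dict[tuple[str, str], list[Interval]] = {}
    for tx in coding_transcripts:
        for iv in tx.cds:
            index.setdefault((tx.chrom, tx.strand), []).append(iv)
    for ivs in index.values():
        ivs.sort(key=lambda iv: iv.start)
    return index


def filter_coding_overlap(candidates: Sequence[TranscriptModel],
                          coding_transcripts: Sequence[TranscriptModel],
                          ) -> list[TranscriptModel]:
    """Drop candidates with any exon overlapping a CDS on the same strand.

    Antisense overlap never removes a candidate; introns spanning a CDS are
    fine — only exonic, same-strand overlap counts.
    """
    index = _cds_index(coding_transcripts)
    kept = []
    for tx in candidates:
        cds_list = index.get((tx.chrom, tx.strand), [])
        hit = any(
            exon.start < cds.end and cds.start < exon.end
            for exon in tx.exons for cds in cds_list
        )
        if not hit:
            kept.append(tx)
    return kept


def coding_potential(transcript_sequence: str) -> int:
    """Longest ATG-initiated ORF, in codons, over the three forward frames.

    The stop codon is excluded from the count; an ORF running off the 3'
    end without a stop still counts its complete codons.
    """
    seq = transcript_sequence.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence contains non-ACGTN symbols")
    best = 0
    n = len(seq)
    for frame in range(3):
        pos = frame
        while pos + 3 <= n:
            if seq[pos:pos + 3] == "ATG":
                codons = 0
                q = pos
                while q + 3 <= n and seq[q:q + 3] not in STOP_CODONS:
                    codons += 1
                    q += 3
                best = max(best, codons)
                pos = q + 3  # longer ORFs in this frame cannot start inside
            else:
                pos += 3
    return best


def promoter_of(transcript: TranscriptModel, upstream: int = 1000,
                downstream: int = 500,
                chrom_length: int | None = None) -> Interval:
    """Promoter window around the TSS, strand-mirrored, clipped at bounds."""
    tss = transcript.tss
    if transcript.strand == "+":
        start, end = tss - upstream, tss + downstream
    else:
        start, end = tss - downstream, tss + upstream
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return Interval(transcript.chrom, start, end, transcript.strand,
                    name=transcript.transcript_id)


def merge_catalogues(annotated: Sequence[TranscriptModel],
                     assembled: Sequence[TranscriptModel],
                     ) -> list[TranscriptModel]:
    """Union of two catalogues keyed by (chrom, strand, intron chain).

    When an assembled transcript shares its intron chain with an annotated
    one the annotated record (and its boundaries) wins; surviving assembled
    transcripts are the catalogue's "novel" fraction.
    """
    merged: dict[tuple, TranscriptModel] = {}
    for tx in annotated:
        merged.setdefault(tx.intron_chain(), tx)
    for tx in assembled:
        merged.setdefault(tx.intron_chain(), tx)
    return sorted(merged.values(),
                  key=lambda t: (t.chrom, t.start, t.transcript_id))


@dataclass
class Catalogue:
    """Outcome of candidate filtering for one species."""

    candidates: list[TranscriptModel]
    coding: list[TranscriptModel]
    promoters: dict[str, Interval]           # transcript_id -> promoter
    orf_codons: dict[str, int] = field(default_factory=dict)


def build_catalogue(transcripts: Iterable[TranscriptModel],
                    genome: dict[str, str],
                    config: PipelineConfig | None = None,
                    coding_scorer: Callable[[str], int] | None = None,
                    ) -> Catalogue:
    """Run the candidate-selection workflow on one species' annotation.

    ``coding_scorer`` may replace the built-in longest-ORF score with an
    external tool's column; it must return a number compared against
    ``config.max_orf_codons``.
    """
    config = config or PipelineConfig()
    scorer = coding_scorer or coding_potential
    transcripts = list(transcripts)
    coding = [tx for tx in transcripts if tx.is_coding]
    noncoding = [tx for tx in transcripts if not tx.is_coding]
    candidates = filter_spliced(noncoding, config.min_exons)
    candidates = filter_coding_overlap(candidates, coding)
    kept, orf_codons = [], {}
    for tx in candidates:
        score = scorer(tx.spliced_sequence(genome))
        orf_codons[tx.transcript_id] = score
        if score < config.max_orf_codons:
            kept.append(tx)
    promoters = {
        tx.transcript_id: promoter_of(
            tx, config.promoter_upstream, config.promoter_downstream,
            chrom_length=len(genome[tx.chrom]))
        for tx in kept
    }
    return Catalogue(kept, coding, promoters, orf_codons)


def genes_from_transcripts(transcripts: Iterable[TranscriptModel],
                           ortholog_map: dict[str, str] | None = None,
                           ) -> dict[str, GeneModel]:
    """Aggregate transcripts into GeneModels; span covers all members."""
    ortholog_map = ortholog_map or {}
    genes: dict[str, GeneModel] = {}
    bounds: dict[str, list[int]] = {}
    for tx in transcripts:
        if tx.gene_id not in genes:
            genes[tx.gene_id] = GeneModel(
                gene_id=tx.gene_id, symbol=tx.gene_symbol or tx.gene_id,
                chrom=tx.chrom, strand=tx.strand,
                span=tx.span, is_coding=tx.is_coding,
                ortholog_id=ortholog_map.get(tx.gene_id),
            )
            bounds[tx.gene_id] = [tx.start, tx.end]
        gene = genes[tx.gene_id]
        gene.transcripts.append(tx.transcript_id)
        gene.is_coding = gene.is_coding or tx.is_coding
        b = bounds[tx.gene_id]
        b[0], b[1] = min(b[0], tx.start), max(b[1], tx.end)
    for gid, gene in genes.items():
        b = bounds[gid]
        gene.span = Interval(gene.chrom, b[0], b[1], gene.strand, name=gid)
    return genes
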