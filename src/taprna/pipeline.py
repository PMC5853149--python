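"""End-to-end orchestration: catalogues -> promoter synteny -> pcRNA calls
-> tapRNA flags.

Each unique promoter interval is aligned to the other genome once and the
hit shared among isoforms, since isoforms with identical promoters are one
conserved promoter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .alignment import AlignmentResult, ScoringScheme, best_genomic_hit
from .catalogue import Catalogue, build_catalogue, genes_from_transcripts
from .config import PipelineConfig
from .models import GeneModel, Interval, Loop, PcRNARecord, TranscriptModel
from .positional import call_pcrnas
from .topology import annotate_tad_distances, call_taprnas


def map_promoters(catalogue: Catalogue, genome_query: dict[str, str],
                  genome_target: dict[str, str],
                  config: PipelineConfig | None = None,
                  ) -> dict[str, AlignmentResult]:
    """Best target-genome hit per candidate promoter.

    Returns {transcript_id: hit} for promoters clearing the synteny
    identity threshold over at least ``synteny_window`` aligned columns.
    """
    config = config or PipelineConfig()
    scoring = ScoringScheme()
    hits: dict[str, AlignmentResult] = {}
    by_interval: dict[tuple, AlignmentResult | None] = {}
    for tx_id, promoter in catalogue.promoters.items():
        key = (promoter.chrom, promoter.start, promoter.end)
        if key not in by_interval:
            seq = genome_query[promoter.chrom][promoter.start:promoter.end]
            by_interval[key] = best_genomic_hit(
                seq, genome_target, scoring,
                min_identity=config.synteny_min_identity,
                min_aligned=min(config.synteny_window, len(seq)))
        hit = by_interval[key]
        if hit is not None:
            hits[tx_id] = hit
    return hits


@dataclass
class PipelineResult:
    records: list[PcRNARecord]
    catalogue_h: Catalogue
    catalogue_m: Catalogue
    genes_h: dict[str, GeneModel]
    genes_m: dict[str, GeneModel]
    synteny_hits: dict[str, AlignmentResult] = field(default_factory=dict)

    @property
    def taprna_records(self) -> list[PcRNARecord]:
        return [r for r in self.records if r.is_taprna]


def run_pipeline(transcripts_h: Sequence[TranscriptModel],
                 transcripts_m: Sequence[TranscriptModel],
                 genome_h: dict[str, str], genome_m: dict[str, str],
                 ortholog_map: Mapping[str, str],
                 config: PipelineConfig | None = None,
                 loops: Iterable[Loop] | None = None,
                 tads: Iterable[Interval] | None = None,
                 synteny_hits: Mapping[str, AlignmentResult] | None = None,
                 ) -> PipelineResult:
    """Full positional-conservation pipeline on in-memory annotations.

    ``synteny_hits`` may supply precomputed promoter hits (genome-scale
    use); otherwise promoters are aligned with the built-in aligner.
    """
    config = config or PipelineConfig()
    cat_h = build_catalogue(transcripts_h, genome_h, config)
    cat_m = build_catalogue(transcripts_m, genome_m, config)
    genes_h = genes_from_transcripts(transcripts_h, ortholog_map)
    reverse = {m: h for h, m in ortholog_map.items()}
    genes_m = genes_from_transcripts(transcripts_m, reverse)
    if synteny_hits is None:
        synteny_hits = map_promoters(cat_h, genome_h, genome_m, config)
    records = call_pcrnas(cat_h, cat_m, genes_h, genes_m, ortholog_map,
                          synteny_hits, config)
    if loops is not None:
        records = call_taprnas(records, loops)
    if tads is not None:
        tss_of = {tx.transcript_id: tx.tss for tx in transcripts_h}
        records = annotate_tad_distances(records, tss_of, tads)
    return PipelineResult(records=records, catalogue_h=cat_h,
                          catalogue_m=cat_m, genes_h=genes_h,
                          genes_m=genes_m, synteny_hits=dict(synteny_hits))
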