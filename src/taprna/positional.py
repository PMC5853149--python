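"""Positionally conserved RNA calling and seven-way orientation
classification.

A lncRNA and its associated coding gene are classified by a fixed decision
order that makes the classifier total and deterministic: span overlap on
opposite strands -> AS; overlap on the same strand -> OLAP; divergent
(head-to-head) TSSs within the bidirectional window -> BT; otherwise the
lncRNA's position in the gene's 5'->3' frame combined with relative strand
gives US-S / US-AS / DS-S / DS-AS.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .config import PipelineConfig
from .models import (
    AlignmentResult,
    GeneModel,
    Interval,
    ORIENTATION_CATEGORIES,
    PcRNARecord,
    TranscriptModel,
    category_sense,
)
from .catalogue import Catalogue


class ClassificationError(ValueError):
    """The (lncRNA, gene) pair violates the pairing preconditions."""


def _spans_overlap(a: Interval, b: Interval) -> bool:
    return a.start < b.end and b.start < a.end


def classify_orientation(lnc: TranscriptModel, gene: GeneModel,
                         config: PipelineConfig | None = None) -> str:
    """Assign one of the seven orientation categories."""
    config = config or PipelineConfig()
    if lnc.chrom != gene.chrom:
        raise ClassificationError("lncRNA and gene on different chromosomes")
    span, gspan = lnc.span, gene.span
    distance = gspan.distance_to_point(lnc.tss)
    if not _spans_overlap(span, gspan) and distance > config.association_window:
        raise ClassificationError("lncRNA beyond the association window")
    same_strand = lnc.strand == gene.strand
    if _spans_overlap(span, gspan):
        return "OLAP" if same_strand else "AS"
    # upstream/downstream in the gene's own 5'->3' frame
    if gene.strand == "+":
        upstream = span.end <= gspan.start
    else:
        upstream = span.start >= gspan.end
    if (not same_strand and upstream
            and abs(lnc.tss - gene.tss) <= config.bidirectional_window):
        return "BT"  # divergent, head-to-head
    if upstream:
        return "US-S" if same_strand else "US-AS"
    return "DS-S" if same_strand else "DS-AS"


def select_associated_gene(lnc: TranscriptModel,
                           coding_genes: Sequence[GeneModel],
                           config: PipelineConfig | None = None,
                           promoter: Interval | None = None,
                           ) -> GeneModel | None:
    """Nearest ortholog-bearing coding gene within the association window.

    Distance is measured from the lncRNA promoter midpoint to the gene span
    (0 if inside). Ties break to the gene with the earlier start.
    """
    config = config or PipelineConfig()
    if promoter is None:
        from .catalogue import promoter_of
        promoter = promoter_of(lnc, config.promoter_upstream,
                               config.promoter_downstream)
    mid = int(promoter.midpoint)
    best, best_key = None, None
    for gene in coding_genes:
        if gene.ortholog_id is None or not gene.is_coding:
            continue
        if gene.chrom != lnc.chrom:
            continue
        dist = gene.span.distance_to_point(mid)
        if dist > config.association_window:
            continue
        key = (dist, gene.span.start, gene.gene_id)
        if best_key is None or key < best_key:
            best, best_key = gene, key
    return best


def assign_name(gene_symbol: str, category: str,
                ordinal: int | None = None) -> str:
    """Systematic name: symbol + category (+ positional ordinal if shared)."""
    if category not in ORIENTATION_CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    name = f"{gene_symbol}-{category}"
    if ordinal is not None:
        name = f"{name}{ordinal}"
    return name


@dataclass
class _Candidate:
    lnc: TranscriptModel
    gene: GeneModel
    mouse_lnc: TranscriptModel
    mouse_gene: GeneModel
    category: str
    promoter: Interval


def _check_ortholog_map(ortholog_map: Mapping[str, str]) -> None:
    if set(ortholog_map) & set(ortholog_map.values()):
        raise ValueError("inconsistent ortholog map (chained A->B->C)")


def call_pcrnas(human_catalogue: Catalogue,
                mouse_catalogue: Catalogue,
                human_genes: Mapping[str, GeneModel],
                mouse_genes: Mapping[str, GeneModel],
                ortholog_map: Mapping[str, str],
                synteny_hits: Mapping[str, AlignmentResult],
                config: PipelineConfig | None = None,
                strict_category_agreement: bool = False,
                ) -> list[PcRNARecord]:
    """Emit one record per human lncRNA isoform that is positionally
    conserved.

    Requires (a) a qualifying mouse hit for the human promoter, (b) that hit
    within the association window of the ortholog of the human associated
    gene, (c) a spliced mouse lncRNA with TSS within promoter-match distance
    of the hit, and (d) cross-species orientation agreement at the
    sense/antisense level (full seven-way agreement when
    ``strict_category_agreement``).
    """
    config = config or PipelineConfig()
    _check_ortholog_map(ortholog_map)
    human_gene_list = list(human_genes.values())
    mouse_lncs = mouse_catalogue.candidates

    candidates: list[_Candidate] = []
    for lnc in human_catalogue.candidates:
        promoter = human_catalogue.promoters[lnc.transcript_id]
        hit = synteny_hits.get(lnc.transcript_id)
        if hit is None:
            continue
        gene = select_associated_gene(lnc, human_gene_list, config,
                                      promoter=promoter)
        if gene is None:
            continue
        mouse_gene_id = ortholog_map.get(gene.gene_id)
        if mouse_gene_id is None or mouse_gene_id not in mouse_genes:
            continue
        mouse_gene = mouse_genes[mouse_gene_id]
        if hit.target_chrom != mouse_gene.chrom:
            continue
        hit_iv = Interval(hit.target_chrom, hit.target_start, hit.target_end)
        if mouse_gene.span.distance_to_point(
                int(hit_iv.midpoint)) > config.association_window:
            continue
        category = classify_orientation(lnc, gene, config)
        # nearest spliced mouse lncRNA whose TSS matches the hit locus
        partner, partner_key = None, None
        for m_lnc in mouse_lncs:
            if m_lnc.chrom != hit.target_chrom:
                continue
            dist = hit_iv.distance_to_point(m_lnc.tss)
            if dist > config.promoter_match_distance:
                continue
            try:
                m_cat = classify_orientation(m_lnc, mouse_gene, config)
            except ClassificationError:
                continue
            if strict_category_agreement:
                if m_cat != category:
                    continue
            elif category_sense(m_cat) != category_sense(category):
                continue
            key = (dist, m_lnc.transcript_id)
            if partner_key is None or key < partner_key:
                partner, partner_key = m_lnc, key
        if partner is None:
            continue
        candidates.append(_Candidate(lnc, gene, partner, mouse_gene,
                                     category, promoter))

    return _finalise_records(candidates)


def _finalise_records(candidates: list[_Candidate]) -> list[PcRNARecord]:
    """Assign systematic names (positional ordinals where needed) and build
    records. Isoforms sharing an identical promoter share one name."""
    promoters_by_name: dict[tuple[str, str], list[tuple]] = defaultdict(list)
    for cand in candidates:
        key = (cand.gene.symbol, cand.category)
        pk = (cand.promoter.chrom, cand.promoter.start, cand.promoter.end,
              cand.promoter.strand)
        if pk not in [p for p, _ in promoters_by_name[key]]:
            promoters_by_name[key].append((pk, cand.promoter.start))
    ordinals: dict[tuple, int | None] = {}
    for key, promoters in promoters_by_name.items():
        promoters.sort(key=lambda item: item[0])
        for i, (pk, _start) in enumerate(promoters, start=1):
            ordinals[key + pk] = i if len(promoters) > 1 else None

    records = []
    for cand in candidates:
        pk = (cand.promoter.chrom, cand.promoter.start, cand.promoter.end,
              cand.promoter.strand)
        ordinal = ordinals[(cand.gene.symbol, cand.category) + pk]
        records.append(PcRNARecord(
            human_transcript_id=cand.lnc.transcript_id,
            mouse_transcript_id=cand.mouse_lnc.transcript_id,
            human_gene=cand.gene.gene_id,
            mouse_gene=cand.mouse_gene.gene_id,
            category=cand.category,
            systematic_name=assign_name(cand.gene.symbol, cand.category,
                                        ordinal),
            tss_to_gene_distance=cand.gene.span.distance_to_point(
                cand.lnc.tss),
            promoter=cand.promoter,
            is_novel=cand.lnc.source == "assembled",
        ))
    records.sort(key=lambda r: (r.promoter.chrom, r.promoter.start,
                                r.human_transcript_id))
    return records


def percentage(count: int, total: int) -> int:
    """Integer percentage as reported in catalogue summaries."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100 * count / total)


def summarize_catalogue(records: Sequence[PcRNARecord],
                        transcripts: Mapping[str, TranscriptModel] | None = None,
                        ) -> pd.DataFrame:
    """Catalogue summary: per-category counts/percentages, novel fraction,
    unique promoters and associated genes, and (when transcript models are
    supplied) mean exon count and spliced length."""
    if not records:
        raise ValueError("no records to summarise")
    total = len(records)
    rows = []
    for cat in ORIENTATION_CATEGORIES:
        n = sum(1 for r in records if r.category == cat)
        rows.append(("category:" + cat, n, percentage(n, total)))
    n_novel = sum(1 for r in records if r.is_novel)
    rows.append(("annotated", total - n_novel, percentage(total - n_novel,
                                                          total)))
    rows.append(("novel", n_novel, percentage(n_novel, total)))
    n_topo = sum(1 for r in records
                 if r.is_taprna or (r.tad_boundary_distance is not None
                                    and r.tad_boundary_distance <= 10_000))
    rows.append(("near_boundary_or_anchor", n_topo, percentage(n_topo, total)))
    unique_promoters = len({(r.promoter.chrom, r.promoter.start,
                             r.promoter.end, r.promoter.strand)
                            for r in records})
    unique_genes = len({r.human_gene for r in records})
    rows.append(("unique_promoters", unique_promoters, None))
    rows.append(("unique_associated_genes", unique_genes, None))
    rows.append(("total_transcripts", total, None))
    if transcripts:
        lncs = [transcripts[r.human_transcript_id] for r in records
                if r.human_transcript_id in transcripts]
        if lncs:
            mean_exons = sum(t.n_exons for t in lncs) / len(lncs)
            mean_len = sum(t.spliced_length for t in lncs) / len(lncs)
            rows.append(("mean_exons", round(mean_exons, 2), None))
            rows.append(("mean_spliced_length", round(mean_len, 1), None))
    return pd.DataFrame(rows, columns=["metric", "count", "percent"])
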