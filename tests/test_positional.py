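"""Orientation classification, gene association, naming and catalogue
summaries."""

import pytest

from taprna.catalogue import Catalogue, promoter_of
from taprna.config import PipelineConfig
from taprna.models import (
    AlignmentResult,
    GeneModel,
    Interval,
    ORIENTATION_CATEGORIES,
    PcRNARecord,
    TranscriptModel,
)
from taprna.positional import (
    ClassificationError,
    assign_name,
    call_pcrnas,
    classify_orientation,
    percentage,
    select_associated_gene,
    summarize_catalogue,
)


def lnc(tid, chrom, strand, exons, gene_id=None):
    return TranscriptModel(
        transcript_id=tid, gene_id=gene_id or f"g_{tid}", chrom=chrom,
        strand=strand,
        exons=[Interval(chrom, a, b, strand) for a, b in exons])


def gene(gid, chrom, strand, start, end, ortholog="M1", symbol=None):
    return GeneModel(gene_id=gid, symbol=symbol or gid, chrom=chrom,
                     strand=strand,
                     span=Interval(chrom, start, end, strand),
                     is_coding=True, ortholog_id=ortholog)


G = gene("FOXA2", "chr1", "+", 100_000, 110_000)


class TestClassifyOrientation:
    @pytest.mark.parametrize("exons,strand,expected", [
        # downstream, same strand
        ([(115_000, 115_500), (116_000, 116_500)], "+", "DS-S"),
        # body overlap, opposite strand
        ([(102_000, 102_500), (104_000, 104_500)], "-", "AS"),
        # divergent, 300 bp upstream, opposite strands
        ([(97_500, 98_000), (99_200, 99_700)], "-", "BT"),
        # 5 kb upstream, same strand
        ([(93_000, 93_500), (94_500, 95_000)], "+", "US-S"),
        # body overlap, same strand
        ([(102_000, 102_500), (104_000, 104_500)], "+", "OLAP"),
        # upstream, opposite strand, beyond the bidirectional window
        ([(93_000, 93_500), (94_500, 95_000)], "-", "US-AS"),
        # downstream, opposite strand
        ([(115_000, 115_500), (116_000, 116_500)], "-", "DS-AS"),
    ])
    def test_seven_categories(self, exons, strand, expected):
        assert classify_orientation(lnc("x", "chr1", strand, exons), G) \
            == expected

    def test_minus_strand_gene_mirrors(self):
        g = gene("HNF6", "chr1", "-", 100_000, 110_000)
        # 5' of a minus-strand gene = higher coordinates
        us = lnc("u", "chr1", "-", [(115_000, 115_500), (116_000, 116_500)])
        assert classify_orientation(us, g) == "US-S"
        bt = lnc("b", "chr1", "+", [(110_300, 110_800), (111_500, 112_000)])
        assert classify_orientation(bt, g) == "BT"

    def test_convergent_close_pair_is_not_bt(self):
        # opposite strand, downstream, TSS near the gene TES
        g = gene("X", "chr1", "+", 100_000, 110_000)
        conv = lnc("c", "chr1", "-",
                   [(110_200, 110_700), (111_200, 111_700)])
        assert classify_orientation(conv, g) == "DS-AS"

    def test_different_chromosome_raises(self):
        with pytest.raises(ClassificationError):
            classify_orientation(
                lnc("x", "chr2", "+", [(0, 100), (200, 300)]), G)

    def test_beyond_association_window_raises(self):
        far = lnc("f", "chr1", "+", [(400_000, 400_100), (401_000, 401_100)])
        with pytest.raises(ClassificationError):
            classify_orientation(far, G)

    def test_partition_is_total_within_window(self, rng):
        """Every in-window pair maps to exactly one of the seven."""
        for _ in range(200):
            s = int(rng.integers(60_000, 140_000))
            strand = "+" if rng.random() < 0.5 else "-"
            t = lnc("r", "chr1", strand, [(s, s + 400), (s + 800, s + 1300)])
            assert classify_orientation(t, G) in ORIENTATION_CATEGORIES

    def test_strand_mirror_symmetry(self, rng):
        """Reflecting all coordinates and flipping all strands preserves
        every category."""
        L = 1_000_000

        def mirror_tx(t):
            flip = {"+": "-", "-": "+"}
            return lnc(t.transcript_id, t.chrom, flip[t.strand],
                       sorted((L - e.end, L - e.start) for e in t.exons))

        def mirror_gene(g):
            flip = {"+": "-", "-": "+"}
            return gene(g.gene_id, g.chrom, flip[g.strand],
                        L - g.span.end, L - g.span.start)

        for _ in range(200):
            s = int(rng.integers(60_000, 140_000))
            strand = "+" if rng.random() < 0.5 else "-"
            t = lnc("r", "chr1", strand, [(s, s + 400), (s + 800, s + 1300)])
            assert classify_orientation(t, G) == \
                classify_orientation(mirror_tx(t), mirror_gene(G))


class TestSelectAssociatedGene:
    def test_promoter_inside_gene(self):
        t = lnc("x", "chr1", "+", [(104_000, 104_500), (105_000, 105_500)])
        assert select_associated_gene(t, [G]).gene_id == "FOXA2"

    def test_equidistant_tie_breaks_to_earlier_start(self):
        # promoter [99250, 100750) has midpoint 100000; both genes sit
        # exactly 5000 bp away under half-open distance
        g1 = gene("g1", "chr1", "+", 90_000, 95_001)
        g2 = gene("g2", "chr1", "+", 105_000, 110_000, ortholog="M2")
        t = lnc("x", "chr1", "+", [(100_250, 100_500), (100_600, 100_750)])
        chosen = select_associated_gene(t, [g2, g1])
        assert chosen.gene_id == "g1"  # tie -> earlier start

    def test_genes_without_ortholog_skipped(self):
        g = gene("no_orth", "chr1", "+", 100_000, 110_000, ortholog=None)
        t = lnc("x", "chr1", "+", [(104_000, 104_500), (105_000, 105_500)])
        assert select_associated_gene(t, [g]) is None

    def test_matches_brute_force_scan(self, rng):
        config = PipelineConfig()
        genes = []
        for i in range(20):
            s = int(rng.integers(0, 900_000))
            orth = f"M{i}" if i < 12 else None
            genes.append(gene(f"g{i}", "chr1", "+", s, s + 5000,
                              ortholog=orth))
        for j in range(15):
            s = int(rng.integers(0, 900_000))
            t = lnc(f"l{j}", "chr1", "+", [(s, s + 300), (s + 600, s + 900)])
            prom = promoter_of(t, config.promoter_upstream,
                               config.promoter_downstream)
            mid = int(prom.midpoint)
            qualifying = [
                (g.span.distance_to_point(mid), g.span.start, g.gene_id)
                for g in genes if g.ortholog_id is not None
                and g.span.distance_to_point(mid) <= config.association_window
            ]
            expected = min(qualifying)[2] if qualifying else None
            got = select_associated_gene(t, genes, config)
            assert (got.gene_id if got else None) == expected


class TestAssignName:
    @pytest.mark.parametrize("symbol,category,ordinal,expected", [
        ("FOXA2", "DS-S", None, "FOXA2-DS-S"),
        ("HNF1A", "BT", 1, "HNF1A-BT1"),
        ("HOXA13", "BT", None, "HOXA13-BT"),
    ])
    def test_examples(self, symbol, category, ordinal, expected):
        assert assign_name(symbol, category, ordinal) == expected

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            assign_name("X", "SIDEWAYS")


def _mini_catalogues():
    """Hand-built two-species fixture exercising call_pcrnas conditions."""
    config = PipelineConfig()
    h_gene_tx = lnc("hg.t", "chr1", "+", [(100_000, 100_300),
                                          (101_000, 110_000)], gene_id="HG1")
    h_lnc = lnc("hl", "chr1", "+", [(115_000, 115_500), (116_000, 116_500)],
                gene_id="HLG")
    m_gene_tx = lnc("mg.t", "chr1", "+", [(100_000, 100_300),
                                          (101_000, 110_000)], gene_id="MG1")
    m_lnc = lnc("ml", "chr1", "+", [(115_000, 115_500), (116_000, 116_500)],
                gene_id="MLG")
    genes_h = {"HG1": gene("HG1", "chr1", "+", 100_000, 110_000,
                           ortholog="MG1", symbol="FOXA2")}
    genes_m = {"MG1": gene("MG1", "chr1", "+", 100_000, 110_000,
                           ortholog="HG1", symbol="FOXA2")}
    prom_h = {h_lnc.transcript_id: promoter_of(h_lnc, 1000, 500)}
    prom_m = {m_lnc.transcript_id: promoter_of(m_lnc, 1000, 500)}
    cat_h = Catalogue([h_lnc], [h_gene_tx], prom_h)
    cat_m = Catalogue([m_lnc], [m_gene_tx], prom_m)
    hits = {"hl": AlignmentResult(score=900, identity=0.95,
                                  n_aligned_columns=1400, target_chrom="chr1",
                                  target_start=114_000, target_end=115_500)}
    return config, cat_h, cat_m, genes_h, genes_m, hits


class TestCallPcrnas:
    def test_conserved_pair_emitted(self):
        config, cat_h, cat_m, gh, gm, hits = _mini_catalogues()
        records = call_pcrnas(cat_h, cat_m, gh, gm, {"HG1": "MG1"}, hits,
                              config)
        assert len(records) == 1
        rec = records[0]
        assert rec.category == "DS-S"
        assert rec.systematic_name == "FOXA2-DS-S"
        assert rec.mouse_transcript_id == "ml"

    def test_monoexonic_mouse_partner_gives_no_record(self):
        config, cat_h, cat_m, gh, gm, hits = _mini_catalogues()
        cat_m.candidates[:] = []  # mouse catalogue already filters splicing
        assert call_pcrnas(cat_h, cat_m, gh, gm, {"HG1": "MG1"}, hits,
                           config) == []

    def test_sense_antisense_disagreement_gives_no_record(self):
        config, cat_h, cat_m, gh, gm, hits = _mini_catalogues()
        flipped = lnc("ml", "chr1", "-",
                      [(115_000, 115_500), (116_000, 116_500)], gene_id="MLG")
        cat_m.candidates[:] = [flipped]
        cat_m.promoters["ml"] = promoter_of(flipped, 1000, 500)
        assert call_pcrnas(cat_h, cat_m, gh, gm, {"HG1": "MG1"}, hits,
                           config) == []

    def test_no_synteny_hit_gives_no_record(self):
        config, cat_h, cat_m, gh, gm, _hits = _mini_catalogues()
        assert call_pcrnas(cat_h, cat_m, gh, gm, {"HG1": "MG1"}, {},
                           config) == []

    def test_inconsistent_ortholog_map_raises(self):
        config, cat_h, cat_m, gh, gm, hits = _mini_catalogues()
        with pytest.raises(ValueError):
            call_pcrnas(cat_h, cat_m, gh, gm, {"A": "B", "B": "C"}, hits,
                        config)


def _record(i, category="BT", novel=False, topo=False):
    return PcRNARecord(
        human_transcript_id=f"t{i}", mouse_transcript_id=f"m{i}",
        human_gene=f"g{i % 7}", mouse_gene=f"mg{i % 7}", category=category,
        systematic_name=f"S{i}-{category}", tss_to_gene_distance=100,
        promoter=Interval("chr1", 1000 * i + 10, 1000 * i + 1510, "+"),
        is_taprna=topo, is_novel=novel)


class TestSummarize:
    def test_percentage_rounding(self):
        assert percentage(1401, 1700) == 82
        assert percentage(299, 1700) == 18
        assert percentage(912, 1700) == 54

    def test_summary_counts(self):
        records = [_record(i, novel=(i < 3), topo=(i < 5))
                   for i in range(10)]
        table = summarize_catalogue(records).set_index("metric")
        assert table.loc["novel", "count"] == 3
        assert table.loc["novel", "percent"] == 30
        assert table.loc["near_boundary_or_anchor", "count"] == 5
        assert table.loc["unique_promoters", "count"] == 10
        assert table.loc["unique_associated_genes", "count"] == 7

    def test_isoforms_sharing_promoter_collapse(self):
        records = [_record(1), _record(1)]
        table = summarize_catalogue(records).set_index("metric")
        assert table.loc["unique_promoters", "count"] == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_catalogue([])
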