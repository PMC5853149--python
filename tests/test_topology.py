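"""tapRNA calling, TAD distances, overlap enrichment, profiles,
co-occupancy, distal-anchor states and the KS comparison."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from taprna.models import Interval, Loop, PcRNARecord, TranscriptModel
from taprna.topology import (
    ContactAnnotation,
    OccupancyMatrix,
    call_taprnas,
    contact_ecdf_compare,
    cooccupancy_correlation,
    distal_anchor_states,
    distance_to_nearest,
    enhancer_fraction,
    hypergeom_upper_tail,
    meta_locus_profile,
    occupancy_matrix,
    overlap_enrichment,
    tad_boundary_distance,
    tss_aggregation_profile,
)

import oracles


def record(i, prom_start, prom_end, chrom="chr1", taprna=False):
    return PcRNARecord(
        human_transcript_id=f"t{i}", mouse_transcript_id=f"m{i}",
        human_gene=f"g{i}", mouse_gene=f"mg{i}", category="BT",
        systematic_name=f"S{i}-BT", tss_to_gene_distance=0,
        promoter=Interval(chrom, prom_start, prom_end, "+"),
        is_taprna=taprna)


def loop(chrom, a1, a2, b1, b2, lid=None):
    return Loop(Interval(chrom, a1, a2), Interval(chrom, b1, b2),
                loop_id=lid)


class TestCallTaprnas:
    def test_one_bp_overlap_counts(self):
        recs = call_taprnas([record(0, 100, 600)],
                            [loop("chr1", 599, 800, 5000, 5100)])
        assert recs[0].is_taprna

    def test_touching_does_not_count(self):
        recs = call_taprnas([record(0, 100, 600)],
                            [loop("chr1", 600, 800, 5000, 5100)])
        assert not recs[0].is_taprna

    def test_planted_subset_recovered(self, rng):
        records, loops = [], []
        for i in range(30):
            s = i * 10_000
            records.append(record(i, s, s + 1500))
            if i < 12:
                loops.append(loop("chr1", s + 1000, s + 2000,
                                  s + 500_000, s + 501_000))
        out = call_taprnas(records, loops)
        assert {r.human_transcript_id for r in out if r.is_taprna} == \
            {f"t{i}" for i in range(12)}

    def test_idempotent_and_anchor_order_invariant(self):
        records = [record(0, 100, 600), record(1, 9000, 9500)]
        loops = [loop("chr1", 200, 300, 5000, 5100)]
        once = call_taprnas(records, loops)
        assert call_taprnas(once, loops) == once
        # anchors swapped at read time are canonicalised; the distal anchor
        # matching still flags the same set
        swapped = [Loop(l.anchor_a, l.anchor_b) for l in loops]
        assert [r.is_taprna for r in call_taprnas(records, swapped)] == \
            [r.is_taprna for r in once]


class TestTadBoundaryDistance:
    def test_inside_domain(self):
        assert tad_boundary_distance(
            15_000, "chr1", [Interval("chr1", 10_000, 50_000)]) == 5000

    def test_at_boundary(self):
        assert tad_boundary_distance(
            50_000, "chr1", [Interval("chr1", 10_000, 50_000)]) == 0

    def test_no_domains_is_infinite(self):
        assert math.isinf(tad_boundary_distance(100, "chrX", []))

    def test_matches_exhaustive_scan(self, rng):
        doms = []
        for _ in range(10):
            s = int(rng.integers(0, 900_000))
            doms.append(Interval("chr1", s, s + int(rng.integers(1, 50_000))))
        bounds = [b for d in doms for b in (d.start, d.end)]
        for _ in range(100):
            tss = int(rng.integers(0, 1_000_000))
            assert tad_boundary_distance(tss, "chr1", doms) == \
                min(abs(tss - b) for b in bounds)


class TestOverlapEnrichment:
    def test_exact_enumeration_example(self):
        # N=10, K=4, n=5, k=3
        p = hypergeom_upper_tail(3, 10, 4, 5)
        assert p == pytest.approx(oracles.hypergeom_upper(3, 10, 4, 5))

    def test_zero_hits_gives_p_one(self):
        assert hypergeom_upper_tail(0, 10, 4, 5) == pytest.approx(1.0)

    def test_degenerate_urn(self):
        assert hypergeom_upper_tail(4, 10, 4, 10) == pytest.approx(1.0)

    def test_counts_built_from_intervals(self):
        peaks = [Interval("chr1", 0, 1000)]
        test = [Interval("chr1", 500, 600), Interval("chr1", 5000, 5100)]
        bg = [Interval("chr1", 700, 800), Interval("chr1", 9000, 9100)]
        res = overlap_enrichment(test, bg, peaks)
        assert (res.k, res.n, res.K, res.N) == (1, 2, 2, 4)
        assert res.enrichment_score == 0.5

    def test_small_sweep_matches_enumeration(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, n + K - N), min(n, K) + 1):
                        assert hypergeom_upper_tail(k, N, K, n) == \
                            pytest.approx(
                                oracles.hypergeom_upper(k, N, K, n)), \
                            (k, N, K, n)

    def test_power_on_planted_anchor_rates(self, rng):
        """q_test=0.6 vs q_bg=0.1 with n=40, N=400 -> p < 0.01."""
        peaks = []
        test, bg = [], []
        for i in range(40):
            s = i * 10_000
            test.append(Interval("chr1", s, s + 1000))
            if rng.random() < 0.6:
                peaks.append(Interval("chr1", s + 500, s + 700))
        for i in range(360):
            s = 1_000_000 + i * 10_000
            bg.append(Interval("chr1", s, s + 1000))
            if rng.random() < 0.1:
                peaks.append(Interval("chr1", s + 500, s + 700))
        assert overlap_enrichment(test, bg, peaks).p_raw < 0.01


class TestTssAggregation:
    domains = [Interval("chr1", 10_000, 20_000),
               Interval("chr1", 50_000, 80_000)]

    def test_tss_at_domain_starts_fill_first_body_bin(self):
        tss = [("chr1", 10_000), ("chr1", 50_000)]
        prof = tss_aggregation_profile(tss, self.domains, n_bins=10,
                                       flank=5000, flank_bins=2)
        assert prof[2] == 2 and prof.sum() == 2

    def test_anchor_midpoint_hits_central_bin(self):
        anchors = [Interval("chr1", 9_500, 10_500)]
        prof = tss_aggregation_profile([("chr1", 10_000)], anchors,
                                       n_bins=5, flank=1000, mode="anchors")
        assert prof[2] == 1 and prof.sum() == 1

    def test_uniform_tss_multinomial(self, rng):
        dom = [Interval("chr1", 0, 100_000)]
        n = 10_000
        tss = [("chr1", int(p)) for p in rng.integers(0, 100_000, n)]
        n_bins = 10
        prof = tss_aggregation_profile(tss, dom, n_bins=n_bins, flank=1000,
                                       flank_bins=1)
        body = prof[1:-1]
        expect = n / n_bins
        sd = math.sqrt(n * (1 / n_bins) * (1 - 1 / n_bins))
        assert np.all(np.abs(body - expect) < 3 * sd)
        assert prof.sum() == n


class TestMetaLocusProfile:
    def tx(self, tid, strand, exons, chrom="chr1"):
        return TranscriptModel(
            transcript_id=tid, gene_id=f"g{tid}", chrom=chrom, strand=strand,
            exons=[Interval(chrom, a, b, strand) for a, b in exons])

    def test_fully_covered_body(self):
        t = self.tx("a", "+", [(50_000, 52_000)])
        feats = [Interval("chr1", 50_000, 52_000)]
        prof = meta_locus_profile(feats, [t], flank=1000, body_bins=10,
                                  flank_bins=4)
        assert np.allclose(prof[4:14], 1.0)
        assert np.allclose(prof[:4], 0.0) and np.allclose(prof[14:], 0.0)

    def test_minus_strand_flips_upstream(self):
        t = self.tx("a", "-", [(50_000, 52_000)])
        # feature upstream of a minus-strand transcript = right of the span
        feats = [Interval("chr1", 52_000, 53_000)]
        prof = meta_locus_profile(feats, [t], flank=1000, body_bins=10,
                                  flank_bins=4)
        assert np.allclose(prof[:4], 1.0) and np.allclose(prof[4:], 0.0)

    def test_matches_base_level_oracle(self, rng):
        t = self.tx("a", "+", [(40_000, 41_000), (43_000, 44_500)])
        feats = [Interval("chr1", int(s), int(s) + int(w))
                 for s, w in zip(rng.integers(38_000, 46_000, 15),
                                 rng.integers(50, 800, 15))]
        flank, body_bins, flank_bins = 2000, 9, 5
        prof = meta_locus_profile(feats, [t], flank=flank,
                                  body_bins=body_bins, flank_bins=flank_bins)
        tuples = [(f.chrom, f.start, f.end) for f in feats]
        cov = oracles.covered_bases(tuples, "chr1", t.start - flank,
                                    t.end + flank)
        expected = (oracles.bin_mean(cov[:flank], flank_bins)
                    + oracles.bin_mean(cov[flank:flank + (t.end - t.start)],
                                       body_bins)
                    + oracles.bin_mean(cov[flank + (t.end - t.start):],
                                       flank_bins))
        np.testing.assert_allclose(prof, expected)

    def test_linearity_over_transcripts(self, rng):
        txs = [self.tx("a", "+", [(10_000, 12_000)]),
               self.tx("b", "+", [(30_000, 33_000)])]
        feats = [Interval("chr1", int(s), int(s) + 500)
                 for s in rng.integers(8_000, 35_000, 10)]
        combined = meta_locus_profile(feats, txs, flank=1000, body_bins=8,
                                      flank_bins=3)
        singles = [meta_locus_profile(feats, [t], flank=1000, body_bins=8,
                                      flank_bins=3) for t in txs]
        np.testing.assert_allclose(combined, np.mean(singles, axis=0))


class TestCooccupancy:
    def _mat(self, arr, prefix):
        return OccupancyMatrix(pd.DataFrame(
            arr, index=[f"assay{i}" for i in range(arr.shape[0])],
            columns=[f"{prefix}{j}" for j in range(arr.shape[1])]))

    def test_identical_matrices_r_one(self, rng):
        a = rng.integers(0, 2, (6, 8))
        r, p = cooccupancy_correlation(self._mat(a, "p"), self._mat(a, "g"),
                                       n_permutations=200, seed=0)
        assert r == pytest.approx(1.0)

    def test_complement_r_minus_one(self, rng):
        a = rng.integers(0, 2, (6, 8))
        r, _ = cooccupancy_correlation(self._mat(a, "p"),
                                       self._mat(1 - a, "g"),
                                       n_permutations=200, seed=0)
        assert r == pytest.approx(-1.0)

    def test_planted_agreement_matches_direct_formula(self, rng):
        a = rng.integers(0, 2, (40, 60))
        b = np.where(rng.random((40, 60)) < 0.8, a,
                     rng.integers(0, 2, (40, 60)))
        r, p = cooccupancy_correlation(self._mat(a, "p"), self._mat(b, "g"),
                                       n_permutations=300, seed=1)
        x, y = a.ravel().astype(float), b.ravel().astype(float)
        direct = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert r == pytest.approx(direct)
        assert p < 0.01

    def test_occupancy_matrix_from_peaks(self):
        proms = {"p1": Interval("chr1", 0, 1000),
                 "p2": Interval("chr1", 5000, 6000)}
        assays = {"TF1": [Interval("chr1", 500, 600)],
                  "TF2": [Interval("chr1", 5500, 5600)]}
        m = occupancy_matrix(assays, proms)
        assert m.values.loc["TF1", "p1"] == 1
        assert m.values.loc["TF1", "p2"] == 0
        assert m.values.loc["TF2", "p2"] == 1


class TestDistalAnchorStates:
    taprna = record(0, 1000, 2500, taprna=True)

    def test_fully_enhancer_anchor(self):
        loops = [loop("chr1", 1500, 2000, 50_000, 51_000)]
        states = [Interval("chr1", 49_000, 52_000, name="Strong_Enhancer")]
        (ann,) = distal_anchor_states(self.taprna, loops, states)
        assert ann.state_fractions["Strong_Enhancer"] == 1.0
        assert enhancer_fraction(ann) == 1.0

    def test_half_covered_anchor(self):
        loops = [loop("chr1", 1500, 2000, 50_000, 51_000)]
        states = [Interval("chr1", 50_000, 50_500, name="Weak_Enhancer")]
        (ann,) = distal_anchor_states(self.taprna, loops, states)
        assert ann.state_fractions["Weak_Enhancer"] == 0.5

    def test_priority_resolves_overlaps(self):
        loops = [loop("chr1", 1500, 2000, 50_000, 51_000)]
        states = [Interval("chr1", 50_000, 51_000, name="Txn"),
                  Interval("chr1", 50_000, 50_500, name="Strong_Enhancer")]
        (ann,) = distal_anchor_states(
            self.taprna, loops, states,
            state_priority=["Strong_Enhancer", "Txn"])
        assert ann.state_fractions["Strong_Enhancer"] == 0.5
        assert ann.state_fractions["Txn"] == 0.5

    def test_matches_base_level_oracle(self, rng):
        loops = [loop("chr1", 1500, 2000, 50_000, 51_000)]
        states = []
        for i, name in enumerate(["S1", "S2", "S3"] * 4):
            s = int(rng.integers(49_500, 51_200))
            states.append(Interval("chr1", s, s + int(rng.integers(50, 600)),
                                   name=name))
        (ann,) = distal_anchor_states(self.taprna, loops, states,
                                      state_priority=["S1", "S2", "S3"])
        # oracle: per-base first-priority label
        labels = {}
        for name in ["S1", "S2", "S3"]:
            for st in states:
                if st.name != name:
                    continue
                for pos in range(max(st.start, 50_000), min(st.end, 51_000)):
                    labels.setdefault(pos, name)
        for name in ["S1", "S2", "S3"]:
            frac = sum(1 for v in labels.values() if v == name) / 1000
            assert ann.state_fractions.get(name, 0.0) == pytest.approx(frac)

    def test_non_taprna_rejected(self):
        with pytest.raises(ValueError):
            distal_anchor_states(record(0, 0, 100), [], [])

    def test_fractions_sum_at_most_one(self):
        loops = [loop("chr1", 1500, 2000, 50_000, 51_000)]
        states = [Interval("chr1", 50_000, 50_400, name="A"),
                  Interval("chr1", 50_600, 51_000, name="B")]
        (ann,) = distal_anchor_states(self.taprna, loops, states)
        assert sum(ann.state_fractions.values()) <= 1.0


class TestContactEcdf:
    def test_identical_samples_d_zero(self):
        d, p = contact_ecdf_compare([0.1, 0.5, 0.9], [0.1, 0.5, 0.9])
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_supports_d_one(self):
        d, _ = contact_ecdf_compare([0.1, 0.2], [0.8, 0.9])
        assert d == 1.0

    def test_matches_exhaustive_sup_oracle(self):
        a, b = [0.1, 0.5, 0.9], [0.2, 0.6]
        d, _ = contact_ecdf_compare(a, b)
        assert d == pytest.approx(oracles.ks_statistic(a, b))

    def test_p_monotone_decreasing_in_d(self):
        # fixed sizes 5 vs 5, increasing separation
        base = [0.1, 0.2, 0.3, 0.4, 0.5]
        ps = []
        for shift in (0.05, 0.2, 0.4, 0.6):
            other = [x + shift for x in base]
            ps.append(contact_ecdf_compare(base, other)[1])
        assert all(x >= y for x, y in zip(ps, ps[1:]))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            contact_ecdf_compare([], [0.1])


class TestDistanceToNearest:
    def test_inside_feature_zero(self):
        assert distance_to_nearest([("chr1", 50)],
                                   [Interval("chr1", 0, 100)]) == [0.0]

    def test_nine_bp_away(self):
        assert distance_to_nearest([("chr1", 91)],
                                   [Interval("chr1", 100, 200)]) == [9.0]

    def test_matches_exhaustive_scan(self, rng):
        feats = [Interval("chr1", int(s), int(s) + 100)
                 for s in rng.integers(0, 100_000, 20)]
        for _ in range(50):
            pos = int(rng.integers(0, 100_000))
            (got,) = distance_to_nearest([("chr1", pos)], feats)
            expected = min(f.distance_to_point(pos) for f in feats)
            assert got == expected
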