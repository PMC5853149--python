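"""tapRNA calling and chromatin-topology statistics.

A pcRNA is a topological anchor point RNA (tapRNA) when its promoter
overlaps a chromatin loop anchor by at least one base (strand-agnostic).
The module also computes TAD-boundary distances, hypergeometric overlap
enrichments, TSS aggregation and meta-locus coverage profiles, promoter
co-occupancy correlation with a permutation null, distal-anchor chromatin
state fractions and their ECDF comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .models import Interval, Loop, PcRNARecord

# ---------------------------------------------------------------------------
# interval indexing helpers


def _build_trees(features: Iterable[Interval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in features:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def _overlaps_any(trees: Mapping[str, IntervalTree], iv: Interval) -> bool:
    tree = trees.get(iv.chrom)
    return bool(tree is not None and tree.overlap(iv.start, iv.end))


# ---------------------------------------------------------------------------
# tapRNA calling and TAD distances


def call_taprnas(pcrnas: Sequence[PcRNARecord],
                 loops: Iterable[Loop]) -> list[PcRNARecord]:
    """Flag pcRNAs whose promoter overlaps any loop anchor (>= 1 bp)."""
    anchors = []
    for loop in loops:
        anchors.extend([loop.anchor_a, loop.anchor_b])
    trees = _build_trees(anchors)
    return [rec.with_taprna(_overlaps_any(trees, rec.promoter))
            for rec in pcrnas]


def tad_boundaries(tads: Iterable[Interval]) -> dict[str, np.ndarray]:
    """Both end coordinates of every domain, per chromosome, sorted."""
    coords: dict[str, list[int]] = {}
    for dom in tads:
        coords.setdefault(dom.chrom, []).extend([dom.start, dom.end])
    return {chrom: np.unique(np.array(v)) for chrom, v in coords.items()}


def tad_boundary_distance(tss: int, chrom: str,
                          tads: Iterable[Interval] | Mapping[str, np.ndarray],
                          ) -> float:
    """bp distance from a TSS to the nearest domain boundary
    (inf when the chromosome has no domains)."""
    bounds = tads if isinstance(tads, Mapping) else tad_boundaries(tads)
    arr = bounds.get(chrom)
    if arr is None or len(arr) == 0:
        return math.inf
    return float(np.min(np.abs(arr - tss)))


def annotate_tad_distances(pcrnas: Sequence[PcRNARecord],
                           tss_of: Mapping[str, int],
                           tads: Iterable[Interval]) -> list[PcRNARecord]:
    bounds = tad_boundaries(tads)
    out = []
    for rec in pcrnas:
        tss = tss_of[rec.human_transcript_id]
        dist = tad_boundary_distance(tss, rec.promoter.chrom, bounds)
        out.append(pd_replace(rec, tad_boundary_distance=dist))
    return out


def pd_replace(rec: PcRNARecord, **kwargs) -> PcRNARecord:
    from dataclasses import replace
    return replace(rec, **kwargs)


def distance_to_nearest(points: Sequence[tuple[str, int]],
                        features: Iterable[Interval]) -> list[float]:
    """Per-point bp distance to the nearest feature (0 inside; inf when the
    chromosome has no features)."""
    by_chrom: dict[str, list[Interval]] = {}
    for iv in features:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = []
    for chrom, pos in points:
        ivs = by_chrom.get(chrom)
        if not ivs:
            out.append(math.inf)
            continue
        out.append(float(min(iv.distance_to_point(pos) for iv in ivs)))
    return out


# ---------------------------------------------------------------------------
# hypergeometric overlap enrichment


@dataclass
class EnrichmentResult:
    """Generic k/K/n/N hypergeometric record."""

    unit: str
    k: int
    n: int
    K: int
    N: int
    p_raw: float
    p_adjusted: float | None = None

    @property
    def enrichment_score(self) -> float:
        """Hits in the category divided by the category size."""
        return self.k / self.K if self.K else 0.0


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), computed exactly."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def overlap_enrichment(test_promoters: Sequence[Interval],
                       background_promoters: Sequence[Interval],
                       features: Iterable[Interval],
                       unit: str = "overlap") -> EnrichmentResult:
    """Upper-tail hypergeometric test of feature overlap.

    The population is test + background; K counts population promoters
    overlapping >= 1 feature, k those among the test set.
    """
    trees = _build_trees(features)
    k = sum(_overlaps_any(trees, p) for p in test_promoters)
    n = len(test_promoters)
    K = k + sum(_overlaps_any(trees, p) for p in background_promoters)
    N = n + len(background_promoters)
    if k > K or n > N:
        raise ValueError("inconsistent urn counts")
    return EnrichmentResult(unit=unit, k=k, n=n, K=K, N=N,
                            p_raw=hypergeom_upper_tail(k, N, K, n))


# ---------------------------------------------------------------------------
# aggregation and meta-locus profiles


def tss_aggregation_profile(tss_list: Sequence[tuple[str, int]],
                            reference, n_bins: int = 50,
                            flank: int = 50_000,
                            mode: str = "domains",
                            flank_bins: int | None = None,
                            density: bool = False) -> np.ndarray:
    """TSS aggregation around TADs (``mode="domains"``) or loop anchor
    midpoints (``mode="anchors"``).

    For domains each TSS inside a domain maps to a scaled-position body bin;
    TSSs within ``flank`` of a boundary map to flank bins, so the profile is
    ``[left flank bins, body bins, right flank bins]``. For anchors the
    signed distance to the nearest anchor midpoint is binned over
    [-flank, +flank). The profile sums to the number of mapped TSSs unless
    ``density`` normalises it to 1.
    """
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    if mode == "anchors":
        by_chrom: dict[str, list[float]] = {}
        for iv in reference:
            by_chrom.setdefault(iv.chrom, []).append(iv.midpoint)
        counts = np.zeros(n_bins)
        width = 2 * flank / n_bins
        for chrom, tss in tss_list:
            if chrom not in by_chrom:
                continue
            arr = np.asarray(by_chrom[chrom])
            delta = tss - arr[np.argmin(np.abs(arr - tss))]
            if -flank <= delta < flank:
                counts[int((delta + flank) // width)] += 1
        return counts / counts.sum() if density and counts.sum() else counts

    if mode != "domains":
        raise ValueError(f"unknown mode {mode!r}")
    flank_bins = flank_bins if flank_bins is not None else max(1, n_bins // 2)
    domains: dict[str, list[Interval]] = {}
    for dom in reference:
        domains.setdefault(dom.chrom, []).append(dom)
    counts = np.zeros(flank_bins + n_bins + flank_bins)
    fwidth = flank / flank_bins
    for chrom, tss in tss_list:
        doms = domains.get(chrom, [])
        inside = [d for d in doms if d.start <= tss < d.end]
        if inside:
            dom = min(inside, key=lambda d: (d.start, d.end))
            frac = (tss - dom.start) / dom.length
            counts[flank_bins + min(n_bins - 1, int(frac * n_bins))] += 1
            continue
        if not doms:
            continue
        # nearest boundary: left flank precedes a domain start, right flank
        # follows a domain end
        starts = np.array([d.start for d in doms])
        ends = np.array([d.end for d in doms])
        d_start = starts - tss    # >0 when tss left of a domain
        d_end = tss - ends        # >=0 when tss right of a domain
        left_ok = d_start[d_start > 0]
        right_ok = d_end[d_end >= 0]
        best_left = left_ok.min() if left_ok.size else math.inf
        best_right = right_ok.min() if right_ok.size else math.inf
        if best_left <= best_right and best_left <= flank:
            counts[flank_bins - 1 - int((best_left - 1) // fwidth)] += 1
        elif best_right < best_left and best_right < flank:
            counts[flank_bins + n_bins + int(best_right // fwidth)] += 1
    return counts / counts.sum() if density and counts.sum() else counts


def _coverage_mask(features: Sequence[Interval], chrom: str,
                   start: int, end: int) -> np.ndarray:
    mask = np.zeros(end - start, dtype=bool)
    for iv in features:
        if iv.chrom != chrom:
            continue
        lo, hi = max(iv.start, start), min(iv.end, end)
        if lo < hi:
            mask[lo - start:hi - start] = True
    return mask


def _bin_fractions(mask: np.ndarray, n_bins: int) -> np.ndarray:
    # integer edges (i * L // n) keep binning exact for any length
    L = len(mask)
    edges = [i * L // n_bins for i in range(n_bins + 1)]
    out = np.empty(n_bins)
    for i in range(n_bins):
        lo, hi = edges[i], edges[i + 1]
        out[i] = mask[lo:hi].mean() if hi > lo else 0.0
    return out


def meta_locus_profile(features: Sequence[Interval], transcripts,
                       flank: int = 20_000, body_bins: int = 100,
                       flank_bins: int = 20) -> np.ndarray:
    """Mean per-bin fraction of bases covered by features over
    [-flank, TSS..TES scaled to ``body_bins``, +flank], 5'->3' oriented.

    Bases outside chromosome bounds count as uncovered.
    """
    profiles = []
    for tx in transcripts:
        lo, hi = tx.start - flank, tx.end + flank
        mask = np.zeros(hi - lo, dtype=bool)
        inner = _coverage_mask(features, tx.chrom, max(0, lo), hi)
        mask[max(0, lo) - lo:] = inner
        up = _bin_fractions(mask[:flank], flank_bins)
        body = _bin_fractions(mask[flank:flank + (tx.end - tx.start)],
                              body_bins)
        down = _bin_fractions(mask[flank + (tx.end - tx.start):], flank_bins)
        prof = np.concatenate([up, body, down])
        if tx.strand == "-":
            prof = prof[::-1]
        profiles.append(prof)
    if not profiles:
        raise ValueError("no transcripts")
    return np.mean(profiles, axis=0)


# ---------------------------------------------------------------------------
# promoter co-occupancy


@dataclass
class OccupancyMatrix:
    """Binary assays x promoters occupancy matrix."""

    values: pd.DataFrame

    def __post_init__(self):
        arr = self.values.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("occupancy matrix must be binary")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("row/column labels must be unique")


def occupancy_matrix(assays: Mapping[str, Sequence[Interval]],
                     promoters: Mapping[str, Interval]) -> OccupancyMatrix:
    """Binary peak-overlaps-promoter matrix from per-assay peak sets."""
    data = {}
    prom_ids = list(promoters)
    for assay, peaks in assays.items():
        trees = _build_trees(peaks)
        data[assay] = [int(_overlaps_any(trees, promoters[p]))
                       for p in prom_ids]
    return OccupancyMatrix(pd.DataFrame.from_dict(
        data, orient="index", columns=prom_ids))


def cooccupancy_correlation(matrix_a: OccupancyMatrix,
                            matrix_b: OccupancyMatrix,
                            n_permutations: int = 10_000,
                            seed: int = 0) -> tuple[float, float]:
    """Pearson correlation between paired flattened binding vectors, with a
    column-pairing permutation p-value ((s+1)/(n+1) smoothing)."""
    a = matrix_a.values.to_numpy(dtype=float)
    b = matrix_b.values.to_numpy(dtype=float)
    if a.shape != b.shape:
        raise ValueError("matrices must share assays and paired columns")
    r_obs = float(np.corrcoef(a.ravel(), b.ravel())[0, 1])
    rng = np.random.default_rng(seed)
    n_cols = a.shape[1]
    hits = 0
    flat_a = a.ravel()
    for _ in range(n_permutations):
        perm = rng.permutation(n_cols)
        r = np.corrcoef(flat_a, b[:, perm].ravel())[0, 1]
        if r >= r_obs:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return r_obs, p


# ---------------------------------------------------------------------------
# distal-anchor chromatin states


@dataclass
class ContactAnnotation:
    taprna_id: str
    loop_id: str
    distal_anchor: Interval
    state_fractions: dict[str, float] = field(default_factory=dict)


def distal_anchor_states(taprna: PcRNARecord, loops: Iterable[Loop],
                         states: Sequence[Interval],
                         state_priority: Sequence[str] | None = None,
                         ) -> list[ContactAnnotation]:
    """Chromatin-state composition of the anchors in contact with a tapRNA
    promoter.

    For every loop with one anchor overlapping the promoter, the other
    anchor is the distal anchor; each of its bases is assigned to one state
    (overlaps resolved by ``state_priority`` order, then input order), and
    fractions are covered bases / anchor length.
    """
    if not taprna.is_taprna:
        raise ValueError(f"{taprna.human_transcript_id} is not a tapRNA")
    priority = {s: i for i, s in enumerate(state_priority or [])}
    out = []
    for i, loop in enumerate(loops):
        for anchor, distal in ((loop.anchor_a, loop.anchor_b),
                               (loop.anchor_b, loop.anchor_a)):
            if not taprna.promoter.overlaps(anchor):
                continue
            labels = np.full(distal.length, -1)
            rank = np.full(distal.length, np.inf)
            state_names: list[str] = []
            for j, st in enumerate(states):
                if st.chrom != distal.chrom or st.name is None:
                    continue
                lo = max(st.start, distal.start)
                hi = min(st.end, distal.end)
                if lo >= hi:
                    continue
                r = priority.get(st.name, len(priority) + j)
                if st.name not in state_names:
                    state_names.append(st.name)
                idx = state_names.index(st.name)
                sel = slice(lo - distal.start, hi - distal.start)
                better = rank[sel] > r
                labels[sel] = np.where(better, idx, labels[sel])
                rank[sel] = np.minimum(rank[sel], r)
            fractions = {
                name: float((labels == idx).sum()) / distal.length
                for idx, name in enumerate(state_names)
            }
            out.append(ContactAnnotation(
                taprna_id=taprna.human_transcript_id,
                loop_id=loop.loop_id or f"loop_{i}",
                distal_anchor=distal, state_fractions=fractions))
            break  # a loop contributes one distal anchor
    return out


def enhancer_fraction(annotation: ContactAnnotation,
                      enhancer_token: str = "Enhancer") -> float:
    """Fraction of the distal anchor in states whose label contains the
    token (mirrors 9-state segmentation naming)."""
    return sum(f for name, f in annotation.state_fractions.items()
               if enhancer_token.lower() in name.lower())


def contact_ecdf_compare(fractions_a: Sequence[float],
                         fractions_b: Sequence[float],
                         ) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov comparison of state-fraction
    distributions (exact p for samples of <= 10, asymptotic otherwise)."""
    a, b = np.asarray(fractions_a), np.asarray(fractions_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if min(a.size, b.size) <= 10 else "asymp"
    res = stats.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)
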