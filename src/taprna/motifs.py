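"""k-mer enrichment in conserved domains, consensus clustering, PWM
scanning and similarity.

k-mer counting is single-strand in transcript space (the sequences are
RNAs); occurrences overlap freely. Enrichment is a one-sided Fisher exact
test on position counts, computed through the equivalent hypergeometric
upper tail and vectorised across all k-mers. PWM scanning of genomic DNA is
double-stranded with log-odds scores against the motif background.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .models import BASE_ORDER, Interval, Pwm, revcomp

_BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}


@dataclass
class KmerEnrichment:
    kmer: str
    count_fg: int
    total_fg: int
    count_bg: int
    total_bg: int
    p_raw: float
    enriched: bool

    @property
    def rate_fg(self) -> float:
        return self.count_fg / self.total_fg if self.total_fg else 0.0

    @property
    def rate_bg(self) -> float:
        return self.count_bg / self.total_bg if self.total_bg else 0.0


def count_kmers(seqs: Sequence[str], k: int) -> tuple[dict[str, int], int]:
    """Overlapping k-mer counts and the total number of k-mer positions.

    k-mers containing N are not counted but their positions still count
    toward the total; sequences shorter than k contribute zero positions.
    """
    counts: dict[str, int] = {}
    total = 0
    for seq in seqs:
        seq = seq.upper()
        n_pos = max(0, len(seq) - k + 1)
        total += n_pos
        for i in range(n_pos):
            kmer = seq[i:i + k]
            if "N" not in kmer:
                counts[kmer] = counts.get(kmer, 0) + 1
    return counts, total


def kmer_enrichment(fg_seqs: Sequence[str], bg_seqs: Sequence[str],
                    k: int = 8, alpha: float = 1e-4,
                    adjust: bool = False) -> list[KmerEnrichment]:
    """Per-k-mer one-sided Fisher exact test of foreground vs background
    position counts, most significant first.

    ``enriched`` requires p <= alpha (raw by default, BH-adjusted with
    ``adjust``) and a strictly higher foreground rate.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not fg_seqs or not bg_seqs:
        raise ValueError("foreground and background must be non-empty")
    fg_counts, total_fg = count_kmers(fg_seqs, k)
    bg_counts, total_bg = count_kmers(bg_seqs, k)
    kmers = sorted(set(fg_counts) | set(bg_counts))
    cfg = np.array([fg_counts.get(m, 0) for m in kmers])
    cbg = np.array([bg_counts.get(m, 0) for m in kmers])
    # one-sided Fisher (greater) == hypergeometric upper tail on the
    # 2x2 table [[cfg, total_fg-cfg], [cbg, total_bg-cbg]]; evaluated on
    # unique count pairs only (most k-mers share small counts)
    pairs, inverse = np.unique(np.stack([cfg, cbg]), axis=1,
                               return_inverse=True)
    p_unique = stats.hypergeom.sf(pairs[0] - 1, total_fg + total_bg,
                                  pairs[0] + pairs[1], total_fg)
    p = np.minimum(p_unique[inverse], 1.0)
    p_test = p
    if adjust:
        from statsmodels.stats.multitest import multipletests
        p_test = multipletests(p, method="fdr_bh")[1]
    results = [
        KmerEnrichment(
            kmer=m, count_fg=int(f), total_fg=total_fg,
            count_bg=int(b), total_bg=total_bg, p_raw=float(pr),
            enriched=bool(pt <= alpha
                          and f * total_bg > b * total_fg),
        )
        for m, f, b, pr, pt in zip(kmers, cfg, cbg, p, p_test)
    ]
    results.sort(key=lambda r: (r.p_raw, r.kmer))
    return results


# ---------------------------------------------------------------------------
# consensus clustering of enriched k-mers


@dataclass
class ConsensusMotif:
    members: list[str]
    offsets: list[int]
    pwm: Pwm
    label: str = ""


def _best_offset(seed: str, kmer: str, min_overlap: int,
                 max_mismatch: int) -> int | None:
    """Best ungapped offset of `kmer` against `seed` (positive shifts move
    the k-mer right); None when no offset satisfies the merge rule."""
    k_s, k_m = len(seed), len(kmer)
    best_key, best_off = None, None
    for off in range(-(k_m - min_overlap), k_s - min_overlap + 1):
        lo, hi = max(0, off), min(k_s, off + k_m)
        overlap = hi - lo
        if overlap < min_overlap:
            continue
        mismatches = sum(seed[i] != kmer[i - off] for i in range(lo, hi))
        if mismatches > max_mismatch:
            continue
        key = (-overlap, mismatches, abs(off), off)
        if best_key is None or key < best_key:
            best_key, best_off = key, off
    return best_off


def _pwm_from_members(members: Sequence[str], offsets: Sequence[int],
                      motif_id: str, pseudocount: float = 0.5) -> Pwm:
    lo = min(offsets)
    hi = max(off + len(m) for m, off in zip(members, offsets))
    counts = np.zeros((4, hi - lo))
    for m, off in zip(members, offsets):
        for i, base in enumerate(m):
            counts[_BASE_INDEX[base], off - lo + i] += 1
    probs = counts + pseudocount
    return Pwm(motif_id, probs / probs.sum(axis=0))


def cluster_kmers(enriched: Sequence[KmerEnrichment],
                  max_mismatch: int = 1,
                  min_overlap: int = 6) -> list[ConsensusMotif]:
    """Greedy agglomeration of enriched k-mers into consensus motifs.

    The most significant unassigned k-mer seeds a cluster; every remaining
    k-mer whose best ungapped offset alignment to the seed has
    >= ``min_overlap`` overlapping positions and <= ``max_mismatch``
    mismatches joins it. Deterministic given the (p, lexicographic) order.
    """
    if not enriched:
        raise ValueError("no enriched k-mers to cluster")
    pool = sorted(enriched, key=lambda r: (r.p_raw, r.kmer))
    motifs = []
    while pool:
        seed = pool.pop(0)
        members, offsets = [seed.kmer], [0]
        rest = []
        for cand in pool:
            off = _best_offset(seed.kmer, cand.kmer, min_overlap,
                               max_mismatch)
            if off is None:
                rest.append(cand)
            else:
                members.append(cand.kmer)
                offsets.append(off)
        pool = rest
        label = f"consensus_{len(motifs) + 1}"
        motifs.append(ConsensusMotif(
            members=members, offsets=offsets,
            pwm=_pwm_from_members(members, offsets, label), label=label))
    return motifs


# ---------------------------------------------------------------------------
# PWM scanning


@dataclass(frozen=True)
class MotifHit:
    pwm_id: str
    interval: Interval
    strand: str
    score: float


def _log_odds(pwm: Pwm) -> np.ndarray:
    return np.log2(pwm.matrix / pwm.background[:, None])


def _encode(seq: str) -> np.ndarray:
    out = np.full(len(seq), -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8)
            == ord(base)] = idx
    return out


def _scan_strand(seq: str, lod: np.ndarray) -> np.ndarray:
    """Log-odds score at every start position (NaN where N intrudes)."""
    L = lod.shape[1]
    enc = _encode(seq.upper())
    n_pos = len(seq) - L + 1
    if n_pos <= 0:
        return np.empty(0)
    scores = np.zeros(n_pos)
    valid = np.ones(n_pos, dtype=bool)
    for j in range(L):
        col = enc[j:j + n_pos]
        ok = col >= 0
        valid &= ok
        scores += np.where(ok, lod[np.clip(col, 0, 3), j], 0.0)
    scores[~valid] = np.nan
    return scores


def pwm_scan(sequences: Mapping[str, str] | str, pwm: Pwm,
             min_score_fraction: float = 0.8) -> list[MotifHit]:
    """Scan both strands for log-odds hits scoring at least
    ``min_score_fraction`` of the maximum attainable score.

    ``sequences`` is a {chrom: sequence} mapping (a bare string scans as
    chromosome ``"seq"``). Hits are reported on forward-strand coordinates.
    """
    if not 0 < min_score_fraction <= 1:
        raise ValueError("min_score_fraction must be in (0, 1]")
    if isinstance(sequences, str):
        sequences = {"seq": sequences}
    lod = _log_odds(pwm)
    threshold = min_score_fraction * lod.max(axis=0).sum()
    L = pwm.length
    hits = []
    for chrom in sorted(sequences):
        seq = sequences[chrom]
        n = len(seq)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            scores = _scan_strand(s, lod)
            for pos in np.nonzero(scores >= threshold)[0]:
                start = int(pos) if strand == "+" else n - int(pos) - L
                hits.append(MotifHit(
                    pwm_id=pwm.motif_id,
                    interval=Interval(chrom, start, start + L, strand,
                                      name=pwm.motif_id),
                    strand=strand, score=float(scores[pos])))
    hits.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# PWM similarity


def pwm_similarity(pwm_a: Pwm, pwm_b: Pwm,
                   min_overlap: int = 4) -> tuple[float, int, str]:
    """Best mean column-wise Pearson correlation over all ungapped offsets
    and both orientations of ``pwm_b``.

    Returns (score, offset, orientation) with orientation "+" or "-".
    """
    if pwm_a.length < 4 or pwm_b.length < 4:
        raise ValueError("PWMs must have length >= 4")
    best = (-2.0, 0, "+")
    for orientation, b in (("+", pwm_b), ("-", pwm_b.reverse_complement())):
        for off in range(-(b.length - min_overlap),
                         pwm_a.length - min_overlap + 1):
            lo, hi = max(0, off), min(pwm_a.length, off + b.length)
            if hi - lo < min_overlap:
                continue
            cols_a = pwm_a.matrix[:, lo:hi]
            cols_b = b.matrix[:, lo - off:hi - off]
            rs = []
            for ca, cb in zip(cols_a.T, cols_b.T):
                if np.std(ca) == 0 or np.std(cb) == 0:
                    rs.append(0.0)
                else:
                    rs.append(float(np.corrcoef(ca, cb)[0, 1]))
            score = float(np.mean(rs))
            if score > best[0]:
                best = (score, off, orientation)
    return best


def enumerate_kmers(k: int) -> list[str]:
    """All 4^k DNA k-mers in lexicographic order."""
    return ["".join(p) for p in itertools.product(BASE_ORDER, repeat=k)]
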