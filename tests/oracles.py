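"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (pure-Python dynamic programming,
exhaustive enumeration, base-by-base counting) and shares no code with the
package implementation.
"""

from __future__ import annotations

import itertools
from math import comb


# ---------------------------------------------------------------------------
# affine-gap alignment (Gotoh) — scores only

NEG = float("-inf")


def local_score(a: str, b: str, match=1.0, mismatch=-1.0,
                gap_open=-2.0, gap_extend=-1.0) -> float:
    """Smith-Waterman score with affine gaps; a gap of length L costs
    gap_open + (L-1) * gap_extend."""
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def global_score(a: str, b: str, match=1.0, mismatch=-1.0,
                 gap_open=-2.0, gap_extend=-1.0) -> float:
    """Needleman-Wunsch score with affine gaps, end gaps penalised."""
    n, m = len(a), len(b)
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    H[0][0] = 0.0
    for j in range(1, m + 1):
        E[0][j] = gap_open + (j - 1) * gap_extend
        H[0][j] = E[0][j]
    for i in range(1, n + 1):
        F[i][0] = gap_open + (i - 1) * gap_extend
        H[i][0] = F[i][0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else mismatch
            H[i][j] = max(H[i - 1][j - 1] + s, E[i][j], F[i][j])
    return H[n][m]


def global_alignments(a: str, b: str):
    """All gapped global alignments of two short strings, as row pairs."""
    if not a and not b:
        yield ("", "")
        return
    if a:
        for ra, rb in global_alignments(a[1:], b):
            yield (a[0] + ra, "-" + rb)
    if b:
        for ra, rb in global_alignments(a, b[1:]):
            yield ("-" + ra, b[0] + rb)
    if a and b:
        for ra, rb in global_alignments(a[1:], b[1:]):
            yield (a[0] + ra, b[0] + rb)


def score_alignment(ra: str, rb: str, match=1.0, mismatch=-1.0,
                    gap_open=-2.0, gap_extend=-1.0) -> float:
    score, in_gap = 0.0, False
    for x, y in zip(ra, rb):
        if x == "-" or y == "-":
            score += gap_extend if in_gap else gap_open
            in_gap = True
        else:
            in_gap = False
            score += match if (x == y and x != "N") else mismatch
    return score


# ---------------------------------------------------------------------------
# exact hypergeometric / Fisher enumeration


def hypergeom_pmf(k: int, N: int, K: int, n: int) -> float:
    if k < max(0, n + K - N) or k > min(n, K):
        return 0.0
    return comb(K, k) * comb(N - K, n - k) / comb(N, n)


def hypergeom_upper(k: int, N: int, K: int, n: int) -> float:
    return sum(hypergeom_pmf(i, N, K, n) for i in range(k, min(n, K) + 1))


def fisher_greater(a: int, b: int, c: int, d: int) -> float:
    """One-sided (greater) Fisher exact p for table [[a, b], [c, d]]."""
    return hypergeom_upper(a, a + b + c + d, a + c, a + b)


# ---------------------------------------------------------------------------
# KS statistic by exhaustive sup enumeration


def ks_statistic(xs, ys) -> float:
    xs, ys = sorted(xs), sorted(ys)
    points = sorted(set(xs) | set(ys))
    d = 0.0
    for p in points:
        fa = sum(1 for x in xs if x <= p) / len(xs)
        fb = sum(1 for y in ys if y <= p) / len(ys)
        d = max(d, abs(fa - fb))
    return d


# ---------------------------------------------------------------------------
# base-level coverage counting


def covered_bases(features, chrom: str, start: int, end: int) -> list[bool]:
    """Per-base coverage flags over [start, end) from (chrom, s, e) tuples."""
    out = [False] * (end - start)
    for fc, fs, fe in features:
        if fc != chrom:
            continue
        for pos in range(max(fs, start), min(fe, end)):
            out[pos - start] = True
    return out


def bin_mean(values, n_bins: int) -> list[float]:
    edges = [i * len(values) // n_bins for i in range(n_bins + 1)]
    return [
        (sum(values[edges[i]:edges[i + 1]]) / (edges[i + 1] - edges[i]))
        if edges[i + 1] > edges[i] else 0.0
        for i in range(n_bins)
    ]


# ---------------------------------------------------------------------------
# misc


def longest_orf(seq: str) -> int:
    """Codon count of the longest ATG-initiated ORF, all start positions."""
    stops = {"TAA", "TAG", "TGA"}
    best = 0
    for i in range(len(seq) - 2):
        if seq[i:i + 3] != "ATG":
            continue
        codons, q = 0, i
        while q + 3 <= len(seq) and seq[q:q + 3] not in stops:
            codons += 1
            q += 3
        best = max(best, codons)
    return best


def all_kmer_positions(seqs, k: int) -> int:
    return sum(max(0, len(s) - k + 1) for s in seqs)


def pwm_best_offset_corr(mat_a, mat_b, min_overlap=4):
    """Exhaustive mean column-Pearson over offsets (single orientation)."""
    import numpy as np

    la, lb = mat_a.shape[1], mat_b.shape[1]
    best = -2.0
    for off in range(-(lb - min_overlap), la - min_overlap + 1):
        lo, hi = max(0, off), min(la, off + lb)
        if hi - lo < min_overlap:
            continue
        rs = []
        for j in range(lo, hi):
            ca, cb = mat_a[:, j], mat_b[:, j - off]
            if ca.std() == 0 or cb.std() == 0:
                rs.append(0.0)
            else:
                rs.append(float(np.corrcoef(ca, cb)[0, 1]))
        best = max(best, sum(rs) / len(rs))
    return best
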