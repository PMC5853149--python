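"""Co-expression, tissue specificity and generic enrichment statistics.

Spearman correlations are computed as Pearson on average ranks; the
mean-correlation permutation test re-pairs lncRNAs with non-partner genes
(derangement-style) and reports the add-one-smoothed upper tail. Tissue
specificity uses tau: 0 for uniform expression, 1 for single-tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix
from .topology import EnrichmentResult, hypergeom_upper_tail

logger = logging.getLogger(__name__)


def _ranked_rows(matrix: np.ndarray) -> np.ndarray:
    """Average ranks along rows, centred and scaled to unit norm (zero rows
    for zero-variance features, which callers must exclude)."""
    ranks = np.apply_along_axis(stats.rankdata, 1, matrix)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(norms > 0, ranks / norms, 0.0)
    return out


def pair_correlations(expr: ExpressionMatrix,
                      pairs: Sequence[tuple[str, str]],
                      ) -> pd.DataFrame:
    """Spearman rho per (lncRNA, gene) pair over shared samples.

    Pairs with zero variance in either member are excluded and logged.
    """
    values = expr.values
    if values.shape[1] < 3:
        raise ValueError("need >= 3 shared samples")
    rows = []
    for lnc, gene in pairs:
        x = values.loc[lnc].to_numpy(dtype=float)
        y = values.loc[gene].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("excluding zero-variance pair (%s, %s)", lnc, gene)
            continue
        rho = stats.spearmanr(x, y).statistic
        rows.append((lnc, gene, float(rho)))
    return pd.DataFrame(rows, columns=["lnc", "gene", "rho"])


@dataclass
class MeanCorrelationResult:
    mean_rho: float
    p_value: float
    n_pairs: int
    null_means: np.ndarray
    background_rhos: np.ndarray = field(default_factory=lambda: np.empty(0))


def mean_correlation_test(expr: ExpressionMatrix,
                          pairs: Sequence[tuple[str, str]],
                          n_perm: int = 10_000, seed: int = 0,
                          max_background: int = 100_000,
                          ) -> MeanCorrelationResult:
    """Permutation test of the mean pairwise Spearman correlation.

    The null re-pairs each lncRNA with a non-partner gene (derangement-style
    shuffle of the gene side); p = (count(null >= observed) + 1)/(n_perm+1).
    The all-pairs background correlation distribution is returned for
    plotting (subsampled beyond ``max_background``).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    lncs = [p[0] for p in pairs]
    genes = [p[1] for p in pairs]
    L = _ranked_rows(expr.values.loc[lncs].to_numpy(dtype=float))
    G = _ranked_rows(expr.values.loc[genes].to_numpy(dtype=float))
    keep = (np.abs(L).sum(axis=1) > 0) & (np.abs(G).sum(axis=1) > 0)
    if not keep.all():
        logger.warning("excluding %d zero-variance pairs", (~keep).sum())
        L, G = L[keep], G[keep]
    n = L.shape[0]
    if n < 2:
        raise ValueError("need >= 2 usable pairs")
    observed = float(np.einsum("ij,ij->i", L, G).mean())
    rng = np.random.default_rng(seed)
    null_means = np.empty(n_perm)
    for i in range(n_perm):
        perm = _derangement(n, rng)
        null_means[i] = np.einsum("ij,ij->i", L, G[perm]).mean()
    p = (float((null_means >= observed).sum()) + 1) / (n_perm + 1)
    background = (L @ G.T).ravel()
    if background.size > max_background:
        background = rng.choice(background, size=max_background,
                                replace=False)
    return MeanCorrelationResult(mean_rho=observed, p_value=p, n_pairs=n,
                                 null_means=null_means,
                                 background_rhos=background)


def _derangement(n: int, rng: np.random.Generator,
                 max_tries: int = 200) -> np.ndarray:
    for _ in range(max_tries):
        perm = rng.permutation(n)
        if not (perm == np.arange(n)).any():
            return perm
    # pathological only for tiny n; fix remaining fixed points by swapping
    fixed = np.nonzero(perm == np.arange(n))[0]
    for i in fixed:
        j = (i + 1) % n
        perm[i], perm[j] = perm[j], perm[i]
    return perm


def tissue_specificity_tau(expression_vector: Sequence[float]) -> float:
    """Tau index: sum(1 - x_i/x_max) / (n - 1); 0 uniform, 1 one-hot."""
    x = np.asarray(expression_vector, dtype=float)
    if (x < 0).any():
        raise ValueError("expression must be non-negative")
    if x.max() <= 0:
        raise ValueError("max expression must be positive")
    if x.size < 2:
        raise ValueError("need >= 2 tissues")
    return float((1 - x / x.max()).sum() / (x.size - 1))


def _matched_sample(test_values: np.ndarray, pool_values: np.ndarray,
                    n_bins: int, rng: np.random.Generator) -> np.ndarray:
    """Indices into the pool matching the test set's quantile-bin counts."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if pool_values.size < test_values.size:
        raise ValueError("pool must be at least as large as the test set")
    edges = np.quantile(test_values, np.linspace(0, 1, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    test_bins = np.searchsorted(edges, test_values, side="right") - 1
    pool_bins = np.searchsorted(edges, pool_values, side="right") - 1
    chosen = []
    for b in range(n_bins):
        need = int((test_bins == b).sum())
        avail = np.nonzero(pool_bins == b)[0]
        if avail.size < need:
            raise ValueError(
                f"bin {b}: pool has {avail.size} members, need {need}")
        chosen.append(rng.choice(avail, size=need, replace=False))
    return np.sort(np.concatenate(chosen))


def expression_matched_background(test_features: Sequence[str],
                                  pool_features: Sequence[str],
                                  expr: ExpressionMatrix,
                                  n_bins: int = 5,
                                  seed: int = 0) -> list[str]:
    """Sample pool features whose mean-expression histogram (quantile bins
    of the test set) matches the test set exactly; without replacement."""
    rng = np.random.default_rng(seed)
    test_vals = expr.values.loc[list(test_features)].mean(axis=1).to_numpy()
    pool_vals = expr.values.loc[list(pool_features)].mean(axis=1).to_numpy()
    idx = _matched_sample(test_vals, pool_vals, n_bins, rng)
    return [pool_features[i] for i in idx]


def span_matched_universe(target_genes: Sequence[str],
                          universe_genes: Sequence[str],
                          span_of: Callable[[str], float] | Mapping[str, float],
                          n_bins: int = 5, seed: int = 0) -> list[str]:
    """Universe sample matched to the targets' intergenic-span distribution
    (same contract as the expression-matched background)."""
    getter = span_of.__getitem__ if isinstance(span_of, Mapping) else span_of
    rng = np.random.default_rng(seed)
    t = np.array([getter(g) for g in target_genes], dtype=float)
    u = np.array([getter(g) for g in universe_genes], dtype=float)
    idx = _matched_sample(t, u, n_bins, rng)
    return [universe_genes[i] for i in idx]


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def distance_correlation_regression(distances_bp: Sequence[float],
                                    rhos: Sequence[float],
                                    ) -> RegressionResult:
    """OLS of pair correlation on genomic distance, with R^2 and the
    two-sided slope p-value."""
    d = np.asarray(distances_bp, dtype=float)
    r = np.asarray(rhos, dtype=float)
    if d.size != r.size or d.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(r) == 0:  # constant response: flat fit, nothing explained
        return RegressionResult(slope=0.0, intercept=float(r[0]),
                                r_squared=0.0, p_value=1.0)
    res = stats.linregress(d, r)
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            r_squared=float(res.rvalue ** 2),
                            p_value=float(res.pvalue))


def set_enrichment(target_genes: Sequence[str],
                   universe_genes: Sequence[str],
                   term_map: Mapping[str, Sequence[str]],
                   ) -> list[EnrichmentResult]:
    """Per-term hypergeometric enrichment of the target set with BH
    adjustment; the enrichment score is k/K (hits over category size)."""
    universe = set(universe_genes)
    target = set(target_genes)
    if not target <= universe:
        raise ValueError("target genes must be a subset of the universe")
    N, n = len(universe), len(target)
    results = []
    for term in sorted(term_map):
        members = set(term_map[term]) & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & target)
        results.append(EnrichmentResult(
            unit=term, k=k, n=n, K=K, N=N,
            p_raw=hypergeom_upper_tail(k, N, K, n)))
    if results:
        adj = multipletests([r.p_raw for r in results], method="fdr_bh")[1]
        for r, p in zip(results, adj):
            r.p_adjusted = float(p)
    return results
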