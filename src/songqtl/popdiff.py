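"""Population-level trait comparison between France (FR) and Zambia (ZI) panels.

Three layers:

1. Two-sample Mann-Whitney U tests per trait (exact two-sided p by dynamic
   programming over the null rank-sum distribution when there are no ties and
   both groups are small; tie-corrected normal approximation with continuity
   correction otherwise -- the conventions of R's ``wilcox.test``).
2. A family-wise false-positive-rate correction over the whole trait family:
   per permutation, ONE shared relabeling of strains (drawn without
   replacement into pseudo-FR/pseudo-ZI groups of the empirical sizes) is
   applied to every trait, the minimum raw p across traits is recorded, and a
   trait's corrected FPR is the fraction of permutations whose min-p was as
   low or lower than that trait's empirical raw p.  Sharing the relabeling
   preserves the trait correlation structure (a min-p / Westfall-Young
   procedure).
3. Q_ST, the quantitative-trait analogue of F_ST, from a one-way
   random-effects decomposition of strain means grouped by population, and
   its percentile within a supplied per-SNP F_ST distribution.
"""

from __future__ import annotations

import functools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trait_io import StrainTraitTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=256)
def _u_null_pmf(n1: int, n2: int) -> np.ndarray:
    """Exact null pmf of the Mann-Whitney U statistic (no ties).

    Classic recurrence f(i, j, u) = f(i-1, j, u-j) + f(i, j-1, u) over the
    number of group-1 (i) and group-2 (j) observations placed so far.
    """
    maxu = n1 * n2
    # f[j, u] for the current i; start at i = 0: only u = 0 possible.
    f = np.zeros((n2 + 1, maxu + 1))
    f[:, 0] = 1.0
    for _i in range(1, n1 + 1):
        g = np.zeros_like(f)
        g[0, 0] = 1.0
        for j in range(1, n2 + 1):
            g[j] = g[j - 1]
            g[j, j:] = g[j, j:] + f[j, : maxu + 1 - j]
        f = g
    pmf = f[n2]
    return pmf / pmf.sum()


@functools.lru_cache(maxsize=256)
def exact_two_sided_p(n1: int, n2: int) -> np.ndarray:
    """Two-sided exact p-value indexed by integer U (0..n1*n2), no ties."""
    pmf = _u_null_pmf(n1, n2)
    cdf = np.cumsum(pmf)
    sf = np.cumsum(pmf[::-1])[::-1]  # P(U >= u)
    return np.minimum(1.0, 2.0 * np.minimum(cdf, sf))


def _tie_sigma(n1: int, n2: int, values: np.ndarray) -> float:
    """SD of U under the null with mid-rank tie correction."""
    n = n1 + n2
    _, t = np.unique(values, return_counts=True)
    tie_term = float(np.sum(t**3 - t))
    return math.sqrt(n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1))))


def _normal_two_sided_p(u, mu: float, sigma: float, continuity: bool = True):
    """Normal-approximation two-sided p (vectorised over u)."""
    z = np.asarray(u, dtype=float) - mu
    if continuity:
        z = z - np.sign(z) * 0.5
    z = z / sigma
    return np.minimum(1.0, 2.0 * stats.norm.sf(np.abs(z)))


@dataclass
class MannWhitneyResult:
    u: float
    pvalue: float
    method: str  # "exact" | "normal"

    def __iter__(self):  # allow (u, p) unpacking
        return iter((self.u, self.pvalue))


def mann_whitney(a, b, exact_cap: int = 50, continuity: bool = True) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test of two independent samples.

    ``a`` is group 1 (its U statistic is reported).  Exact enumeration of the
    null rank-sum distribution is used when there are no ties and both sample
    sizes are below ``exact_cap``; otherwise the tie-corrected normal
    approximation with continuity correction (matching R's ``wilcox.test``
    defaults).  Empty groups raise :class:`ValueError`.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("mann_whitney requires two nonempty groups")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    has_ties = len(np.unique(pooled)) < n1 + n2
    if not has_ties and n1 < exact_cap and n2 < exact_cap:
        p = float(exact_two_sided_p(n1, n2)[int(round(u))])
        return MannWhitneyResult(u, p, "exact")
    sigma = _tie_sigma(n1, n2, pooled)
    p = float(_normal_two_sided_p(u, n1 * n2 / 2.0, sigma, continuity))
    return MannWhitneyResult(u, p, "normal")


# ---------------------------------------------------------------------------
# Family-wise permutation correction
# ---------------------------------------------------------------------------

def familywise_permutation_fpr(
    table: StrainTraitTable,
    n_perm: int = 10_000,
    seed: int | None = None,
    populations: tuple[str, str] = ("FR", "ZI"),
    shared: bool = True,
    plus_one: bool = False,
    exact_cap: int = 50,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Per-trait MW tests with family-wise permutation-corrected FPR.

    Returns a DataFrame indexed by trait with columns ``u``, ``raw_p``,
    ``fpr``, group means and sizes.  ``shared=True`` (default) applies one
    relabeling per permutation across all traits (min-p correction);
    ``shared=False`` shuffles independently per trait, yielding per-trait
    permutation p-values without family-wise control.  ``plus_one`` switches
    the FPR from the plain proportion to ``(k+1)/(n_perm+1)``.

    Traits with any missing strain mean are dropped from the family with a
    warning.  The permutation engine and the empirical raw p use the same
    p-value convention per trait (exact table when the trait has no ties,
    tie-corrected normal approximation otherwise), so the comparison
    "permutation p as low or lower than the empirical p" is internally
    consistent.

    ``exhaustive=True`` replaces random sampling by the full set of
    C(n1+n2, n1) relabelings (shared mode only; feasible for small panels),
    making the corrected FPR an exact tail probability.
    """
    t = table.subset(populations)
    labels = t.cohort.values
    n1 = int((labels == populations[0]).sum())
    n2 = int((labels == populations[1]).sum())
    if n1 + n2 != len(t.strains):
        raise ValueError("population labels do not partition the strain table")
    if n1 < 1 or n2 < 1:
        raise ValueError("both populations need at least one strain")
    X = t.means
    complete = X.columns[X.notna().all(axis=0)]
    dropped = [c for c in X.columns if c not in complete]
    if dropped:
        logger.warning("dropping %d traits with missing strain means: %s", len(dropped), dropped)
    X = X[complete]
    traits = list(X.columns)
    n = n1 + n2
    values = X.values  # (n, T)
    ranks = np.apply_along_axis(stats.rankdata, 0, values)
    offset = n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    tie_mask = np.array([len(np.unique(values[:, j])) < n for j in range(len(traits))])
    sigmas = np.array(
        [_tie_sigma(n1, n2, values[:, j]) if tie_mask[j] else np.nan for j in range(len(traits))]
    )
    use_exact = ~tie_mask & (n1 < exact_cap) & (n2 < exact_cap)
    p_table = exact_two_sided_p(n1, n2)

    def p_matrix(u: np.ndarray) -> np.ndarray:
        """Map a (perm, trait) matrix of U statistics to two-sided p-values."""
        p = np.empty_like(u, dtype=float)
        if use_exact.any():
            p[:, use_exact] = p_table[np.rint(u[:, use_exact]).astype(int)]
        for j in np.flatnonzero(~use_exact):
            p[:, j] = _normal_two_sided_p(u[:, j], mu, sigmas[j])
        return p

    group1 = labels == populations[0]
    u_emp = group1 @ ranks - offset
    p_emp = p_matrix(u_emp[None, :])[0]

    rng = np.random.default_rng(seed)
    if exhaustive:
        if not shared:
            raise ValueError("exhaustive enumeration requires shared relabelings")
        from itertools import combinations

        combos = list(combinations(range(n), n1))
        n_perm = len(combos)
        indicator = np.zeros((n_perm, n), dtype=float)
        for i, c in enumerate(combos):
            indicator[i, list(c)] = 1.0
        u_perm = indicator @ ranks - offset
        p_perm = p_matrix(u_perm)
        min_p = p_perm.min(axis=1)
        hits = (min_p[:, None] <= p_emp[None, :]).sum(axis=0)
    elif shared:
        order = np.argsort(rng.random((n_perm, n)), axis=1)
        indicator = np.zeros((n_perm, n), dtype=float)
        np.put_along_axis(indicator, order[:, :n1], 1.0, axis=1)
        u_perm = indicator @ ranks - offset
        p_perm = p_matrix(u_perm)
        min_p = p_perm.min(axis=1)
        hits = (min_p[:, None] <= p_emp[None, :]).sum(axis=0)
    else:
        hits = np.zeros(len(traits))
        for j in range(len(traits)):
            order = np.argsort(rng.random((n_perm, n)), axis=1)
            indicator = np.zeros((n_perm, n), dtype=float)
            np.put_along_axis(indicator, order[:, :n1], 1.0, axis=1)
            u_col = indicator @ ranks[:, j] - offset
            if use_exact[j]:
                p_col = p_table[np.rint(u_col).astype(int)]
            else:
                p_col = _normal_two_sided_p(u_col, mu, sigmas[j])
            hits[j] = (p_col <= p_emp[j]).sum()

    fpr = (hits + 1) / (n_perm + 1) if plus_one else hits / n_perm
    out = pd.DataFrame(
        {
            "u": u_emp,
            "raw_p": p_emp,
            "fpr": fpr,
            f"mean_{populations[0]}": values[group1].mean(axis=0),
            f"mean_{populations[1]}": values[~group1].mean(axis=0),
            f"n_{populations[0]}": n1,
            f"n_{populations[1]}": n2,
        },
        index=pd.Index(traits, name="trait"),
    )
    return out


# ---------------------------------------------------------------------------
# Q_ST
# ---------------------------------------------------------------------------

@dataclass
class QstResult:
    v_between: float
    v_within: float
    qst: float
    fst_percentile: float | None = None


def qst(fr_means, zi_means, inbred: bool = True) -> QstResult:
    """Q_ST from strain means of two populations.

    Method-of-moments one-way random-effects decomposition with the
    unbalanced-design correction for unequal strain counts; negative
    between-population variance estimates truncate to 0.  For fully inbred
    lines the among-line variance within populations is ~2x the additive
    variance, so the inbred form Q_ST = V_b/(V_b + V_w) absorbs the usual
    factor of 2; ``inbred=False`` selects the outbred form V_b/(V_b + 2 V_w).
    """
    groups = [np.asarray(fr_means, dtype=float), np.asarray(zi_means, dtype=float)]
    groups = [g[~np.isnan(g)] for g in groups]
    sizes = np.array([len(g) for g in groups])
    if (sizes < 2).any():
        raise ValueError("qst requires at least 2 strains per population")
    n_total = sizes.sum()
    k = len(groups)
    grand = np.concatenate(groups).mean()
    group_means = np.array([g.mean() for g in groups])
    msb = float(np.sum(sizes * (group_means - grand) ** 2) / (k - 1))
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, group_means)))
    msw = ssw / (n_total - k)
    n0 = (n_total - np.sum(sizes**2) / n_total) / (k - 1)
    v_b = max(0.0, (msb - msw) / n0)
    v_w = msw
    denom = v_b + v_w if inbred else v_b + 2 * v_w
    q = 0.0 if denom == 0 else v_b / denom
    return QstResult(v_b, v_w, q)


def qst_fst_quantile(q: float, fst_values) -> float:
    """Percentile of a Q_ST value within a per-SNP F_ST distribution.

    ``100 * (# F_ST values < q) / N`` over non-missing values.
    """
    v = np.asarray(fst_values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("empty F_ST distribution")
    return float(100.0 * np.mean(v < q))
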