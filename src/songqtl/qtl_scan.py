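"""Additive single-QTL genome scan over RIL ancestry-window genotypes.

The marker "genotype" at each genomic window is the dosage (0, 1 or 2) of one
parental strain's ancestry in a recombinant inbred line (RIL).  Because some
genotype classes are rare in many windows, the scan fits a purely additive
model: ordinary least squares of the trait on dosage.  The LOD score at a
window with n informative RILs is

    LOD = (n/2) * log10(RSS0 / RSS1) = -(n/2) * log10(1 - R^2),

where RSS0 is the intercept-only residual sum of squares (Haley-Knott-style
regression mapping).  Genome-wide significance comes from phenotype
permutations: the trait vector is shuffled across RILs, the full scan re-run,
and the maximum LOD recorded; the threshold is the empirical (1 - alpha)
quantile of the max-LOD distribution and the genome-wide p-value of an
observed peak is the fraction of permutation maxima at least as large.

Windows whose panel-wide ancestry proportion exceeds ``max_prop`` (default
0.90) for either parent carry almost no information and are masked from the
scan entirely.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_VAR_TOL = 1e-12


@dataclass
class AncestryGenotypeMatrix:
    """RIL x window dosage of FR-parent ancestry with window coordinates.

    ``windows`` is a DataFrame with columns ``arm``, ``start``, ``end``
    (0-based half-open bp), sorted and non-overlapping within an arm;
    ``dosage`` is float (NaN = missing call) with values in {0, 1, 2}.
    """

    windows: pd.DataFrame
    dosage: np.ndarray
    ril_ids: np.ndarray

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.ril_ids = np.asarray(self.ril_ids)
        if self.dosage.shape != (len(self.ril_ids), len(self.windows)):
            raise ValueError("dosage shape does not match (n_ril, n_window)")
        vals = self.dosage[~np.isnan(self.dosage)]
        if not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be in {0, 1, 2} or missing")

    @property
    def n_rils(self) -> int:
        return len(self.ril_ids)

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def ancestry_proportion(self) -> np.ndarray:
        """Panel-wide FR-ancestry proportion per window (mean dosage / 2)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def to_tsv(self, genotype_path, window_path) -> None:
        pd.DataFrame(self.dosage, index=self.ril_ids,
                     columns=[f"w{i}" for i in range(self.n_windows)]).to_csv(
            genotype_path, sep="\t", index_label="ril")
        self.windows.to_csv(window_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, genotype_path, window_path) -> "AncestryGenotypeMatrix":
        g = pd.read_csv(genotype_path, sep="\t", index_col="ril")
        w = pd.read_csv(window_path, sep="\t")
        return cls(w, g.values, g.index.values)


def mask_skewed_windows(G: AncestryGenotypeMatrix, max_prop: float = 0.90) -> np.ndarray:
    """Boolean mask of windows with panel ancestry skewed toward either parent.

    A window is masked iff its panel-wide ancestry proportion is strictly
    above ``max_prop`` for either parent (mean dosage/2 > max_prop or
    < 1 - max_prop); a proportion of exactly ``max_prop`` is retained.
    Raises if every window would be masked.
    """
    prop = G.ancestry_proportion
    mask = (prop > max_prop) | (prop < 1.0 - max_prop) | np.isnan(prop)
    if mask.all():
        raise ValueError("all windows masked as ancestry-skewed; nothing to scan")
    return mask


@dataclass
class LodProfile:
    """Per-window LOD scores with mask and (optionally) a genome-wide threshold."""

    windows: pd.DataFrame  # arm, start, end, lod, n, masked
    threshold: float | None = None
    perm_maxima: np.ndarray | None = None

    @property
    def lod(self) -> np.ndarray:
        return self.windows["lod"].values

    @property
    def masked(self) -> np.ndarray:
        return self.windows["masked"].values

    @property
    def significant(self) -> np.ndarray:
        if self.threshold is None:
            raise ValueError("no genome-wide threshold set on this profile")
        with np.errstate(invalid="ignore"):
            return ~self.masked & (np.nan_to_num(self.lod, nan=-np.inf) >= self.threshold)

    def to_tsv(self, path) -> None:
        out = self.windows.copy()
        if self.threshold is not None:
            out["significant"] = self.significant
        out.to_csv(path, sep="\t", index=False)


def _lod_columns(D: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """LOD score and sample size per column of D, pairwise-complete in y."""
    valid = ~np.isnan(D) & ~np.isnan(y)[:, None]
    n = valid.sum(axis=0).astype(float)
    D0 = np.where(valid, D, 0.0)
    Y0 = np.where(valid, y[:, None], 0.0)
    sd = D0.sum(axis=0)
    sy = Y0.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ssd = (D0 * D0).sum(axis=0) - sd * sd / n
        ssy = (Y0 * Y0).sum(axis=0) - sy * sy / n
        sxy = (D0 * Y0).sum(axis=0) - sd * sy / n
        r2 = np.where((ssd > _VAR_TOL) & (ssy > _VAR_TOL), sxy**2 / (ssd * ssy), 0.0)
    r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
    lod = np.where(n >= 3, -(n / 2.0) * np.log10(1.0 - r2), 0.0)
    return lod, n


def additive_lod_scan(
    G: AncestryGenotypeMatrix, y, mask: np.ndarray | None = None
) -> LodProfile:
    """Scan every unmasked window with the additive OLS model.

    ``y`` is aligned to the rows of ``G``; per window, RILs with a missing
    dosage or missing trait are dropped pairwise.  Windows with a single
    genotype class get LOD 0 with a warning; masked windows carry no LOD
    (NaN).
    """
    y = np.asarray(y, dtype=float)
    if len(y) != G.n_rils:
        raise ValueError("trait vector length does not match the RIL panel")
    if mask is None:
        mask = np.zeros(G.n_windows, dtype=bool)
    lod, n = _lod_columns(G.dosage, y)
    single = ~mask & (n >= 3)
    with np.errstate(invalid="ignore"):
        varless = np.array([
            np.nanstd(G.dosage[:, j][~np.isnan(y)]) < 1e-12 if single[j] else False
            for j in range(G.n_windows)
        ])
    if varless.any():
        logger.warning("%d windows with a single genotype class (LOD set to 0)",
                       int(varless.sum()))
    out = G.windows.copy()
    out["lod"] = np.where(mask, np.nan, lod)
    out["n"] = n.astype(int)
    out["masked"] = mask
    return LodProfile(out)


@dataclass
class PermutationScan:
    """Genome-wide max-LOD null distribution from phenotype permutations."""

    threshold: float
    maxima: np.ndarray
    alpha: float

    def genome_wide_p(self, peak_lod: float) -> float:
        """Fraction of permutation maxima >= an observed peak LOD."""
        return float(np.mean(self.maxima >= peak_lod))


def permutation_threshold(
    G: AncestryGenotypeMatrix,
    y,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int | None = None,
    mask: np.ndarray | None = None,
) -> PermutationScan:
    """Genome-wide LOD threshold from phenotype permutations.

    Shuffles strain-mean trait values across RILs, re-runs the full scan and
    records the max LOD over unmasked windows; the threshold is the empirical
    ``1 - alpha`` quantile of those maxima (``alpha=1`` gives the minimum).
    """
    if n_perm < 100:
        logger.warning("n_perm=%d permutations: threshold will be unstable", n_perm)
    y = np.asarray(y, dtype=float)
    if mask is None:
        mask = np.zeros(G.n_windows, dtype=bool)
    rng = np.random.default_rng(seed)
    D = G.dosage[:, ~mask]
    n_ril = G.n_rils
    complete = ~np.isnan(y)
    maxima = np.empty(n_perm)
    if not np.isnan(D).any() and complete.all():
        # fast path: correlations via one matrix product per batch
        Dc = D - D.mean(axis=0)
        dnorm = np.sqrt((Dc**2).sum(axis=0))
        informative = dnorm > _VAR_TOL
        Dn = Dc[:, informative] / dnorm[informative]
        perms = np.argsort(rng.random((n_perm, n_ril)), axis=1)
        Y = y[perms].T  # (n_ril, n_perm)
        Yc = Y - Y.mean(axis=0)
        ssy = (Yc**2).sum(axis=0)
        C = Dn.T @ Yc  # (n_windows, n_perm)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(ssy > _VAR_TOL, C**2 / ssy, 0.0)
        r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
        lod = -(n_ril / 2.0) * np.log10(1.0 - r2)
        maxima = lod.max(axis=0) if lod.size else np.zeros(n_perm)
    else:
        for i in range(n_perm):
            yp = y.copy()
            yp[complete] = rng.permutation(y[complete])
            lod, _ = _lod_columns(D, yp)
            maxima[i] = lod.max() if lod.size else 0.0
    threshold = float(np.quantile(maxima, 1.0 - alpha))
    return PermutationScan(threshold, maxima, alpha)


@dataclass
class EffectSize:
    """Additive QTL effect as a fraction of the parental strain difference."""

    fraction: float          # |2 beta| / |parent_fr - parent_zi|
    slope: float             # beta per dosage unit
    homozygote_diff: float   # 2 beta, the fitted FF - ZZ class difference
    direction: int           # +1 if FR ancestry shifts toward the FR parent


def qtl_effect_size(dosage, y, parent_fr: float, parent_zi: float) -> EffectSize:
    """Proportion of the parental trait difference explained by one window.

    Fits the additive slope beta of trait on dosage; the fitted homozygote
    contrast 2*beta is compared with the parental difference.  A zero
    parental difference is an error.
    """
    delta = parent_fr - parent_zi
    if delta == 0:
        raise ValueError("parental trait values are identical; effect size undefined")
    d = np.asarray(dosage, dtype=float)
    yv = np.asarray(y, dtype=float)
    ok = ~np.isnan(d) & ~np.isnan(yv)
    d, yv = d[ok], yv[ok]
    if np.ptp(d) == 0:
        raise ValueError("single genotype class; slope undefined")
    beta = float(np.polyfit(d, yv, 1)[0])
    homo = 2.0 * beta
    return EffectSize(abs(homo / delta), beta, homo,
                      int(np.sign(homo * delta)) if homo != 0 else 0)
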