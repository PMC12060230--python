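"""Residual trait construction for pairs of correlated traits.

When two correlated traits map to overlapping QTLs, the overlap may reflect
pleiotropy of a single locus.  To test this, the trait with the *smaller*
peak LOD (the "secondary" trait) is regressed on the trait with the greater
peak LOD (the "primary"), and the residuals -- the RIL variation in the
secondary trait not explained by the primary -- are fed back through the
standard scan with a fresh permutation threshold.  A shared-QTL signal that
is fully mediated by the primary trait disappears from the residual scan; an
independent QTL of the secondary trait survives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .qtl_scan import (AncestryGenotypeMatrix, LodProfile, PermutationScan,
                       additive_lod_scan, permutation_threshold)


@dataclass
class ResidualTrait:
    """Residuals of a secondary trait after OLS adjustment for a primary one.

    ``values`` is aligned to the input vectors, with NaN where either trait
    was missing.  Residuals sum to ~0 over the complete cases and are exactly
    uncorrelated with the primary trait.
    """

    values: np.ndarray
    slope: float
    intercept: float
    primary: str = "primary"
    secondary: str = "secondary"
    n: int = 0


def residualize(y_secondary, y_primary, names: tuple[str, str] | None = None) -> ResidualTrait:
    """OLS residuals of the secondary trait on the primary trait.

    Pairwise-complete cases are used; a constant primary trait raises (the
    slope is undefined).  The caller is responsible for designating the
    primary trait as the one with the greater QTL peak LOD; when the two peak
    LODs tie, an explicit user choice is required.
    """
    ys = np.asarray(y_secondary, dtype=float)
    yp = np.asarray(y_primary, dtype=float)
    if ys.shape != yp.shape:
        raise ValueError("trait vectors must be aligned on the same RILs")
    ok = ~np.isnan(ys) & ~np.isnan(yp)
    if np.ptp(yp[ok]) == 0:
        raise ValueError("primary trait is constant; regression slope undefined")
    fit = stats.linregress(yp[ok], ys[ok])
    resid = np.full_like(ys, np.nan)
    resid[ok] = ys[ok] - (fit.intercept + fit.slope * yp[ok])
    a, b = names if names is not None else ("primary", "secondary")
    return ResidualTrait(resid, float(fit.slope), float(fit.intercept),
                         primary=a, secondary=b, n=int(ok.sum()))


def residual_scan(
    G: AncestryGenotypeMatrix,
    y_secondary,
    y_primary,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    mask: np.ndarray | None = None,
) -> tuple[ResidualTrait, LodProfile, PermutationScan]:
    """Residualize then re-run the standard scan with a fresh threshold."""
    res = residualize(y_secondary, y_primary)
    profile = additive_lod_scan(G, res.values, mask=mask)
    perm = permutation_threshold(G, res.values, n_perm=n_perm, alpha=alpha,
                                 seed=seed, mask=mask)
    profile.threshold = perm.threshold
    profile.perm_maxima = perm.maxima
    return res, profile, perm
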