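"""Window-based population differentiation statistics over QTL intervals.

Three statistics per genomic window, computed from two haplotype panels
(e.g. Zambia vs France genomes):

* ``fst_fullwin`` -- Hudson-form F_ST over all variable sites in the window,
  as a ratio of summed per-site numerators to summed denominators
  (ratio-of-averages, stable for low-frequency sites).
* ``fst_maxsnp`` -- the maximum defined per-site F_ST in the window.
* ``chi_md`` -- comparative haplotype identity: the mean (over haplotype
  pairs within a population) of summed identical-tract lengths in bp,
  contrasted between the putatively selected population (population 1) and
  the reference population.  Local sweeps inflate shared haplotype lengths
  in the swept population, pushing chi_MD above 1.

Per-site F_ST uses the Hudson estimator

    num = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)

with sample sizes taken from the non-missing haplotype counts at the site.
Windows are ranked per chromosome arm, and a window is a differentiation
outlier if any of the three statistics reaches the top ``q`` (default 1%)
quantile on its arm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1


@dataclass
class HaplotypePanel:
    """Binary haplotype matrix (haplotypes x biallelic SNP sites) for one arm.

    ``haplotypes`` holds alleles in {0, 1} with -1 for missing;
    ``positions`` are strictly increasing 1-based bp coordinates.
    """

    haplotypes: np.ndarray
    positions: np.ndarray
    arm: str = "3R"

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[1] != len(self.positions):
            raise ValueError("haplotype matrix does not match the positions vector")
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("site positions must be strictly increasing")
        if not np.isin(self.haplotypes, (0, 1, MISSING)).all():
            raise ValueError("alleles must be 0, 1 or -1 (missing)")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    def site_slice(self, start: int, end: int) -> slice:
        """Sites falling in a 0-based half-open [start, end) bp window."""
        lo = int(np.searchsorted(self.positions, start + 1))
        hi = int(np.searchsorted(self.positions, end, side="right"))
        return slice(lo, hi)

    def allele_counts(self, sl: slice | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(derived allele count, non-missing sample size) per site."""
        H = self.haplotypes if sl is None else self.haplotypes[:, sl]
        called = H != MISSING
        return (H == 1).sum(axis=0), called.sum(axis=0)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.haplotypes,
                          columns=[str(p) for p in self.positions])
        df.insert(0, "haplotype", [f"h{i}" for i in range(self.n_haplotypes)])
        with open(path, "w") as fh:
            fh.write(f"#arm={self.arm}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "HaplotypePanel":
        with open(path) as fh:
            first = fh.readline().strip()
            arm = first.split("=", 1)[1] if first.startswith("#arm=") else "3R"
            df = pd.read_csv(fh, sep="\t")
        pos = np.array([int(c) for c in df.columns[1:]])
        return cls(df.iloc[:, 1:].values, pos, arm)

    @classmethod
    def from_vcf(cls, path, arm: str | None = None) -> "HaplotypePanel":
        """Read biallelic SNPs from a VCF; diploid samples contribute both
        alleles as separate (pseudo-)haplotypes, haploid calls one."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        rows, positions, chrom = [], [], arm
        for v in vcf:
            if len(v.ALT) != 1 or not v.is_snp:
                continue
            if chrom is None:
                chrom = v.CHROM
            if v.CHROM != chrom:
                continue
            alleles = []
            for gt in v.genotypes:
                calls = gt[:-1]  # last entry is the phased flag
                alleles.extend(MISSING if c < 0 else int(c) for c in calls)
            rows.append(alleles)
            positions.append(v.POS)
        if not rows:
            raise ValueError(f"no biallelic SNPs found in {path}")
        return cls(np.array(rows, dtype=np.int8).T, np.array(positions), chrom or "3R")


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

@dataclass
class SiteFst:
    num: float
    den: float

    @property
    def fst(self) -> float:
        return self.num / self.den if self.den > 0 else np.nan


def _fst_components(c1, n1, c2, n2) -> tuple[np.ndarray, np.ndarray]:
    c1, n1, c2, n2 = (np.asarray(x, dtype=float) for x in (c1, n1, c2, n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        p1, p2 = c1 / n1, c2 / n2
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    bad = (n1 < 2) | (n2 < 2)
    num = np.where(bad, np.nan, num)
    den = np.where(bad, np.nan, den)
    return num, den


def site_fst(count1: int, n1: int, count2: int, n2: int) -> SiteFst:
    """Hudson-form per-site F_ST from derived-allele counts.

    Returns the (numerator, denominator) pair; the ratio is undefined (NaN)
    for sites monomorphic for the same allele in both populations (den = 0),
    which are excluded from window summaries.  Sample sizes below 2 raise.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("site_fst requires at least 2 sampled alleles per population")
    if not (0 <= count1 <= n1 and 0 <= count2 <= n2):
        raise ValueError("allele counts must lie within [0, n]")
    num, den = _fst_components(count1, n1, count2, n2)
    return SiteFst(float(num), float(den))


def _window_components(panel1: HaplotypePanel, panel2: HaplotypePanel,
                       start: int, end: int) -> tuple[np.ndarray, np.ndarray]:
    sl1 = panel1.site_slice(start, end)
    sl2 = panel2.site_slice(start, end)
    if (sl1.start, sl1.stop) != (sl2.start, sl2.stop):
        raise ValueError("panels must share the same site list")
    c1, n1 = panel1.allele_counts(sl1)
    c2, n2 = panel2.allele_counts(sl1)
    num, den = _fst_components(c1, n1, c2, n2)
    usable = np.isfinite(den) & (den > 0)
    return num[usable], den[usable]


def window_fst_full(panel1: HaplotypePanel, panel2: HaplotypePanel,
                    start: int, end: int) -> float:
    """Ratio-of-averages Hudson F_ST over all variable sites in a window."""
    num, den = _window_components(panel1, panel2, start, end)
    if den.size == 0:
        return np.nan
    return float(num.sum() / den.sum())


def window_fst_maxsnp(panel1: HaplotypePanel, panel2: HaplotypePanel,
                      start: int, end: int) -> float:
    """Maximum defined per-site F_ST within a window."""
    num, den = _window_components(panel1, panel2, start, end)
    if den.size == 0:
        return np.nan
    return float((num / den).max())


def site_fst_distribution(
    panel1: HaplotypePanel,
    panel2: HaplotypePanel,
    n1: int | None = None,
    n2: int | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Per-site F_ST ratios genome-wide, optionally downsampled.

    When ``n1``/``n2`` are given, allele counts are hypergeometrically
    downsampled to those haploid sample sizes -- used to match the F_ST
    distribution to the allelic sample sizes of a phenotyped strain panel
    before comparing with Q_ST.  Undefined sites are dropped.
    """
    c1, m1 = panel1.allele_counts()
    c2, m2 = panel2.allele_counts()
    rng = np.random.default_rng(seed)
    if n1 is not None:
        keep = m1 >= n1
        c1 = np.where(keep, rng.hypergeometric(c1, m1 - c1, np.minimum(n1, m1)), 0)
        m1 = np.where(keep, n1, 0)
    if n2 is not None:
        keep = m2 >= n2
        c2 = np.where(keep, rng.hypergeometric(c2, m2 - c2, np.minimum(n2, m2)), 0)
        m2 = np.where(keep, n2, 0)
    num, den = _fst_components(c1, m1, c2, m2)
    ok = np.isfinite(den) & (den > 0)
    return (num[ok] / den[ok])


# ---------------------------------------------------------------------------
# Comparative haplotype identity (chi_MD)
# ---------------------------------------------------------------------------

def _pair_identity_bp(a: np.ndarray, b: np.ndarray, pos: np.ndarray,
                      wstart: int, wend: int, max_missing_frac: float) -> float:
    """Summed identical-tract length (bp) for one haplotype pair.

    Maximal runs of identical compared sites: a multi-site run spans from its
    first to its last site; a single-site run gets the inter-site midpoint
    span (window edges at the boundaries).  Sites missing in either haplotype
    are skipped without breaking runs.  Returns NaN when more than
    ``max_missing_frac`` of the window's sites are missing for the pair.
    """
    valid = (a != MISSING) & (b != MISSING)
    if pos.size and 1.0 - valid.mean() > max_missing_frac:
        return np.nan
    vpos = pos[valid]
    if vpos.size == 0:
        return 0.0
    eq = a[valid] == b[valid]
    idx = np.flatnonzero(eq)
    if idx.size == 0:
        return 0.0
    gaps = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[gaps + 1]))
    ends = np.concatenate((idx[gaps], [idx[-1]]))
    multi = ends > starts
    total = float((vpos[ends[multi]] - vpos[starts[multi]]).sum())
    singles = starts[~multi]
    if singles.size:
        left = np.where(singles > 0,
                        (vpos[np.maximum(singles - 1, 0)] + vpos[singles]) / 2.0,
                        float(wstart))
        right = np.where(singles < vpos.size - 1,
                         (vpos[singles] + vpos[np.minimum(singles + 1, vpos.size - 1)]) / 2.0,
                         float(wend))
        total += float((right - left).sum())
    return total


def _pairs_identity_fast(H: np.ndarray, pos: np.ndarray, wstart: int, wend: int,
                         i_idx: np.ndarray, j_idx: np.ndarray) -> np.ndarray:
    """Vectorised summed identical-tract lengths for many pairs (no missing).

    For each pair the contribution of a multi-site run is pos[last] -
    pos[first] -- accumulated as (sum over run ends) - (sum over run starts)
    -- and a single-site run (start == end) instead gets the span between the
    midpoints of its flanking inter-site gaps.
    """
    E = H[i_idx] == H[j_idx]  # (n_pairs, n_sites)
    pad = np.zeros((E.shape[0], 1), dtype=bool)
    starts = E & ~np.hstack([pad, E[:, :-1]])
    ends = E & ~np.hstack([E[:, 1:], pad])
    single = starts & ends
    posf = pos.astype(float)
    left = np.empty_like(posf)
    right = np.empty_like(posf)
    left[0], left[1:] = float(wstart), (posf[:-1] + posf[1:]) / 2.0
    right[-1], right[:-1] = float(wend), (posf[:-1] + posf[1:]) / 2.0
    total = (ends * posf).sum(axis=1) - (starts * posf).sum(axis=1)
    return total + (single * (right - left)).sum(axis=1)


def _population_identity(panel: HaplotypePanel, start: int, end: int,
                         max_missing_frac: float, max_pairs: int | None,
                         rng: np.random.Generator | None) -> float:
    sl = panel.site_slice(start, end)
    H = panel.haplotypes[:, sl]
    pos = panel.positions[sl]
    pairs = list(combinations(range(panel.n_haplotypes), 2))
    if max_pairs is not None and len(pairs) > max_pairs:
        r = rng if rng is not None else np.random.default_rng()
        pairs = [pairs[i] for i in r.choice(len(pairs), max_pairs, replace=False)]
    if pos.size == 0:
        return 0.0
    if not (H == MISSING).any():
        i_idx = np.array([p[0] for p in pairs])
        j_idx = np.array([p[1] for p in pairs])
        return float(_pairs_identity_fast(H, pos, start, end, i_idx, j_idx).mean())
    vals = [_pair_identity_bp(H[i], H[j], pos, start, end, max_missing_frac)
            for i, j in pairs]
    vals = [v for v in vals if not np.isnan(v)]
    return float(np.mean(vals)) if vals else np.nan


def window_chi_md(
    panel1: HaplotypePanel,
    panel2: HaplotypePanel,
    start: int,
    end: int,
    max_missing_frac: float = 0.5,
    max_pairs: int | None = None,
    seed: int | None = None,
) -> float:
    """Comparative haplotype identity for one window.

    ``panel1`` is the putatively selected (derived-range) population; the
    statistic is the ratio of its mean pairwise identical-tract length to
    that of ``panel2``.  A zero reference identity yields +inf.  Both panels
    need at least two haplotypes.
    """
    if panel1.n_haplotypes < 2 or panel2.n_haplotypes < 2:
        raise ValueError("chi_MD requires at least 2 haplotypes per population")
    rng = np.random.default_rng(seed) if max_pairs is not None else None
    i1 = _population_identity(panel1, start, end, max_missing_frac, max_pairs, rng)
    i2 = _population_identity(panel2, start, end, max_missing_frac, max_pairs, rng)
    if np.isnan(i1) or np.isnan(i2):
        return np.nan
    if i2 == 0:
        logger.warning("reference population identity is 0 in [%d, %d); chi_MD set to inf",
                       start, end)
        return np.inf
    return i1 / i2


# ---------------------------------------------------------------------------
# Window table and outlier calls
# ---------------------------------------------------------------------------

def windows_stats(
    panel1: HaplotypePanel,
    panel2: HaplotypePanel,
    windows: pd.DataFrame,
    max_missing_frac: float = 0.5,
    max_pairs: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """All three statistics for every window of a BED-like frame."""
    rows = []
    for _, w in windows.iterrows():
        s, e = int(w["start"]), int(w["end"])
        rows.append((
            w.get("arm", panel1.arm), s, e,
            window_fst_full(panel1, panel2, s, e),
            window_fst_maxsnp(panel1, panel2, s, e),
            window_chi_md(panel1, panel2, s, e, max_missing_frac, max_pairs, seed),
        ))
    return pd.DataFrame(rows, columns=["arm", "start", "end",
                                       "fst_fullwin", "fst_maxsnp", "chi_md"])


STAT_COLUMNS = ("fst_fullwin", "fst_maxsnp", "chi_md")


def arm_outliers(stats: pd.DataFrame, q: float = 0.01,
                 min_windows: int = 100) -> pd.DataFrame:
    """Per-arm quantile ranks and top-q outlier flags for each statistic.

    A window is flagged for a statistic when its value is at or above the
    empirical ``1 - q`` quantile of that statistic on the arm (so an arm
    where every value ties flags every window).  ``outlier_any`` marks
    windows flagged for any of the three statistics.
    """
    out = stats.copy()
    for col in STAT_COLUMNS:
        out[f"rank_{col}"] = np.nan
        out[f"outlier_{col}"] = False
    for arm, idx in out.groupby("arm").groups.items():
        if len(idx) < min_windows:
            logger.warning("arm %s has only %d windows; quantiles will be coarse",
                           arm, len(idx))
        for col in STAT_COLUMNS:
            v = out.loc[idx, col].astype(float)
            finite = v[np.isfinite(v)]
            if finite.empty:
                continue
            capped = v.replace(np.inf, finite.max() + 1.0)
            ranks = capped.rank(method="max", pct=True)
            out.loc[idx, f"rank_{col}"] = ranks
            thr = np.quantile(capped.dropna(), 1.0 - q)
            out.loc[idx, f"outlier_{col}"] = (capped >= thr).fillna(False)
    out["outlier_any"] = out[[f"outlier_{c}" for c in STAT_COLUMNS]].any(axis=1)
    return out
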