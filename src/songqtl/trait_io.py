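"""Recording-level courtship-song trait tables.

A *recording* is one 30-minute assay of a single male paired with a female;
automated segmentation software reduces it to ~37 named quantitative traits
(counts per minute, durations, carrier frequencies in Hz, transition
probabilities, amplitudes in arbitrary units) plus two bookkeeping rates:
seconds of song per minute and total seconds of sine song.  This module loads
such tables, applies the study's replicate exclusion rules, collapses
replicates to strain-level trait means, and computes trait-trait Pearson
correlations among strains.

Filtering rules
---------------
A recording is retained iff it produced at least ``min_song`` seconds of song
per minute (default 1; very quiet assays carry no usable signal) AND no more
than ``max_sine`` total seconds of sine song (default 55; aberrantly high sine
rates indicate an equipment failure).  Boundary values are retained.
Separately, when computing a strain's mean for a given trait, replicates with
a *zero* value for that trait are dropped for that trait only -- a zero is the
segmentation software's way of signalling that the trait could not be
measured, not a genuine measurement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Non-trait columns of a recordings table.
MANDATORY_COLUMNS = ("strain", "cohort", "replicate")
RATE_COLUMNS = ("song_per_min", "sine_total")
META_COLUMNS = MANDATORY_COLUMNS + ("assay_day",) + RATE_COLUMNS

COHORTS = ("FR", "ZI", "RIL", "parental")

#: Correlation significance tiers (threshold on the raw p-value, label).
CORRELATION_TIERS = ((1e-9, "1e-9"), (1e-6, "1e-6"), (1e-3, "1e-3"), (0.05, "0.05"))


def trait_columns(df: pd.DataFrame) -> list[str]:
    """Names of the trait columns of a recordings table (order preserved)."""
    return [c for c in df.columns if c not in META_COLUMNS]


def load_recordings(path) -> pd.DataFrame:
    """Load a tab-separated recordings file (one row per recording).

    The header must name ``strain``, ``cohort`` and ``replicate`` plus the two
    rate columns ``song_per_min`` and ``sine_total``; every other column
    (except optional ``assay_day``) is treated as a trait.  Unparseable
    numeric cells become missing values with a logged warning; missing
    mandatory columns raise :class:`ValueError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MANDATORY_COLUMNS + RATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"recordings file {path!r} lacks mandatory columns: {missing}")
    numeric_cols = list(RATE_COLUMNS) + trait_columns(df)
    n_bad = 0
    for col in numeric_cols:
        raw = df[col]
        coerced = pd.to_numeric(raw, errors="coerce")
        bad = coerced.isna() & raw.notna() & (raw.str.strip() != "")
        n_bad += int(bad.sum())
        df[col] = coerced
    if n_bad:
        logger.warning("%d unparseable numeric cells set to missing while reading %s", n_bad, path)
    return df


def write_recordings(df: pd.DataFrame, path) -> None:
    """Write a recordings table as TSV (inverse of :func:`load_recordings`)."""
    df.to_csv(path, sep="\t", index=False)


def filter_recordings(
    df: pd.DataFrame, min_song: float = 1.0, max_sine: float = 55.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the replicate exclusion rules.

    Returns ``(retained, report)`` where ``report`` has one row per excluded
    recording with the rule(s) that fired (``low_song``, ``high_sine``).  A
    missing rate value fails the corresponding retention check.  The function
    is idempotent and ``len(retained) + len(report) == len(df)``.
    """
    song = df["song_per_min"]
    sine = df["sine_total"]
    ok_song = song >= min_song  # NaN compares False -> excluded
    ok_sine = sine <= max_sine
    keep = ok_song & ok_sine

    rules = []
    for i in df.index[~keep]:
        fired = []
        if not ok_song.loc[i]:
            fired.append("low_song")
        if not ok_sine.loc[i]:
            fired.append("high_sine")
        rules.append(",".join(fired))
    report = df.loc[~keep, list(MANDATORY_COLUMNS) + list(RATE_COLUMNS)].copy()
    report["rule"] = rules
    return df.loc[keep].copy(), report.reset_index(drop=True)


@dataclass
class StrainTraitTable:
    """Strain x trait matrix of replicate means with population labels.

    ``means`` holds, per strain and trait, the mean over retained replicates
    with a nonzero, non-missing value; the matching ``counts`` entry is the
    number of replicates that contributed.  A cell is missing iff no replicate
    qualified.
    """

    means: pd.DataFrame
    counts: pd.DataFrame
    cohort: pd.Series

    @property
    def strains(self) -> pd.Index:
        return self.means.index

    @property
    def traits(self) -> pd.Index:
        return self.means.columns

    def subset(self, cohorts) -> "StrainTraitTable":
        if isinstance(cohorts, str):
            cohorts = (cohorts,)
        sel = self.cohort.isin(cohorts)
        idx = self.means.index[sel]
        return StrainTraitTable(
            self.means.loc[idx], self.counts.loc[idx], self.cohort.loc[idx]
        )

    def trait_vector(self, trait: str, cohorts=None) -> pd.Series:
        t = self if cohorts is None else self.subset(cohorts)
        return t.means[trait]

    def to_tsv(self, path, counts_path=None) -> None:
        out = self.means.copy()
        out.insert(0, "cohort", self.cohort)
        out.to_csv(path, sep="\t", index_label="strain")
        if counts_path is not None:
            self.counts.to_csv(counts_path, sep="\t", index_label="strain")

    @classmethod
    def from_tsv(cls, path, counts_path=None) -> "StrainTraitTable":
        df = pd.read_csv(path, sep="\t", index_col="strain")
        cohort = df.pop("cohort")
        if counts_path is not None:
            counts = pd.read_csv(counts_path, sep="\t", index_col="strain")
        else:
            counts = df.notna().astype(int)
        return cls(df, counts, cohort)


def strain_trait_means(records: pd.DataFrame) -> StrainTraitTable:
    """Collapse (already filtered) recordings to per-strain trait means.

    Zero trait values are excluded per trait; missing values propagate as
    missing.  Duplicate ``(strain, replicate)`` keys are a hard error.
    """
    dup = records.duplicated(subset=["strain", "replicate"])
    if dup.any():
        keys = records.loc[dup, ["strain", "replicate"]].values.tolist()
        raise ValueError(f"duplicate (strain, replicate) keys: {keys[:5]}")
    traits = trait_columns(records)
    vals = records[traits].where(records[traits] != 0)  # zeros -> NaN, per trait
    grouped = vals.groupby(records["strain"])
    means = grouped.mean()
    counts = grouped.count()
    cohort = records.groupby("strain")["cohort"].agg(
        lambda s: s.iloc[0] if s.nunique() == 1 else (_ for _ in ()).throw(
            ValueError(f"conflicting cohort labels for strain {s.name!r}")
        )
    )
    return StrainTraitTable(means, counts.astype(int), cohort.loc[means.index])


def _tier(p: float) -> str:
    if not np.isfinite(p):
        return "nc"
    for thr, label in CORRELATION_TIERS:
        if p < thr:
            return label
    return "none"


@dataclass
class CorrelationResult:
    """Pairwise Pearson correlations among strains for every trait pair."""

    r: pd.DataFrame
    p: pd.DataFrame
    tier: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        rows = []
        traits = list(self.r.columns)
        for i, a in enumerate(traits):
            for b in traits[i + 1:]:
                rows.append((a, b, self.r.loc[a, b], self.p.loc[a, b], self.tier.loc[a, b]))
        return pd.DataFrame(rows, columns=["trait_a", "trait_b", "r", "p", "tier"])


def trait_correlations(
    table: StrainTraitTable, cohort=None, min_pairs: int = 3
) -> CorrelationResult:
    """Pairwise-complete Pearson correlations between traits across strains.

    Cells with fewer than ``min_pairs`` complete strain pairs, or with a
    constant trait, are flagged not-computable (``r`` NaN, tier ``"nc"``).
    The diagonal is exact unity with the strongest tier.
    """
    t = table if cohort is None else table.subset(cohort)
    X = t.means
    traits = list(X.columns)
    n = len(traits)
    r = np.full((n, n), np.nan)
    p = np.full((n, n), np.nan)
    for i in range(n):
        r[i, i], p[i, i] = 1.0, 0.0
        for j in range(i + 1, n):
            pair = X[[traits[i], traits[j]]].dropna()
            if len(pair) < min_pairs:
                continue
            x, y = pair.iloc[:, 0].values, pair.iloc[:, 1].values
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            res = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    tier = np.vectorize(_tier)(p)
    idx = pd.Index(traits)
    return CorrelationResult(
        pd.DataFrame(r, idx, idx), pd.DataFrame(p, idx, idx), pd.DataFrame(tier, idx, idx)
    )
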