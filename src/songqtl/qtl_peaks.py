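"""QTL region calling from a LOD profile.

Turns a per-window LOD landscape into discrete QTL regions:

1. *Runs*: maximal stretches of consecutive unmasked windows with LOD at or
   above the genome-wide threshold.  Adjacency is evaluated within a
   chromosome by default, so a run (or a merged region) may span the
   centromere between the left and right arms.
2. *Merging*: two adjacent runs are merged when the valley between them never
   drops to (or below) the shorter run's maximum LOD minus 1.5 -- a plain
   1.5-LOD support interval for the shorter peak would engulf the taller one.
   Applied left-to-right and iterated to a fixed point.
3. *Confidence intervals*: within a region with maximum LOD M, the windows
   with LOD strictly greater than M - 1.5 "qualify".  The *inclusive* CI is
   the contiguous bp span from the leftmost to the rightmost qualifying
   window (it may contain non-qualifying windows); the *restrictive* CI is
   the possibly noncontiguous set of maximal runs of qualifying windows --
   the sub-intervals most likely to contain the causative locus.
4. *Mask extension*: when a CI boundary abuts windows excluded for ancestry
   skew, the CI is extended across the masked stretch, absorbing any
   qualifying unmasked windows encountered, and stops just before the first
   unmasked window that fails the qualification criterion.

All "greater than" comparisons are strict, and ties at the maximum LOD are
broken toward the leftmost window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qtl_scan import LodProfile

logger = logging.getLogger(__name__)

DEFAULT_LOD_DROP = 1.5


def _group_labels(profile: LodProfile, group_by: str = "chromosome") -> np.ndarray:
    """Window grouping used for adjacency (chromosome spans the centromere)."""
    arms = profile.windows["arm"].astype(str)
    if group_by == "arm":
        return arms.values
    if group_by == "chromosome":
        return arms.str.replace(r"[LR]$", "", regex=True).values
    raise ValueError(f"unknown group_by: {group_by!r}")


def significant_regions(
    profile: LodProfile, threshold: float | None = None, group_by: str = "chromosome"
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive unmasked windows with LOD >= threshold.

    Returns inclusive ``(first, last)`` window-index pairs in genome order.
    Masked windows and group boundaries break runs.
    """
    thr = profile.threshold if threshold is None else threshold
    if thr is None:
        raise ValueError("no LOD threshold available")
    groups = _group_labels(profile, group_by)
    lod = np.nan_to_num(profile.lod, nan=-np.inf)
    sig = ~profile.masked & (lod >= thr)
    runs: list[tuple[int, int]] = []
    start = None
    for i in range(len(sig) + 1):
        boundary = i == len(sig) or not sig[i] or (start is not None and groups[i] != groups[start])
        if start is not None and boundary:
            runs.append((start, i - 1))
            start = None
        if i < len(sig) and sig[i] and start is None:
            start = i
    return runs


def _valley_min(profile: LodProfile, left_end: int, right_start: int) -> float:
    """Minimum LOD over unmasked windows strictly between two runs.

    An all-masked gap has no defined valley and is treated as +inf (the runs
    merge; the masked stretch is bridged).
    """
    between = profile.lod[left_end + 1 : right_start]
    between = between[~np.isnan(between)]
    return float(between.min()) if between.size else np.inf


def merge_regions(
    runs: list[tuple[int, int]],
    profile: LodProfile,
    drop: float = DEFAULT_LOD_DROP,
    group_by: str = "chromosome",
) -> list[tuple[int, int]]:
    """Merge adjacent runs whose separating valley stays within ``drop`` LOD
    of the shorter run's maximum.  Idempotent; region count never increases.
    """
    groups = _group_labels(profile, group_by)
    lod = np.nan_to_num(profile.lod, nan=-np.inf)

    def run_max(r):
        return lod[r[0] : r[1] + 1].max()

    merged = list(runs)
    changed = True
    while changed:
        changed = False
        out: list[tuple[int, int]] = []
        i = 0
        while i < len(merged):
            cur = merged[i]
            while i + 1 < len(merged) and groups[merged[i + 1][0]] == groups[cur[0]]:
                nxt = merged[i + 1]
                vmin = _valley_min(profile, cur[1], nxt[0])
                if vmin > min(run_max(cur), run_max(nxt)) - drop:
                    cur = (cur[0], nxt[1])
                    i += 1
                    changed = True
                else:
                    break
            out.append(cur)
            i += 1
        merged = out
    return merged


def confidence_intervals(
    run: tuple[int, int], profile: LodProfile, drop: float = DEFAULT_LOD_DROP
) -> tuple[tuple[int, int], list[tuple[int, int]]]:
    """Inclusive and restrictive CIs of a region, as window-index spans.

    Qualifying windows have LOD strictly greater than (region max - drop).
    The inclusive CI is the span from the first to the last qualifying
    window; the restrictive CI is the list of maximal qualifying runs
    (masked windows inside a merged/extended region are bridged: they break
    neither span).
    """
    i, j = run
    lod = profile.lod[i : j + 1]
    finite = np.nan_to_num(lod, nan=-np.inf)
    max_lod = finite.max()
    qual = np.flatnonzero(finite > max_lod - drop) + i
    inclusive = (int(qual[0]), int(qual[-1]))
    qual_set = set(qual.tolist())
    segments: list[tuple[int, int]] = []
    masked = profile.masked
    seg_start = None
    prev_q = None
    for w in range(inclusive[0], inclusive[1] + 1):
        if masked[w]:
            continue  # bridged, breaks nothing
        if w in qual_set:
            if seg_start is None:
                seg_start = w
            prev_q = w
        else:
            if seg_start is not None:
                segments.append((seg_start, prev_q))
                seg_start = None
    if seg_start is not None:
        segments.append((seg_start, prev_q))
    return inclusive, segments


def extend_through_masked(
    ci: tuple[int, int],
    profile: LodProfile,
    max_lod: float,
    drop: float = DEFAULT_LOD_DROP,
    group_by: str = "chromosome",
) -> tuple[int, int]:
    """Extend a CI whose boundary abuts masked (ancestry-skewed) windows.

    Walks outward across the masked stretch; a qualifying unmasked window
    (LOD > max_lod - drop) is absorbed and the walk continues, while the
    first non-qualifying unmasked window stops the walk and is excluded.  A
    masked stretch reaching the chromosome end extends the CI to the end
    with a warning.
    """
    groups = _group_labels(profile, group_by)
    lod = np.nan_to_num(profile.lod, nan=-np.inf)
    masked = profile.masked
    lo, hi = ci
    cutoff = max_lod - drop

    def walk(edge: int, step: int) -> int:
        k = edge + step
        n = len(lod)
        if not (0 <= k < n) or groups[k] != groups[edge] or not masked[k]:
            return edge  # extension only triggers on an adjacent masked window
        pos = edge
        while 0 <= k < n and groups[k] == groups[edge]:
            if masked[k]:
                pos = k
            elif lod[k] > cutoff:
                pos = k
            else:
                return pos
            k += step
        logger.warning("masked stretch reaches chromosome end; CI extended to the end")
        return pos

    return (walk(lo, -1), walk(hi, +1))


@dataclass
class QtlRegion:
    """One merged significant QTL region with its support intervals."""

    arm: str
    peak_index: int
    peak_bp: int
    max_lod: float
    span: tuple[int, int]
    inclusive_ci: tuple[int, int]             # window indices
    inclusive_ci_bp: tuple[int, int]          # 0-based half-open bp span
    restrictive_ci: list[tuple[int, int]]
    restrictive_ci_bp: list[tuple[int, int]]
    genome_wide_p: float | None = None
    effect: float | None = None


def call_qtl_regions(
    profile: LodProfile,
    threshold: float | None = None,
    drop: float = DEFAULT_LOD_DROP,
    group_by: str = "chromosome",
    extend: bool = True,
) -> list[QtlRegion]:
    """Full pipeline: runs -> merging -> CIs -> masked-window extension."""
    thr = profile.threshold if threshold is None else threshold
    runs = significant_regions(profile, thr, group_by)
    regions = merge_regions(runs, profile, drop, group_by)
    lod = np.nan_to_num(profile.lod, nan=-np.inf)
    win = profile.windows
    out = []
    for run in regions:
        seg_lod = lod[run[0] : run[1] + 1]
        max_lod = float(seg_lod.max())
        peak = int(run[0] + np.argmax(seg_lod))  # leftmost max
        inclusive, restrictive = confidence_intervals(run, profile, drop)
        if extend:
            extended = extend_through_masked(inclusive, profile, max_lod, drop, group_by)
            if extended != inclusive:
                inclusive = extended
                _, restrictive = confidence_intervals(extended, profile, drop)
        inc_bp = (int(win["start"].iloc[inclusive[0]]), int(win["end"].iloc[inclusive[1]]))
        res_bp = [(int(win["start"].iloc[a]), int(win["end"].iloc[b])) for a, b in restrictive]
        out.append(
            QtlRegion(
                arm=str(win["arm"].iloc[peak]),
                peak_index=peak,
                peak_bp=int((win["start"].iloc[peak] + win["end"].iloc[peak]) // 2),
                max_lod=max_lod,
                span=run,
                inclusive_ci=inclusive,
                inclusive_ci_bp=inc_bp,
                restrictive_ci=restrictive,
                restrictive_ci_bp=res_bp,
                genome_wide_p=(
                    float(np.mean(profile.perm_maxima >= max_lod))
                    if profile.perm_maxima is not None else None
                ),
            )
        )
    return out


def regions_to_bed(regions: list[QtlRegion], profile: LodProfile,
                   which: str = "inclusive") -> pd.DataFrame:
    """QTL CIs as a 0-based half-open BED-like frame, sorted per arm."""
    rows = []
    win = profile.windows
    for k, reg in enumerate(regions):
        if which == "inclusive":
            spans = [(reg.inclusive_ci, reg.inclusive_ci_bp)]
        elif which == "restrictive":
            spans = list(zip(reg.restrictive_ci, reg.restrictive_ci_bp))
        else:
            raise ValueError(f"unknown CI kind {which!r}")
        for (a, b), (s, e) in spans:
            rows.append((str(win["arm"].iloc[a]), s, e, f"qtl{k}", reg.max_lod))
    bed = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
    return bed.sort_values(["chrom", "start"]).reset_index(drop=True)
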