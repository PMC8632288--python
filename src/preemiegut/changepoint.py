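"""Succession timing via nonparametric change-point detection.

The procedure: taxa whose abundance varies with postmenstrual age (per the
mixed models) are selected; for each (taxon, group) a weekly mean
percent-abundance trajectory over PMA weeks 24-36 is built (contributing
patients only, missing weeks linearly interpolated); change points are
detected by PELT with the empirical-distribution (ED) nonparametric cost,
with the penalty chosen automatically from the elbow of the
penalty-vs-number-of-change-points path; finally change points are tallied
by PMA week across taxa, and the week collecting the most change points is
called the key succession time point.

A change point tau (the number of observations in the left segment) is
tallied under the first week of the *new* regime, i.e. a shift in mean
abundance "at week w" contributes a tally at w.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_stats import LmmResult, bh_adjust
from .data_model import HcgGroup, SampleRecord

__all__ = [
    "GroupTrajectory",
    "ChangePointResult",
    "ChangePointTally",
    "PenaltyPath",
    "select_taxa_for_cpa",
    "build_trajectory",
    "ed_cost_terms",
    "ed_pelt",
    "penalty_elbow",
    "tally_change_points",
    "default_penalty_grid",
]


@dataclass
class GroupTrajectory:
    """Weekly mean percent abundance of one taxon in one group."""

    taxon: str
    group: int
    weeks: np.ndarray
    values: np.ndarray
    imputed: np.ndarray  # True where no sample contributed and the value
    # was filled by interpolation / edge extension
    n_contributing_patients: int


@dataclass
class ChangePointResult:
    taxon: str
    group: int
    penalty: float
    change_points: list[int]  # tau values: size of each left part
    weeks: np.ndarray

    @property
    def change_weeks(self) -> list[int]:
        """First week of each new regime (week tallied)."""
        return [int(self.weeks[tau]) for tau in self.change_points]


@dataclass
class ChangePointTally:
    rank: str
    counts: pd.Series  # indexed by PMA week
    key_week: int | None

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class PenaltyPath:
    penalties: np.ndarray
    n_change_points: np.ndarray
    selected_penalty: float
    no_elbow: bool = False


def select_taxa_for_cpa(results: Sequence[LmmResult], fdr: float = 0.01) -> list[str]:
    """Taxa whose PMA fixed effect passes Benjamini-Hochberg at ``fdr``."""
    usable = [r for r in results if r.p_pma is not None and np.isfinite(r.p_pma)]
    if not usable:
        return []
    flags = bh_adjust([r.p_pma for r in usable], fdr=fdr)
    return [r.taxon for r, keep in zip(usable, flags.flags) if keep]


def build_trajectory(
    pct: pd.DataFrame,
    taxon: str,
    group: int,
    samples: Sequence[SampleRecord],
    groups: Mapping[str, HcgGroup | int],
    week_start: int = 24,
    week_end: int = 36,
) -> GroupTrajectory | None:
    """Weekly mean percent abundance over the group's contributing patients.

    Only patients with the taxon present (>0) in at least one of their
    samples contribute.  Weeks with no contributing sample are imputed by
    linear interpolation between the nearest observed weeks; edge weeks
    are extended from the nearest observed value.  Returns None (caller
    logs/skips) when the group has no contributing patient.
    """
    weeks = np.arange(week_start, week_end + 1)
    in_group = [
        s
        for s in samples
        if s.sample_id in pct.columns
        and s.patient_id in groups
        and int(groups[s.patient_id]) == int(group)
        and week_start <= s.pma_week <= week_end
    ]
    vals = pct.loc[taxon]
    contributing = {
        p
        for p in {s.patient_id for s in in_group}
        if any(vals[s.sample_id] > 0 for s in in_group if s.patient_id == p)
    }
    if not contributing:
        return None
    by_week: dict[int, list[float]] = {}
    for s in in_group:
        if s.patient_id in contributing:
            by_week.setdefault(s.pma_week, []).append(float(vals[s.sample_id]))
    series = np.full(weeks.size, np.nan)
    for w, xs in by_week.items():
        series[w - week_start] = float(np.mean(xs))
    imputed = np.isnan(series)
    if imputed.any():
        obs_idx = np.flatnonzero(~imputed)
        series = np.interp(np.arange(weeks.size), obs_idx, series[obs_idx])
    return GroupTrajectory(
        taxon=taxon,
        group=int(group),
        weeks=weeks,
        values=series,
        imputed=imputed,
        n_contributing_patients=len(contributing),
    )


# --------------------------------------------------------------------------
# ED-PELT
# --------------------------------------------------------------------------


def ed_cost_terms(series: np.ndarray, n_quantiles: int | None = None):
    """Precompute the ED (empirical-distribution) cost machinery.

    Returns ``(cost, K)`` where ``cost(s, e)`` is the nonparametric cost of
    the segment covering 0-based positions ``s..e-1``.  The cost evaluates
    the empirical CDF of the segment at K quantiles of the full series
    (default ``ceil(4 ln n)``) and sums the Bernoulli log-likelihood terms,
    scaled by ``2 ln(2n-1)/K``.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n_quantiles is None:
        n_quantiles = int(math.ceil(4.0 * math.log(n)))
    K = max(1, min(int(n_quantiles), n))
    xs = np.sort(x)
    ks = np.arange(1, K + 1)
    probs = 1.0 / (1.0 + (2.0 * n - 1.0) ** (1.0 - (2.0 * ks - 1.0) / K))
    idx = np.minimum(np.ceil(probs * n).astype(int) - 1, n - 1)
    idx = np.maximum(idx, 0)
    quantiles = xs[idx]
    # per-quantile cumulative "half-tie" counts: < counts 1, == counts 0.5
    a = (x[None, :] < quantiles[:, None]) + 0.5 * (x[None, :] == quantiles[:, None])
    csum = np.zeros((K, n + 1))
    csum[:, 1:] = np.cumsum(a, axis=1)
    scale = 2.0 * math.log(2.0 * n - 1.0) / K

    def cost(s: int, e: int) -> float:
        L = e - s
        f = (csum[:, e] - csum[:, s]) / L
        inner = np.zeros(K)
        ok = (f > 0) & (f < 1)
        fo = f[ok]
        inner[ok] = fo * np.log(fo) + (1.0 - fo) * np.log(1.0 - fo)
        return float(-L * scale * inner.sum())

    return cost, K


def ed_pelt(
    series: Sequence[float],
    penalty: float,
    n_quantiles: int | None = None,
    prune: bool = True,
) -> list[int]:
    """Exact penalized change-point segmentation under the ED cost.

    Minimizes ``sum(segment costs) + penalty * (#change points)`` by the
    PELT dynamic program.  Returns the change points as ``tau`` values
    (number of observations to the left of each change), strictly
    increasing in ``1..n-1``.  Pruning never alters the optimum.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("series too short for change-point analysis (need >= 4)")
    if penalty < 0:
        raise ValueError("penalty must be nonnegative")
    cost, _ = ed_cost_terms(x, n_quantiles)
    F = np.full(n + 1, np.inf)
    F[0] = -penalty
    last = np.zeros(n + 1, dtype=int)
    candidates = [0]
    for e in range(1, n + 1):
        best, arg = np.inf, 0
        vals = {}
        for s in candidates:
            v = F[s] + cost(s, e) + penalty
            vals[s] = v
            if v < best:
                best, arg = v, s
        F[e] = best
        last[e] = arg
        if prune:
            candidates = [s for s in candidates if vals[s] - penalty <= F[e]]
        candidates.append(e)
    cps = []
    e = n
    while e > 0:
        s = last[e]
        if s > 0:
            cps.append(s)
        e = s
    return sorted(cps)


def default_penalty_grid(n_points: int = 25) -> np.ndarray:
    """Log-spaced penalty grid spanning ~3 orders of magnitude around the
    ED-cost scale of a length-13 weekly trajectory."""
    return np.logspace(-1.5, 1.7, n_points)


def penalty_elbow(
    series: Sequence[float],
    penalty_grid: Sequence[float] | None = None,
    n_quantiles: int | None = None,
    curvature_threshold: float = 2.0,
) -> PenaltyPath:
    """Automated Lavielle-style penalty selection.

    The number of change points is computed along the (ascending) penalty
    grid; each distinct model size m on the path is paired with its
    unpenalized segmentation cost J(m).  Costs are normalized so the
    J-vs-m curve has average slope -1, and the selected m* is the largest
    model size whose discrete curvature (slope change) exceeds
    ``curvature_threshold`` -- the automated reading of the manual elbow
    diagnostic.  If no curvature exceeds the threshold the most
    parsimonious model on the path is kept (0 change points for a pure
    noise series).  The selected penalty is the largest grid value
    reproducing m*; a constant path is flagged ``no_elbow``.
    """
    grid = np.asarray(
        default_penalty_grid() if penalty_grid is None else penalty_grid, dtype=float
    )
    if grid.size < 5:
        raise ValueError("penalty grid needs at least 5 values")
    if grid.max() <= 0 or grid.min() < 0:
        raise ValueError("penalties must be nonnegative, grid increasing")
    grid = np.sort(grid)
    x = np.asarray(series, dtype=float)
    cost, _ = ed_cost_terms(x, n_quantiles)
    counts = np.empty(grid.size, dtype=int)
    raw_cost: dict[int, float] = {}
    for i, b in enumerate(grid):
        cps = ed_pelt(x, b, n_quantiles)
        counts[i] = len(cps)
        if counts[i] not in raw_cost:
            bounds = [0] + list(cps) + [x.size]
            raw_cost[counts[i]] = sum(
                cost(s, e) for s, e in zip(bounds[:-1], bounds[1:])
            )
    if counts.max() == counts.min():
        return PenaltyPath(grid, counts, float(grid[-1]), no_elbow=True)
    ms = np.array(sorted(raw_cost))
    js = np.array([raw_cost[m] for m in ms])
    # normalize so the average slope of J vs m is -1 over the path
    span = js[0] - js[-1]
    jn = (js - js[-1]) / span * (ms[-1] - ms[0]) if span > 0 else js * 0.0
    best_m = int(ms[0])
    for i in range(1, ms.size - 1):
        slope_in = (jn[i - 1] - jn[i]) / (ms[i] - ms[i - 1])
        slope_out = (jn[i] - jn[i + 1]) / (ms[i + 1] - ms[i])
        if slope_in - slope_out >= curvature_threshold:
            best_m = int(ms[i])  # largest qualifying m wins (ms ascending)
    sel = grid[counts == best_m]
    return PenaltyPath(grid, counts, float(sel.max()), no_elbow=False)


def tally_change_points(
    results: Sequence[ChangePointResult],
    rank: str,
    week_start: int = 24,
    week_end: int = 36,
) -> ChangePointTally:
    """Tally change points by PMA week over all (taxon, group) results.

    Each change point is recorded under the first week of its new regime;
    the key week is the argmax (earliest on ties).  Empty input yields an
    all-zero tally with ``key_week=None``.
    """
    weeks = np.arange(week_start, week_end + 1)
    counts = pd.Series(0, index=weeks)
    for r in results:
        for w in r.change_weeks:
            if week_start <= w <= week_end:
                counts[w] += 1
    if counts.sum() == 0:
        return ChangePointTally(rank, counts, None)
    key = int(counts.index[np.argmax(counts.to_numpy())])
    return ChangePointTally(rank, counts, key)
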