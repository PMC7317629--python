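"""Four-group risk stratification of the frailty score via the distance
index and coverage index over Kaplan-Meier curve sets.

The goal is a partition of the frailty score into four dose-ordered
strata (fit, mild, moderate, severe) whose survival curves stay strictly
separated — no overlap even of the 95% confidence intervals — at every
follow-up time after the first year.

For an ordered set of four KM curves S_fit >= S_mild >= S_moderate >=
S_severe evaluated at time t:

* distance index  D(t) = min of the three adjacent gaps
  (S_upper(t) - S_lower(t)); D is large only when all three gaps are
  wide and balanced, so a large D means wider, more stable separation.
* coverage index  C(t) = L_error(t) / L_total(t), where L_error is the
  summed 95% CI length of the four curves and L_total =
  S_fit(t) - S_severe(t); a small C means little estimation error
  relative to the total spread.

The search enumerates ordered threshold triples drawn from midpoints of
consecutive distinct observed score values, discards candidates that are
infeasible (a group below the minimum size, a non-positive adjacent gap,
or adjacent CI overlap at any monthly grid point after month 12), and
among feasible candidates maximizes min-over-t D (max-min criterion),
breaking ties by minimizing max-over-t C (min-max criterion) and then by
the lexicographically smallest triple.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DataError
from .survival_eval import GROUP_ORDER, SurvivalCurve, km_estimate

DEFAULT_GRID_MONTHS = np.arange(12, 97)


@dataclass(frozen=True)
class CutPoints:
    """Score thresholds; intervals are lower-inclusive, upper-exclusive:
    fit = [0, c1), mild = [c1, c2), moderate = [c2, c3), severe = [c3, 1]."""

    c1: float
    c2: float
    c3: float

    def __post_init__(self):
        if not (0.0 < self.c1 < self.c2 < self.c3 < 1.0):
            raise ConfigError("cutpoints: require 0 < c1 < c2 < c3 < 1")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.c1, self.c2, self.c3)


def assign_groups(scores: np.ndarray | pd.Series, cutpoints: CutPoints) -> np.ndarray:
    """Label each score by its interval; a boundary score joins the upper
    group (e.g. score == c1 -> mild)."""
    values = np.asarray(scores, dtype=float) if not isinstance(scores, pd.DataFrame) \
        else scores["value"].to_numpy()
    if np.any((values < 0) | (values > 1)):
        raise DataError("assign_groups: scores must lie in [0, 1]")
    idx = np.searchsorted(np.array(cutpoints.as_tuple()), values, side="right")
    return np.array(GROUP_ORDER, dtype=object)[idx]


@dataclass
class SurvivalCurveSet:
    """Four KM curves ordered fit -> severe, on a common monthly grid."""

    curves: dict[str, SurvivalCurve]
    grid: np.ndarray                        # months
    surv: np.ndarray = field(init=False)    # (4, T)
    ci_lower: np.ndarray = field(init=False)
    ci_upper: np.ndarray = field(init=False)

    def __post_init__(self):
        if tuple(self.curves) != GROUP_ORDER:
            raise DataError(f"SurvivalCurveSet: curves must be keyed {GROUP_ORDER}")
        self.grid = np.asarray(self.grid, dtype=float)
        s, lo, hi = [], [], []
        for g in GROUP_ORDER:
            si, loi, hii = self.curves[g].evaluate(self.grid)
            s.append(si); lo.append(loi); hi.append(hii)
        self.surv = np.vstack(s)
        self.ci_lower = np.vstack(lo)
        self.ci_upper = np.vstack(hi)

    def _t_index(self, t: float) -> int:
        hits = np.nonzero(np.isclose(self.grid, t))[0]
        if hits.size == 0:
            raise ConfigError(f"t: {t} is not on the evaluation grid")
        return int(hits[0])


def curve_set(
    time: np.ndarray,
    event: np.ndarray,
    groups: np.ndarray,
    grid: np.ndarray = DEFAULT_GRID_MONTHS,
    ci_level: float = 0.95,
) -> SurvivalCurveSet:
    """Fit the four per-group KM curves on a common grid."""
    groups = np.asarray(groups)
    time = np.asarray(time, float)
    event = np.asarray(event)
    curves = {}
    for g in GROUP_ORDER:
        mask = groups == g
        if not mask.any():
            raise DataError(f"curve_set: group {g!r} is empty")
        curves[g] = km_estimate(time[mask], event[mask], ci_level=ci_level)
    return SurvivalCurveSet(curves=curves, grid=grid)


def distance_index(curveset: SurvivalCurveSet, t: float) -> float:
    """Minimum adjacent KM gap at time t (negative when curves cross)."""
    i = curveset._t_index(t)
    gaps = -np.diff(curveset.surv[:, i])
    return float(gaps.min())


def coverage_index(curveset: SurvivalCurveSet, t: float) -> float:
    """Total within-group CI length relative to the fit-severe spread."""
    i = curveset._t_index(t)
    l_total = curveset.surv[0, i] - curveset.surv[3, i]
    if l_total <= 0:
        raise DataError(f"coverage_index: L_total <= 0 at t={t}; index undefined")
    l_error = float((curveset.ci_upper[:, i] - curveset.ci_lower[:, i]).sum())
    return l_error / l_total


def _profiles(curveset: SurvivalCurveSet) -> tuple[np.ndarray, np.ndarray]:
    """(D(t), C(t)) over the whole grid; C is +inf where undefined."""
    gaps = -np.diff(curveset.surv, axis=0)          # (3, T) adjacent gaps
    d_prof = gaps.min(axis=0)
    l_total = curveset.surv[0] - curveset.surv[3]
    l_error = (curveset.ci_upper - curveset.ci_lower).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c_prof = np.where(l_total > 0, l_error / l_total, np.inf)
    return d_prof, c_prof


def _ci_disjoint(curveset: SurvivalCurveSet) -> bool:
    """True iff adjacent curves' CIs never overlap anywhere on the grid."""
    upper_lo = curveset.ci_lower[:3]   # lower CI bound of the higher curve
    lower_hi = curveset.ci_upper[1:]   # upper CI bound of the lower curve
    return bool(np.all(upper_lo > lower_hi))


@dataclass
class StratificationResult:
    cutpoints: CutPoints | None
    feasible: bool
    distance_profile: np.ndarray | None
    coverage_profile: np.ndarray | None
    grid: np.ndarray
    objective_min_distance: float | None
    objective_max_coverage: float | None
    group_sizes: dict[str, int] | None
    ordering_ok: bool | None
    ci_disjoint: bool | None
    n_candidates: int = 0
    n_feasible: int = 0
    failed_constraint: str | None = None   # set on infeasible results

    def to_json(self, path: str | Path) -> None:
        payload = {
            "cutpoints": list(self.cutpoints.as_tuple()) if self.cutpoints else None,
            "feasible": self.feasible,
            "grid_months": self.grid.tolist(),
            "distance_profile": None if self.distance_profile is None
            else self.distance_profile.tolist(),
            "coverage_profile": None if self.coverage_profile is None
            else [None if not np.isfinite(c) else c for c in self.coverage_profile],
            "objective_min_distance": self.objective_min_distance,
            "objective_max_coverage": self.objective_max_coverage,
            "group_sizes": self.group_sizes,
            "ordering_ok": self.ordering_ok,
            "ci_disjoint": self.ci_disjoint,
            "n_candidates": self.n_candidates,
            "n_feasible": self.n_feasible,
            "failed_constraint": self.failed_constraint,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct observed score values."""
    distinct = np.unique(np.asarray(scores, float))
    if distinct.size < 4:
        return np.empty(0)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    return mids[(mids > 0) & (mids < 1)]


def default_min_group_size(n: int) -> int:
    return max(30, int(np.ceil(0.005 * n)))


def search_cutpoints(
    scores: np.ndarray | pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    grid: np.ndarray = DEFAULT_GRID_MONTHS,
    min_group_size: int | None = None,
    candidates: list[tuple[float, float, float]] | None = None,
    ci_level: float = 0.95,
) -> StratificationResult:
    """Exhaustive search for the best feasible cut-point triple.

    Feasibility at every grid time (the grid starts after the first
    year): all three adjacent KM gaps > 0 and adjacent 95% CIs disjoint;
    plus every group at least ``min_group_size`` subjects (default
    max(30, 0.5% of n)). Among feasible triples: maximize min-over-t D,
    then minimize max-over-t C, then smallest (c1, c2, c3). When nothing
    is feasible the result reports the best-scoring infeasible candidate
    and the constraint it failed.
    """
    values = scores["value"].to_numpy() if isinstance(scores, pd.DataFrame) \
        else np.asarray(scores, float)
    time = np.asarray(time, float)
    event = np.asarray(event)
    n = values.size
    if min_group_size is None:
        min_group_size = default_min_group_size(n)

    if candidates is None:
        thresholds = candidate_thresholds(values)
        candidates = list(itertools.combinations(thresholds.tolist(), 3))
    n_cand = len(candidates)

    order = np.argsort(values, kind="stable")
    sorted_vals = values[order]

    best_feasible = None           # (minD, maxC, triple, payload)
    best_infeasible = None
    n_feasible = 0
    for triple in candidates:
        c1, c2, c3 = triple
        if not (0.0 < c1 < c2 < c3 < 1.0):
            continue
        # group sizes via cumulative counts on the sorted scores
        bounds = np.searchsorted(sorted_vals, [c1, c2, c3], side="left")
        sizes = np.diff(np.concatenate([[0], bounds, [n]]))
        size_ok = bool((sizes >= min_group_size).all())
        payload = None
        if size_ok:
            cp = CutPoints(c1, c2, c3)
            groups = assign_groups(values, cp)
            cs = curve_set(time, event, groups, grid=grid, ci_level=ci_level)
            d_prof, c_prof = _profiles(cs)
            ordering_ok = bool((d_prof > 0).all())
            disjoint = _ci_disjoint(cs)
            feasible = ordering_ok and disjoint
            min_d = float(d_prof.min())
            max_c = float(c_prof.max()) if np.isfinite(c_prof).all() else np.inf
            payload = (cp, d_prof, c_prof, dict(zip(GROUP_ORDER, sizes.tolist())),
                       ordering_ok, disjoint)
        else:
            feasible = False
            min_d, max_c = -np.inf, np.inf
        key = (-min_d, max_c, triple)
        if feasible:
            n_feasible += 1
            if best_feasible is None or key < best_feasible[0]:
                best_feasible = (key, payload, min_d, max_c)
        else:
            if best_infeasible is None or key < best_infeasible[0]:
                failed = (
                    "group_size" if not size_ok
                    else ("curve_ordering" if not payload[4] else "ci_overlap")
                )
                best_infeasible = (key, payload, min_d, max_c, failed, triple)

    if best_feasible is not None:
        _, (cp, d_prof, c_prof, sizes, ordering_ok, disjoint), min_d, max_c = best_feasible
        return StratificationResult(
            cutpoints=cp, feasible=True,
            distance_profile=d_prof, coverage_profile=c_prof, grid=np.asarray(grid, float),
            objective_min_distance=min_d, objective_max_coverage=max_c,
            group_sizes={k: int(v) for k, v in sizes.items()},
            ordering_ok=ordering_ok, ci_disjoint=disjoint,
            n_candidates=n_cand, n_feasible=n_feasible,
        )
    if best_infeasible is not None:
        _, payload, min_d, max_c, failed, triple = best_infeasible
        if payload is not None:
            cp, d_prof, c_prof, sizes, ordering_ok, disjoint = payload
            sizes = {k: int(v) for k, v in sizes.items()}
        else:
            cp = d_prof = c_prof = sizes = ordering_ok = disjoint = None
            try:
                cp = CutPoints(*triple)
            except ConfigError:
                cp = None
        return StratificationResult(
            cutpoints=cp, feasible=False,
            distance_profile=d_prof, coverage_profile=c_prof, grid=np.asarray(grid, float),
            objective_min_distance=None if not np.isfinite(min_d) else min_d,
            objective_max_coverage=None if not np.isfinite(max_c) else max_c,
            group_sizes=sizes, ordering_ok=ordering_ok, ci_disjoint=disjoint,
            n_candidates=n_cand, n_feasible=0, failed_constraint=failed,
        )
    return StratificationResult(
        cutpoints=None, feasible=False, distance_profile=None, coverage_profile=None,
        grid=np.asarray(grid, float), objective_min_distance=None,
        objective_max_coverage=None, group_sizes=None, ordering_ok=None,
        ci_disjoint=None, n_candidates=n_cand, n_feasible=0,
        failed_constraint="no_candidates",
    )
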