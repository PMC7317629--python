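"""Distance/coverage indices, boundary semantics and the cut-point search."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mlmfi import (
    CutPoints,
    DataError,
    OutcomeSpec,
    SurvivalCurveSet,
    assign_groups,
    build_outcome,
    compute_fi,
    coverage_index,
    curve_set,
    distance_index,
    search_cutpoints,
)
from mlmfi.risk_groups import candidate_thresholds, default_min_group_size
from mlmfi.survival_eval import GROUP_ORDER, SurvivalCurve

PRINTED_CUTS = CutPoints(0.026, 0.105, 0.157)


def fake_curveset(surv, ci_half=0.0, t=24.0):
    """Curve set with prescribed S and symmetric CI at a single time."""
    curves = {}
    for g, s, h in zip(GROUP_ORDER, surv, np.broadcast_to(ci_half, (4,))):
        curves[g] = SurvivalCurve(
            times=np.array([1.0]), surv=np.array([float(s)]),
            variance=np.array([0.0]),
            ci_lower=np.array([s - h]), ci_upper=np.array([s + h]),
            at_risk=np.array([100]), n_events=10, n_subjects=100,
        )
    return SurvivalCurveSet(curves=curves, grid=np.array([t]))


# ------------------------------------------------------------ assignment

@pytest.mark.parametrize(
    "score, expected",
    [
        (0.0, "fit"),
        (0.0259, "fit"),
        (0.026, "mild"),
        (0.1049, "mild"),
        (0.105, "moderate"),
        (0.1569, "moderate"),
        (0.157, "severe"),
        (1.0, "severe"),
    ],
)
def test_boundary_belongs_to_upper_group(score, expected):
    assert assign_groups(np.array([score]), PRINTED_CUTS)[0] == expected


def test_assignment_partitions_subjects():
    rng = np.random.default_rng(0)
    scores = rng.random(500)
    labels = assign_groups(scores, PRINTED_CUTS)
    counts = pd.Series(labels).value_counts()
    assert counts.sum() == 500
    assert set(counts.index) <= set(GROUP_ORDER)


def test_score_outside_unit_interval_rejected():
    with pytest.raises(DataError):
        assign_groups(np.array([1.2]), PRINTED_CUTS)


def test_cutpoints_require_strict_order():
    from mlmfi import ConfigError

    with pytest.raises(ConfigError):
        CutPoints(0.2, 0.2, 0.3)


# ------------------------------------------------------------ indices

def test_distance_index_equally_spaced():
    cs = fake_curveset([0.9, 0.8, 0.7, 0.6])
    assert distance_index(cs, 24.0) == pytest.approx(0.1, abs=1e-15)


def test_distance_index_is_min_gap():
    cs = fake_curveset([0.9, 0.85, 0.5, 0.45])
    assert distance_index(cs, 24.0) == pytest.approx(0.05, abs=1e-15)


def test_distance_index_identical_curves_zero():
    cs = fake_curveset([0.7, 0.7, 0.7, 0.7])
    assert distance_index(cs, 24.0) == 0.0


def test_distance_index_negative_when_curves_cross():
    cs = fake_curveset([0.8, 0.9, 0.7, 0.6])
    assert distance_index(cs, 24.0) < 0


def test_coverage_index_ratio():
    cs = fake_curveset([0.9, 0.8, 0.6, 0.5], ci_half=0.01)
    # L_error = 4 * 0.02 = 0.08, L_total = 0.4
    assert coverage_index(cs, 24.0) == pytest.approx(0.2, abs=1e-12)


def test_coverage_index_unequal_ci_lengths():
    cs = fake_curveset([0.95, 0.8, 0.6, 0.45], ci_half=[0.005, 0.01, 0.015, 0.02])
    # L_error = 0.01+0.02+0.03+0.04 = 0.10, L_total = 0.5
    assert coverage_index(cs, 24.0) == pytest.approx(0.2, abs=1e-12)


def test_coverage_index_zero_width_cis():
    cs = fake_curveset([0.9, 0.8, 0.7, 0.6], ci_half=0.0)
    assert coverage_index(cs, 24.0) == 0.0


def test_coverage_index_undefined_when_no_spread():
    cs = fake_curveset([0.7, 0.7, 0.7, 0.7])
    with pytest.raises(DataError):
        coverage_index(cs, 24.0)


# ------------------------------------------------------------ search

def _scores_and_survival(n=300, seed=19, beta=3.0):
    """Discrete frailty-like score plus survival dependent on it."""
    rng = np.random.default_rng(seed)
    scores = rng.choice([0.0, 0.1, 0.2, 0.3, 0.4, 0.5], size=n,
                        p=[0.4, 0.25, 0.15, 0.1, 0.06, 0.04])
    time = rng.exponential(60.0 * np.exp(-beta * scores))
    event = time <= 96
    time = np.minimum(time, 96.0)
    return scores, time, event.astype(int)


def lifelines_brute_force_search(scores, time, event, candidates, grid, min_size):
    """Independent oracle: lifelines KM curves, explicit feasibility rules,
    max-min distance then min-max coverage then lexicographic order."""
    from lifelines import KaplanMeierFitter

    best = None
    for triple in candidates:
        c1, c2, c3 = triple
        labels = np.select(
            [scores < c1, scores < c2, scores < c3],
            ["fit", "mild", "moderate"], default="severe",
        )
        sizes = [np.sum(labels == g) for g in GROUP_ORDER]
        if min(sizes) < min_size:
            continue
        S, LO, HI = [], [], []
        for g in GROUP_ORDER:
            mask = labels == g
            kmf = KaplanMeierFitter().fit(time[mask], event[mask])
            s = kmf.survival_function_at_times(grid).to_numpy()
            ci = kmf.confidence_interval_
            # step interpolation of the CI at grid times
            idx = np.searchsorted(ci.index.to_numpy(), grid, side="right") - 1
            lo = np.where(idx >= 0, ci.iloc[:, 0].to_numpy()[np.maximum(idx, 0)], 1.0)
            hi = np.where(idx >= 0, ci.iloc[:, 1].to_numpy()[np.maximum(idx, 0)], 1.0)
            S.append(s); LO.append(lo); HI.append(hi)
        S, LO, HI = map(np.vstack, (S, LO, HI))
        gaps = -np.diff(S, axis=0)
        if not (gaps > 0).all():
            continue
        if not (LO[:3] > HI[1:]).all():
            continue
        min_d = gaps.min()
        l_total = S[0] - S[3]
        max_c = ((HI - LO).sum(axis=0) / l_total).max()
        key = (-min_d, max_c, triple)
        if best is None or key < best[0]:
            best = (key, triple)
    return None if best is None else best[1]


def test_search_matches_independent_enumeration():
    scores, time, event = _scores_and_survival()
    thresholds = candidate_thresholds(scores)
    candidates = [t for t in itertools.combinations(thresholds.tolist(), 3)]
    assert len(candidates) <= 20
    grid = np.arange(12, 97)
    result = search_cutpoints(scores, time, event, grid=grid, min_group_size=10,
                              candidates=candidates)
    oracle = lifelines_brute_force_search(scores, time, event, candidates, grid, 10)
    assert result.feasible == (oracle is not None)
    if oracle is not None:
        assert result.cutpoints.as_tuple() == pytest.approx(oracle, abs=1e-12)


def test_search_result_invariant_to_subject_order():
    scores, time, event = _scores_and_survival()
    r1 = search_cutpoints(scores, time, event, min_group_size=10)
    perm = np.random.default_rng(1).permutation(len(scores))
    r2 = search_cutpoints(scores[perm], time[perm], event[perm], min_group_size=10)
    assert r1.feasible == r2.feasible
    assert r1.cutpoints.as_tuple() == r2.cutpoints.as_tuple()
    np.testing.assert_allclose(r1.distance_profile, r2.distance_profile, atol=1e-12)


def test_search_beats_quartile_partition_when_feasible():
    """The max-min winner's worst-time distance index is at least the
    quartile partition's, whenever quartiles are feasible."""
    scores, time, event = _scores_and_survival(n=2500, seed=23, beta=4.0)
    result = search_cutpoints(scores, time, event, min_group_size=10)
    assert result.feasible
    qs = np.quantile(scores, [0.25, 0.5, 0.75])
    distinct = np.unique(scores)
    # snap quartile thresholds onto candidate midpoints
    mids = (distinct[:-1] + distinct[1:]) / 2
    triple = tuple(float(mids[np.argmin(np.abs(mids - q))]) for q in qs)
    if len(set(triple)) == 3 and triple[0] < triple[1] < triple[2]:
        q_result = search_cutpoints(scores, time, event, min_group_size=10,
                                    candidates=[triple])
        if q_result.feasible:
            assert result.objective_min_distance >= q_result.objective_min_distance - 1e-12


def test_tiny_cohort_fails_group_size_constraint():
    scores = np.array([0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.1, 0.2, 0.3, 0.0])
    time = np.arange(1.0, 11)
    event = np.ones(10, int)
    result = search_cutpoints(scores, time, event, min_group_size=50)
    assert not result.feasible
    assert result.failed_constraint == "group_size"


def test_default_min_group_size_rule():
    assert default_min_group_size(1000) == 30
    assert default_min_group_size(100_000) == 500


def test_infeasible_result_reports_best_candidate():
    """Identical survival in all groups: ordering can't hold; the result
    names the violated constraint."""
    rng = np.random.default_rng(5)
    scores = rng.choice([0.0, 0.2, 0.4, 0.6], size=200)
    time = rng.exponential(50, 200).clip(max=96)
    event = (time < 96).astype(int)
    result = search_cutpoints(scores, time, event, min_group_size=5)
    assert not result.feasible
    assert result.failed_constraint in ("curve_ordering", "ci_overlap")
    assert result.cutpoints is not None  # best-scoring infeasible candidate


def test_group_sizes_sum_to_n(small_cohort, small_deficits):
    _, subjects, _, _ = small_cohort
    _, matrix = small_deficits
    scores = compute_fi(matrix, matrix.condition_ids[:12])
    t, e = build_outcome(subjects, OutcomeSpec("all_cause_mortality", 8))
    result = search_cutpoints(scores["value"].to_numpy(), t, e, min_group_size=5)
    if result.feasible:
        assert sum(result.group_sizes.values()) == len(subjects)
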