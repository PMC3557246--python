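"""Robust estimation, outlier regions, Youden cutoffs and cohort calling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.robust.scale import Huber as SmHuber

from asecall.ase_calling import (
    CallMethod,
    CohortRecord,
    CohortTable,
    Group,
    HuberEstimates,
    NO_LOWER,
    NO_UPPER,
    alpha_outlier_limits,
    call_ase,
    huber_m,
    screening_tests,
    youden_cutoffs,
)
from asecall.errors import DegenerateScaleError


def cohort_from(cases, controls):
    records = [CohortRecord(f"CASE-{i}", Group.CASE, float(f))
               for i, f in enumerate(cases)]
    records += [CohortRecord(f"CTRL-{i}", Group.CONTROL, float(f))
                for i, f in enumerate(controls)]
    return CohortTable(records)


class TestHuberM:
    def test_degenerate_constant_sample(self):
        est = huber_m([0.4] * 10)
        assert est.location == 0.4
        assert est.scale == 0.0
        assert est.degenerate

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            huber_m([0.1, 0.2])

    def test_normal_consistency(self):
        rng = np.random.default_rng(2024)
        x = rng.normal(0.0, 1.0, 10_000)
        est = huber_m(x)
        assert est.converged
        assert est.location == pytest.approx(0.0, abs=0.05)
        assert est.scale == pytest.approx(1.0, abs=0.05)

    def test_matches_independent_proposal2_solver(self):
        # statsmodels implements the same joint location/scale equations
        rng = np.random.default_rng(5)
        x = rng.normal(0.4, 0.05, 120)
        x[:10] = 0.9
        est = huber_m(x)
        loc, scale = SmHuber(c=1.345, tol=1e-8, maxiter=200)(x)
        assert est.location == pytest.approx(float(loc), abs=1e-6)
        assert est.scale == pytest.approx(float(scale), abs=1e-6)

    def test_resists_moderate_contamination(self):
        # 110 clean values around 0.40 plus 10 gross outliers at 0.9
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(0.40, 0.005, 110), np.full(10, 0.9)])
        est = huber_m(x)
        assert abs(est.location - 0.40) < 0.01

    def test_location_shift_bounded_under_ten_percent_contamination(self):
        rng = np.random.default_rng(13)
        clean = rng.normal(0.0, 1.0, 120)
        base = huber_m(clean)
        contaminated = clean.copy()
        contaminated[:12] = 10.0  # 10% of points at 10 sigma
        est = huber_m(contaminated)
        assert abs(est.location - base.location) < 0.5 * base.scale

    def test_large_tuning_constant_recovers_mean_and_sd(self):
        rng = np.random.default_rng(3)
        x = rng.normal(5.0, 2.0, 200)
        est = huber_m(x, tuning_k=1e6)
        assert est.location == pytest.approx(float(np.mean(x)), abs=1e-7)
        assert est.scale == pytest.approx(float(np.std(x, ddof=1)), abs=1e-7)


class TestAlphaOutlierLimits:
    @pytest.mark.parametrize("loc,scale,alpha,expected", [
        (0.0, 1.0, 0.05, (-1.9600, 1.9600)),
        (0.40, 0.08, 0.05, (0.2432, 0.5568)),
        (0.0, 1.0, 0.32, (-0.9945, 0.9945)),
    ])
    def test_region_examples(self, loc, scale, alpha, expected):
        est = HuberEstimates(location=loc, scale=scale, tuning_k=1.345,
                             iterations=1, converged=True)
        lo, hi = alpha_outlier_limits(est, alpha)
        assert lo == pytest.approx(expected[0], abs=5e-4)
        assert hi == pytest.approx(expected[1], abs=5e-4)

    def test_degenerate_scale_rejected(self):
        est = HuberEstimates(location=0.4, scale=0.0, tuning_k=1.345,
                             iterations=0, converged=True, degenerate=True)
        with pytest.raises(DegenerateScaleError):
            alpha_outlier_limits(est, 0.05)


def brute_force_youden(cases, controls):
    """Independent exhaustive scan over every candidate cutoff.

    Re-derives the direction-wise objective with plain Python loops:
    sensitivity counts cases beyond the cutoff in the direction, specificity
    counts controls inside the symmetric band around the case median.
    """
    cases = sorted(float(c) for c in cases)
    controls = [float(c) for c in controls]
    n = len(cases)
    center = (cases[n // 2] if n % 2 else
              (cases[n // 2 - 1] + cases[n // 2]) / 2)
    pooled = sorted(set(cases) | set(controls) | {center})
    mids = [(a + b) / 2 for a, b in zip(pooled, pooled[1:])]
    out = {}
    for low in (True, False):
        cands = [c for c in mids if (c < center if low else c > center)]
        best = (0.0, -1.0, NO_LOWER if low else NO_UPPER)
        for c in cands:
            t = abs(center - c)
            sens = sum((x < c if low else x > c) for x in cases) / n
            spec = sum(abs(x - center) <= t for x in controls) / len(controls)
            j = sens + spec - 1.0
            if j > best[0] + 1e-12 or (abs(j - best[0]) <= 1e-12
                                       and t > best[1] >= 0.0):
                best = (j, t, c)
        out[low] = best[2]
    return out[True], out[False]


class TestYoudenCutoffs:
    def test_planted_extremes_are_isolated(self):
        controls = [0.40, 0.41, 0.42, 0.43, 0.44, 0.45, 0.46]
        cases = controls + [0.10, 0.90]
        lower, upper = youden_cutoffs(cases, controls)
        assert 0.10 < lower < 0.40
        assert 0.46 < upper < 0.90
        flagged = [f for f in cases if f < lower or f > upper]
        assert flagged == [0.10, 0.90]

    def test_identical_groups_give_sentinels(self):
        vals = [0.38, 0.40, 0.42, 0.44]
        lower, upper = youden_cutoffs(vals, vals)
        assert lower == NO_LOWER
        assert upper == NO_UPPER

    def test_one_sided_mass_gives_sentinel_in_empty_direction(self):
        # every value at or above the case median: nothing to cut below
        cases = [0.5, 0.5, 0.5, 0.5, 0.9]
        controls = [0.5, 0.5, 0.5]
        lower, upper = youden_cutoffs(cases, controls)
        assert lower == NO_LOWER
        assert 0.5 < upper < 0.9

    @given(st.data())
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_equals_brute_force_oracle(self, data):
        n_cases = data.draw(st.integers(4, 30))
        n_controls = data.draw(st.integers(2, 30))
        grid = st.integers(0, 40).map(lambda k: k / 40)
        cases = data.draw(st.lists(grid, min_size=n_cases, max_size=n_cases))
        controls = data.draw(
            st.lists(grid, min_size=n_controls, max_size=n_controls))
        lower, upper = youden_cutoffs(cases, controls)
        b_lower, b_upper = brute_force_youden(cases, controls)
        assert lower == pytest.approx(b_lower)
        assert upper == pytest.approx(b_upper)

    def test_cutoffs_invariant_under_cohort_duplication(self):
        rng = np.random.default_rng(21)
        cases = list(rng.normal(0.4, 0.04, 30)) + [0.1, 0.85]
        controls = list(rng.normal(0.43, 0.03, 20))
        once = youden_cutoffs(cases, controls)
        twice = youden_cutoffs(cases * 2, controls * 2)
        assert once == pytest.approx(twice)


class TestCallAse:
    def test_youden_recovers_planted_fixture_a(self, fixture_a_sim):
        res = call_ase(fixture_a_sim.table, CallMethod.YOUDEN)
        flagged = {s for s, f in res.flags.items() if f}
        assert flagged == set(fixture_a_sim.planted_ids)
        assert res.n_positive == 17

    def test_alpha_outlier_recovers_all_planted_fixture_b(self, fixture_b_sim):
        res = call_ase(fixture_b_sim.table, CallMethod.ALPHA_OUTLIER,
                       alpha=0.05)
        flagged = {s for s, f in res.flags.items() if f}
        # every planted outlier is recovered (sensitivity 1); the alpha
        # region may additionally clip extreme balanced cases because the
        # balanced truncation range is wider than location +/- 1.96 scale
        assert set(fixture_b_sim.planted_ids) <= flagged
        assert res.estimates.location == pytest.approx(0.40, abs=0.01)

    def test_constant_cohort_is_degenerate_for_alpha_caller(self):
        cohort = cohort_from([0.5] * 10, [0.5] * 5)
        with pytest.raises(DegenerateScaleError):
            call_ase(cohort, CallMethod.ALPHA_OUTLIER)
        res = call_ase(cohort, CallMethod.YOUDEN)
        assert res.n_positive == 0

    def test_flags_invariant_under_record_shuffling(self, fixture_a_sim):
        rng = np.random.default_rng(4)
        records = list(fixture_a_sim.table.records)
        rng.shuffle(records)
        res1 = call_ase(fixture_a_sim.table, CallMethod.YOUDEN)
        res2 = call_ase(CohortTable(records), CallMethod.YOUDEN)
        assert res1.flags == res2.flags
        assert res1.lower_cutoff == pytest.approx(res2.lower_cutoff)

    def test_no_cases_rejected(self):
        cohort = CohortTable([CohortRecord("C1", Group.CONTROL, 0.4),
                              CohortRecord("C2", Group.CONTROL, 0.45)])
        with pytest.raises(ValueError, match="no cases"):
            call_ase(cohort, CallMethod.YOUDEN)


class TestScreeningTests:
    def test_identical_groups_uninformative(self):
        vals = [0.40, 0.42, 0.44, 0.46]
        res = screening_tests(cohort_from(vals, vals))
        assert res.mw_p == pytest.approx(1.0, abs=0.05)
        assert res.f_test_p == pytest.approx(1.0)

    def test_exact_mann_whitney_small_sample(self):
        # all 20 rank assignments of {1,2,3} vs {4,5,6}: two-sided p = 0.1
        res = screening_tests(cohort_from([1, 2, 3], [4, 5, 6]))
        assert res.mw_p == pytest.approx(0.1)
        assert res.median_case == 2.0
        assert res.median_control == 5.0

    def test_fixture_a_variance_inflation_detected(self, fixture_a_sim):
        # planted bidirectional outliers inflate the case variance
        res = screening_tests(fixture_a_sim.table)
        assert res.f_test_p < 0.05

    def test_constant_group_f_test_missing(self):
        with pytest.warns(UserWarning, match="F-test"):
            res = screening_tests(cohort_from([1, 2, 3], [4, 4, 4]))
        assert math.isnan(res.f_test_p)
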