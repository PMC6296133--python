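"""Non-progressive detection probabilities and expected overdiagnosis counts."""

import numpy as np
import pytest

from screenmsm import (
    AgePartition,
    Cohort,
    REFERENCE_NONHOMOGENEOUS,
    SimulationConfig,
    expected_npbc,
    nonprogressive_probability_prevalent,
    nonprogressive_probability_subsequent,
    overdiagnosis_ci,
    simulate_cohort,
    transition_quantities,
)
from screenmsm.inference import FitResult, _pack

A = AgePartition()
REF = REFERENCE_NONHOMOGENEOUS


def _fit_with_cov(params, cov):
    names = ("lambda12_1", "lambda12_2", "lambda23_0", "lambda23_1", "lambda23_2", "r", "S")
    return FitResult(
        model_kind="nonhomogeneous",
        params=params,
        free_names=names,
        x=_pack(params, names),
        minus2loglik=0.0,
        converged=True,
        kkt_ok=True,
        n_eval=0,
        grad_inf=0.0,
        cov_transformed=cov,
        partition=A,
    )


class TestProbabilityFormulas:
    def test_no_nonprogressive_pathway_gives_zero(self):
        p = REF.with_values(r=0.0)
        assert nonprogressive_probability_prevalent(p, A, 50.0) == 0.0
        assert nonprogressive_probability_subsequent(p, A, 50.0, 52.0, 54.0) == 0.0

    def test_perfect_sensitivity_drops_missed_terms(self):
        p = REF.with_values(S=1.0)
        got = nonprogressive_probability_subsequent(p, A, 52.0, 54.0, 56.0)
        q = transition_quantities(p, A, 54.0, 56.0)
        expect = float(q["P14"] / (q["P14"] + q["P12"]))
        assert got == pytest.approx(expect, rel=1e-12)

    def test_prevalent_probability_increases_with_r(self):
        probs = [
            nonprogressive_probability_prevalent(REF.with_values(r=r), A, 51.0)
            for r in (0.001, 0.01, 0.1, 0.5)
        ]
        assert all(b > a for a, b in zip(probs, probs[1:]))

    def test_misordered_ages_rejected(self):
        with pytest.raises(ValueError):
            nonprogressive_probability_subsequent(REF, A, 54.0, 52.0, 56.0)
        with pytest.raises(ValueError):
            nonprogressive_probability_prevalent(REF, A, 40.0)

    @pytest.mark.parametrize("r,n,seed", [(0.05, 60_000, 13)])
    def test_formula_matches_latent_ground_truth_elevated_r(self, r, n, seed):
        """Per-round expected non-progressive counts agree with the simulator's
        latent labels (elevated r so the counts carry real information)."""
        config = SimulationConfig(n_women=n, seed=seed, params=REF.with_values(r=r))
        cohort, truth = simulate_cohort(config)
        _assert_formula_matches_truth(cohort, truth, config.params)


def _assert_formula_matches_truth(cohort, truth, params):
    od = expected_npbc(cohort, params, A)
    det = truth[np.isfinite(truth.detected_age)]
    first_screen = {h.woman_id: h.screen_ages[0] for h in cohort if h.screen_ages}
    prev_true = sum(
        1
        for _, row in det.iterrows()
        if row.detected_non_progressive
        and abs(first_screen[row.woman_id] - row.detected_age) < 1e-9
    )
    all_true = int(det.detected_non_progressive.sum())
    for cls, true_count in (
        ("prevalent", prev_true),
        ("subsequent", all_true - prev_true),
        ("overall", all_true),
    ):
        e = od.expected_npbc[cls]
        se = np.sqrt(max(e, 1.0))  # Poisson-scale MC error of the count
        assert abs(true_count - e) < 3 * se, (cls, true_count, e)


class TestExpectedCounts:
    def test_formula_matches_latent_ground_truth_reference_r(self, mc_cohort):
        cohort, truth = mc_cohort
        _assert_formula_matches_truth(cohort, truth, REF)

    def test_overall_is_sum_of_rounds_and_duplication_invariant(self, small_cohort):
        cohort, _ = small_cohort
        od = expected_npbc(cohort, REF, A)
        assert od.expected_npbc["overall"] == pytest.approx(
            od.expected_npbc["prevalent"] + od.expected_npbc["subsequent"]
        )
        doubled = expected_npbc(Cohort(list(cohort) + list(cohort)), REF, A)
        for cls in ("prevalent", "subsequent", "overall"):
            assert doubled.fraction[cls] == pytest.approx(od.fraction[cls], rel=1e-12)
            assert doubled.screen_detected[cls] == 2 * od.screen_detected[cls]
            assert 0.0 <= od.fraction[cls] <= 1.0

    def test_no_detections_warns_and_returns_zero(self):
        from screenmsm import ScreeningHistory

        cohort = Cohort([ScreeningHistory(0, (50.0,), censor_age=52.0)])
        od = expected_npbc(cohort, REF, A)
        assert od.expected_npbc["overall"] == 0.0
        assert od.fraction["overall"] == 0.0


class TestSimulationCI:
    def test_zero_covariance_collapses_to_point(self, small_cohort):
        cohort, _ = small_cohort
        fit = _fit_with_cov(REF, np.zeros((7, 7)))
        od = overdiagnosis_ci(cohort, fit, A, n_draws=50, seed=1)
        for cls in ("prevalent", "subsequent", "overall"):
            lo, hi = od.ci95[cls]
            assert lo == pytest.approx(od.fraction[cls], abs=1e-12)
            assert hi == pytest.approx(od.fraction[cls], abs=1e-12)

    def test_fixed_seed_reproducible(self, small_cohort):
        cohort, _ = small_cohort
        fit = _fit_with_cov(REF, np.diag([0.01] * 6 + [0.04]))
        a = overdiagnosis_ci(cohort, fit, A, n_draws=200, seed=7)
        b = overdiagnosis_ci(cohort, fit, A, n_draws=200, seed=7)
        assert a.ci95 == b.ci95
        c = overdiagnosis_ci(cohort, fit, A, n_draws=200, seed=8)
        assert a.ci95 != c.ci95

    def test_interval_brackets_point_estimate(self, small_cohort):
        cohort, _ = small_cohort
        fit = _fit_with_cov(REF, np.diag([0.01] * 7))
        od = overdiagnosis_ci(cohort, fit, A, n_draws=400, seed=3)
        for cls in ("prevalent", "subsequent", "overall"):
            lo, hi = od.ci95[cls]
            assert lo <= od.fraction[cls] <= hi
            assert 0.0 <= lo <= hi <= 1.0

    def test_missing_covariance_rejected(self, small_cohort):
        cohort, _ = small_cohort
        fit = _fit_with_cov(REF, np.diag([0.01] * 7))
        fit.cov_transformed = None
        with pytest.raises(ValueError):
            overdiagnosis_ci(cohort, fit, A, n_draws=10, seed=0)
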