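"""Maximum-likelihood machinery: optimisation, SEs, and the LRT."""

import numpy as np
import pytest

from screenmsm import (
    AgePartition,
    ModelParameters,
    REFERENCE_NONHOMOGENEOUS,
    SimulationConfig,
    cohort_loglik,
    fit_mle,
    likelihood_ratio_test,
    simulate_cohort,
    standard_errors,
)
from screenmsm.inference import FitResult, _fd_hessian, _pack

A = AgePartition()
REF = REFERENCE_NONHOMOGENEOUS


def _stub_fit(minus2loglik, n_free, model_kind="nonhomogeneous"):
    names = tuple(f"p{i}" for i in range(n_free))
    return FitResult(
        model_kind=model_kind,
        params=REF,
        free_names=names,
        x=np.zeros(n_free),
        minus2loglik=minus2loglik,
        converged=True,
        kkt_ok=True,
        n_eval=0,
        grad_inf=0.0,
    )


class TestHessianAndSEs:
    def test_fd_hessian_exact_on_quadratic(self):
        H_true = np.array([[4.0, 1.0, 0.0], [1.0, 3.0, 0.5], [0.0, 0.5, 2.0]])

        def f(x):
            return 0.5 * x @ H_true @ x + x.sum()

        H = _fd_hessian(f, np.array([0.3, -0.2, 1.0]))
        assert np.abs(H - H_true).max() < 1e-5

    def test_delta_method_on_log_scale(self):
        """SE of a log-normal-ish parameter is θ·se(log θ); CI truncated at 0."""
        params = REF.with_values(r=0.001)
        names = ("r", "S")
        fit = FitResult(
            model_kind="nonhomogeneous",
            params=params,
            free_names=names,
            x=_pack(params, names),
            minus2loglik=0.0,
            converged=True,
            kkt_ok=True,
            n_eval=0,
            grad_inf=0.0,
            cov_transformed=np.diag([4.0, 0.01]),
        )
        se = standard_errors(fit)
        assert se.loc["r", "se"] == pytest.approx(0.001 * 2.0, rel=1e-9)
        assert se.loc["r", "ci_low"] == 0.0  # truncated, matching reported style
        assert se.loc["S", "ci_high"] <= 1.0
        assert se.loc["S", "se"] == pytest.approx(0.88 * 0.12 * 0.1, rel=1e-9)

    def test_missing_covariance_is_explicit(self):
        with pytest.raises(ValueError):
            standard_errors(_stub_fit(0.0, 2))


class TestLikelihoodRatioTest:
    def test_published_deviances_give_854(self):
        stat, df, p = likelihood_ratio_test(_stub_fit(198_878.0, 4, "homogeneous"),
                                            _stub_fit(198_024.0, 7))
        assert stat == pytest.approx(854.0)
        assert df == 3
        assert p < 0.001

    def test_identical_fits(self):
        stat, df, p = likelihood_ratio_test(_stub_fit(100.0, 4, "homogeneous"),
                                            _stub_fit(100.0, 7))
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            likelihood_ratio_test(_stub_fit(99.0, 4, "homogeneous"), _stub_fit(100.0, 7))


@pytest.fixture(scope="module")
def fixture_5000():
    config = SimulationConfig(n_women=5_000, seed=31)
    cohort, _ = simulate_cohort(config)
    return cohort


class TestFitting:
    def test_optimum_beats_random_perturbations(self, recovery_fit):
        cohort, _, fit = recovery_fit
        rng = np.random.default_rng(0)
        from screenmsm.inference import _unpack

        best = fit.minus2loglik
        for _ in range(100):
            x = fit.x + rng.normal(0, 0.05, size=fit.x.size)
            p = _unpack(x, fit.params, fit.free_names, fit.model_kind)
            m2 = -2 * cohort_loglik(cohort, p, A, condition_on_entry=True)
            assert m2 >= best - 1e-6

    def test_minus2loglik_reproducible_from_estimates(self, recovery_fit):
        cohort, _, fit = recovery_fit
        m2 = -2 * cohort_loglik(cohort, fit.params, A, condition_on_entry=True)
        assert m2 == pytest.approx(fit.minus2loglik, abs=1e-8)

    def test_quasi_newton_and_nelder_mead_agree(self, fixture_5000):
        from scipy import optimize

        from screenmsm.inference import _unpack, default_init, _free_names

        fit = fit_mle(fixture_5000, A, "nonhomogeneous", seed=31,
                      condition_on_entry=True, compute_hessian=False)
        init = default_init(fixture_5000, "nonhomogeneous")
        names = _free_names("nonhomogeneous", init)

        def obj(x):
            p = _unpack(x, init, names, "nonhomogeneous")
            ll = cohort_loglik(fixture_5000, p, A, condition_on_entry=True)
            return -ll if np.isfinite(ll) else 1e12

        nm = optimize.minimize(obj, _pack(init, names), method="Nelder-Mead",
                               options={"maxfev": 6000, "fatol": 1e-8, "xatol": 1e-8})
        assert 2 * nm.fun == pytest.approx(fit.minus2loglik, abs=1e-3)

    def test_r_boundary_flagged_when_truth_has_no_nonprogressive(self):
        config = SimulationConfig(n_women=3_000, seed=41, params=REF.with_values(r=0.0))
        cohort, _ = simulate_cohort(config)
        fit = fit_mle(cohort, A, "nonhomogeneous", seed=41,
                      condition_on_entry=True, compute_hessian=False)
        assert fit.params.r < 1e-4

    def test_noninterior_init_rejected(self, fixture_5000):
        with pytest.raises(ValueError):
            fit_mle(
                fixture_5000,
                A,
                "nonhomogeneous",
                init=ModelParameters(
                    lambda12=(0.0015, 0.003, 0.003),
                    lambda23=(0.4,) * 3,
                    r=0.0,  # on the boundary: log transform undefined
                    S=0.9,
                ),
            )

    def test_carry_forward_bias_on_natural_mode_is_small(self):
        """Fitting the carry-forward likelihood to data where every screen is
        an independent Bernoulli(S) test shifts the sensitivity estimate only
        slightly (common random numbers: same seed for both modes)."""
        estimates = {}
        for mode in ("model_faithful", "natural"):
            config = SimulationConfig(n_women=15_000, seed=51, mode=mode)
            cohort, _ = simulate_cohort(config)
            fit = fit_mle(cohort, A, "nonhomogeneous", seed=51,
                          condition_on_entry=True, compute_hessian=False)
            estimates[mode] = fit.params.S
        assert abs(estimates["natural"] - estimates["model_faithful"]) < 0.05
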