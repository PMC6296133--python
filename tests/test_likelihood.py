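"""Observed-data likelihood: emissions, densities, and the forward recursion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.linalg import expm

from screenmsm import (
    AgePartition,
    Cohort,
    ModelParameters,
    ScreeningHistory,
    SimulationConfig,
    clinical_onset_density,
    cohort_loglik,
    history_loglik,
    misclassification_matrix,
    simulate_cohort,
    transition_quantities,
)

A = AgePartition()
REF = ModelParameters(
    lambda12=(0.0015, 0.00276, 0.00381), lambda23=(0.385, 0.464, 0.284), r=0.00182, S=0.88
)


def _history(screens, outcome="no_cancer", outcome_age=None, censor=None, invited=None):
    screens = tuple(screens)
    invited = tuple(invited) if invited is not None else screens
    if censor is None:
        censor = outcome_age if outcome_age is not None else (screens[-1] if screens else 70.0)
    return ScreeningHistory(
        woman_id=0,
        invited_ages=invited or (50.0,),
        screen_ages=screens,
        outcome=outcome,
        outcome_age=outcome_age,
        censor_age=censor,
    )


class TestMisclassification:
    def test_matrix_structure(self):
        E = misclassification_matrix(0.88)
        assert np.allclose(E.sum(axis=1), 1.0)
        assert E[0, 1] == 0.0  # cancer-free never recorded as a case
        assert E[1, 1] == E[3, 1] == 0.88
        assert E[1, 0] == pytest.approx(0.12)
        assert E[2, 2] == 1.0

    def test_perfect_test(self):
        E = misclassification_matrix(1.0)
        assert E[1, 0] == 0.0 and E[3, 0] == 0.0

    @pytest.mark.parametrize("S", [-0.1, 1.1])
    def test_domain(self, S):
        with pytest.raises(ValueError):
            misclassification_matrix(S)


class TestClinicalOnsetDensity:
    def test_two_stage_convolution_formula(self):
        """r = 0, constant rates: textbook series-of-exponentials density."""
        l12, l23 = 0.004, 0.3
        p = ModelParameters(lambda12=(l12,) * 3, lambda23=(l23,) * 3, r=0.0, S=0.9)
        for tau in (0.5, 3.0, 12.0):
            expected = l12 * l23 * (np.exp(-l12 * tau) - np.exp(-l23 * tau)) / (l23 - l12)
            assert clinical_onset_density(p, A, 45.0, 45.0 + tau) == pytest.approx(
                expected, rel=1e-12
            )

    def test_matches_finite_difference_of_p13(self):
        h = 1e-5
        for s, u in [(42.0, 48.0), (45.0, 57.0), (51.0, 66.0)]:
            fd = (
                float(transition_quantities(REF, A, s, u + h)["P13"])
                - float(transition_quantities(REF, A, s, u - h)["P13"])
            ) / (2 * h)
            assert clinical_onset_density(REF, A, s, u) == pytest.approx(fd, abs=1e-6)

    def test_total_clinical_mass_is_progressive_share(self):
        """Integrated to infinity the density reaches 1/(1+r)."""
        p = ModelParameters(lambda12=(0.01,) * 3, lambda23=(0.3,) * 3, r=0.25, S=0.9)
        total, err = quad(
            lambda u: clinical_onset_density(p, A, 40.0, u), 40.0, 3000.0, limit=400
        )
        assert total == pytest.approx(1.0 / 1.25, abs=1e-6)

    def test_domain(self):
        with pytest.raises(ValueError):
            clinical_onset_density(REF, A, 50.0, 50.0)


class TestHistoryLoglik:
    def test_perfect_test_single_negative_screen(self):
        p = REF.with_values(S=1.0)
        h = _history([50.0], censor=50.0, invited=[50.0])
        expect = float(transition_quantities(p, A, 40.0, 50.0)["P11"])
        assert history_loglik(h, p, A) == pytest.approx(np.log(expect), abs=1e-12)

    def test_detection_at_second_screen_decomposition(self):
        """Detection after one negative: newly-entered-and-detected mass plus
        missed-at-previous-screen mass (the A/B structure)."""
        p = REF
        h = _history([50.0, 52.0], "screen_detected", 52.0, invited=[50.0, 52.0])
        q1 = {k: float(v) for k, v in transition_quantities(p, A, 40.0, 50.0).items()}
        q2 = {k: float(v) for k, v in transition_quantities(p, A, 50.0, 52.0).items()}
        expect = q1["P11"] * (q2["P12"] + q2["P14"]) * p.S + (
            q1["P14"] + q1["P12"] * q2["P22"]
        ) * (1 - p.S)
        assert history_loglik(h, p, A) == pytest.approx(np.log(expect), rel=1e-12)

    def test_invalid_detection_age_rejected(self):
        with pytest.raises(ValueError):
            _history([50.0, 52.0], "screen_detected", 51.0, invited=[50.0, 52.0])

    @given(
        gap1=st.floats(0.5, 6.0),
        gap2=st.floats(0.5, 6.0),
        tail=st.floats(0.1, 6.0),
        l12=st.floats(1e-4, 0.05),
        l23=st.floats(0.05, 1.0),
        r=st.floats(0.0, 0.3),
        S=st.floats(0.3, 0.99),
    )
    @settings(max_examples=15, deadline=None)
    def test_outcome_partition_sums_to_one(self, gap1, gap2, tail, l12, l23, r, S):
        """Detections, clinical diagnoses (integrated over their gaps) and
        censoring exhaust the outcome space for an attend-all schedule."""
        p = ModelParameters(lambda12=(l12,) * 3, lambda23=(l23,) * 3, r=r, S=S)
        screens = [50.0, 50.0 + gap1, 50.0 + gap1 + gap2]
        censor = screens[-1] + tail
        total = _partition_total(p, screens, censor)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_three_state_reduction_matches_expm_oracle(self):
        """r = 0 collapses to the classical progressive three-state model; an
        independent matrix-exponential product must reproduce the screen
        factors."""
        p = REF.with_values(r=0.0)

        def P3(s, t):
            out = np.eye(3)
            for lo, hi, k in [(s, 50.0, 0), (50.0, 60.0, 1), (60.0, t, 2)]:
                lo, hi = max(s, min(lo, t)), max(s, min(hi, t))
                if hi > lo:
                    G = np.array(
                        [
                            [-p.lambda12[k], p.lambda12[k], 0.0],
                            [0.0, -p.lambda23[k], p.lambda23[k]],
                            [0.0, 0.0, 0.0],
                        ]
                    )
                    out = out @ expm(G * (hi - lo))
            return out

        h = _history([50.0, 52.0], "screen_detected", 52.0, invited=[50.0, 52.0])
        Pa, Pb = P3(40.0, 50.0), P3(50.0, 52.0)
        expect = Pa[0, 0] * Pb[0, 1] * p.S + Pa[0, 1] * Pb[1, 1] * (1 - p.S)
        assert history_loglik(h, p, A) == pytest.approx(np.log(expect), rel=1e-10)

        h2 = _history([50.0, 53.0], censor=56.0, invited=[50.0, 53.0])
        Pc = P3(50.0, 53.0)
        Pd = P3(53.0, 56.0)
        # healthy through both screens with no clinical phase by censoring,
        # or missed at the second screen and still preclinical at censoring
        expect2 = Pa[0, 0] * Pc[0, 0] * (1 - Pd[0, 2]) + Pa[0, 0] * Pc[0, 1] * (
            1 - p.S
        ) * Pd[1, 1]
        assert history_loglik(h2, p, A) == pytest.approx(np.log(expect2), rel=1e-10)


def _partition_total(p, screens, censor):
    total = 0.0
    invited = list(screens)
    for k in range(len(screens)):
        h = _history(
            screens[: k + 1], "screen_detected", screens[k], censor=screens[k],
            invited=invited,
        )
        total += np.exp(history_loglik(h, p, A))
    gaps = [(40.0, screens[0])] + [
        (screens[j], screens[j + 1]) for j in range(len(screens) - 1)
    ] + [(screens[-1], censor)]
    for j, (lo, hi) in enumerate(gaps):
        if hi <= lo:
            continue
        n_neg = j  # screens attended before this gap

        def dens(u):
            h = _history(
                screens[:n_neg], "clinical", u, censor=max(u, censor), invited=invited
            )
            return np.exp(history_loglik(h, p, A))

        mass, _ = quad(dens, lo + 1e-12, hi, limit=200)
        total += mass
    h = _history(screens, censor=censor, invited=invited)
    total += np.exp(history_loglik(h, p, A))
    return total


class TestCohortLoglik:
    def test_cohort_is_sum_of_histories_and_doubles_when_duplicated(self):
        h1 = _history([50.0, 52.0], censor=54.0)
        h2 = _history([51.0], "clinical", 53.5, censor=53.5, invited=[51.0, 53.0])
        c = Cohort([h1, h2])
        ll = cohort_loglik(c, REF, A)
        assert ll == pytest.approx(
            history_loglik(h1, REF, A) + history_loglik(h2, REF, A), rel=1e-12
        )
        assert cohort_loglik(Cohort([h1, h2, h1, h2]), REF, A) == pytest.approx(
            2 * ll, rel=1e-12
        )

    def test_never_attender_contributions(self):
        censored = ScreeningHistory(0, (50.0, 52.0), censor_age=54.0)
        q = transition_quantities(REF, A, 40.0, 54.0)
        assert history_loglik(censored, REF, A) == pytest.approx(
            np.log(1.0 - float(q["P13"])), rel=1e-12
        )
        clin = ScreeningHistory(
            1, (50.0,), outcome="clinical", outcome_age=55.0, censor_age=55.0
        )
        assert history_loglik(clin, REF, A) == pytest.approx(
            np.log(clinical_onset_density(REF, A, 40.0, 55.0)), rel=1e-12
        )

    def test_outcome_frequencies_match_likelihood(self):
        """End-to-end: relative frequencies of every observable outcome in a
        model-faithful simulation match the likelihood's category
        probabilities (after conditioning on cohort entry) within MC error."""
        n = 150_000
        config = SimulationConfig(
            n_women=n, seed=7, participation_prob=1.0, entry_jitter=0.0
        )
        cohort, _ = simulate_cohort(config)
        screens = [50.0 + 2 * k for k in range(10)]
        censor = 70.0
        p = config.params

        probs = {}
        a1, a2, a4, t_prev = 1.0, 0.0, 0.0, 40.0
        for j, t in enumerate(screens):
            q = {k: float(v) for k, v in transition_quantities(p, A, t_prev, t).items()}
            probs[("det", j)] = a1 * (q["P12"] + q["P14"]) * p.S + a2 * q["P22"] + a4
            if j > 0:
                probs[("clin", j)] = a1 * q["P13"] + a2 * q["P23"]
            a1, a2, a4 = a1 * q["P11"], a1 * q["P12"] * (1 - p.S), a1 * q["P14"] * (1 - p.S)
            t_prev = t
        q = {k: float(v) for k, v in transition_quantities(p, A, t_prev, censor).items()}
        probs[("clin", len(screens))] = a1 * q["P13"] + a2 * q["P23"]
        probs[("cens", 0)] = a1 * (1 - q["P13"]) + a2 * q["P22"] + a4
        norm = sum(probs.values())  # = 1 - P13(40, 50): entry conditioning

        counts = {}
        for h in cohort:
            if h.outcome == "screen_detected":
                key = ("det", screens.index(round(h.outcome_age)))
            elif h.outcome == "clinical":
                key = ("clin", sum(1 for t in screens if t < h.outcome_age))
            else:
                key = ("cens", 0)
            counts[key] = counts.get(key, 0) + 1
        m = len(cohort)
        for key, prob in probs.items():
            pk = prob / norm
            freq = counts.get(key, 0) / m
            se = np.sqrt(pk * (1 - pk) / m)
            assert abs(freq - pk) < 3.5 * se, (key, freq, pk)

    def test_finite_and_continuous_in_parameters(self):
        cohort = Cohort(
            [
                _history([50.0, 52.0], censor=54.0),
                _history([50.0], "screen_detected", 50.0, invited=[50.0]),
            ]
        )
        base = cohort_loglik(cohort, REF, A)
        bumped = cohort_loglik(
            cohort, REF.with_values(lambda23=tuple(v * (1 + 1e-9) for v in REF.lambda23)), A
        )
        assert np.isfinite(base)
        assert bumped == pytest.approx(base, abs=1e-6)
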