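"""Overdiagnosis: expected screen-detected non-progressive cancers.

A screen-detected cancer is overdiagnosed here when it is non-progressive
(latent state 4): it would never have surfaced clinically.  For a woman
detected at her k-th attended screen (age t_k, previous attended screens at
t_{k-1} and t_{k-2}), the probability that the detection is non-progressive is

    (A1 + A2) / ((A1 + B1) + (A2 + B2))

where, writing P_ij for the fitted transition probabilities and S for the
fitted sensitivity,

    A1 = P11(t_{k-2}, t_{k-1}) · P14(t_{k-1}, t_k) · S
    B1 = P11(t_{k-2}, t_{k-1}) · P12(t_{k-1}, t_k) · S
    A2 = P14(t_{k-2}, t_{k-1}) · (1 − S)
    B2 = P12(t_{k-2}, t_{k-1}) · P22(t_{k-1}, t_k) · (1 − S)

A1/B1 are the newly-entered-and-detected paths, A2/B2 the missed-at-the-
previous-screen paths (the probability of remaining in state 4 is one, so no
persistence factor appears in A2).  At a woman's first (prevalent) screen
there is no missed-carryover term and the sensitivity cancels, leaving
P14(t0, t1) / (P14(t0, t1) + P12(t0, t1)) with the belief anchored in state 1
at the initiation age t0 — the minimal model-consistent choice for a round
the displayed formula does not cover.  For a woman's second screen, t_{k-2}
is likewise replaced by t0.

The expected number of non-progressive detections per round class is the sum
of these per-case probabilities, each evaluated at the woman's own attended
screen ages (irregular gaps from missed invitations are respected).
Uncertainty is propagated by redrawing the fitted parameters from a
multivariate normal on the transformed (log/logit) scale — which guarantees
valid parameters — and taking percentiles of the recomputed fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort
from .inference import FitResult, _unpack
from .model import AgePartition, ModelParameters, transition_quantities

__all__ = [
    "OverdiagnosisResult",
    "nonprogressive_probability_prevalent",
    "nonprogressive_probability_subsequent",
    "expected_npbc",
    "overdiagnosis_ci",
]

log = logging.getLogger(__name__)

_CLASSES = ("prevalent", "subsequent", "overall")


@dataclass
class OverdiagnosisResult:
    """Per-round-class screen-detected counts, expected non-progressive
    counts, overdiagnosis fractions, and (optionally) simulation CIs."""

    screen_detected: dict[str, int]
    expected_npbc: dict[str, float]
    fraction: dict[str, float]
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in _CLASSES:
            lo, hi = self.ci95.get(c, (np.nan, np.nan))
            rows.append(
                {
                    "round": c,
                    "screen_detected": self.screen_detected[c],
                    "expected_npbc": self.expected_npbc[c],
                    "fraction": self.fraction[c],
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
        return pd.DataFrame(rows)


def nonprogressive_probability_prevalent(
    params: ModelParameters, partition: AgePartition, t_1
):
    """Probability a detection at a first-ever screen is non-progressive."""
    t_1 = np.asarray(t_1, dtype=float)
    if np.any(t_1 <= partition.t0):
        raise ValueError("first screen age must exceed the initiation age t0")
    q = transition_quantities(params, partition, partition.t0, t_1)
    out = _safe_ratio(q["P14"], q["P14"] + q["P12"])
    return out if out.ndim else float(out)


def nonprogressive_probability_subsequent(
    params: ModelParameters, partition: AgePartition, t_km2, t_km1, t_k
):
    """Probability a detection at a subsequent screen is non-progressive."""
    t_km2, t_km1, t_k = np.broadcast_arrays(
        np.asarray(t_km2, float), np.asarray(t_km1, float), np.asarray(t_k, float)
    )
    if np.any(t_km2 >= t_km1) or np.any(t_km1 >= t_k):
        raise ValueError("screen ages must be strictly increasing")
    S = params.S
    q_prev = transition_quantities(params, partition, t_km2, t_km1)
    q_cur = transition_quantities(params, partition, t_km1, t_k)
    a1 = q_prev["P11"] * q_cur["P14"] * S
    b1 = q_prev["P11"] * q_cur["P12"] * S
    a2 = q_prev["P14"] * (1.0 - S)
    b2 = q_prev["P12"] * q_cur["P22"] * (1.0 - S)
    out = _safe_ratio(a1 + a2, a1 + b1 + a2 + b2)
    return out if out.ndim else float(out)


def _safe_ratio(num, den):
    num = np.asarray(num, float)
    den = np.asarray(den, float)
    return np.divide(num, den, out=np.zeros_like(num), where=den > 0)


def _case_screen_ages(cohort: Cohort, partition: AgePartition):
    """Split screen-detected cases into prevalent and subsequent with the
    (t_{k-2}, t_{k-1}, t_k) triplets the formula needs."""
    t0 = partition.t0
    prevalent_t1 = []
    triplets = []
    for h in cohort:
        if h.outcome != "screen_detected":
            continue
        s = h.screen_ages
        if len(s) == 1:
            prevalent_t1.append(s[-1])
        else:
            t_km2 = s[-3] if len(s) >= 3 else t0
            triplets.append((t_km2, s[-2], s[-1]))
    return np.array(prevalent_t1), np.array(triplets).reshape(-1, 3)


def _expected_from_params(
    params: ModelParameters,
    partition: AgePartition,
    prevalent_t1: np.ndarray,
    triplets: np.ndarray,
) -> tuple[float, float]:
    e_prev = (
        float(
            np.sum(nonprogressive_probability_prevalent(params, partition, prevalent_t1))
        )
        if prevalent_t1.size
        else 0.0
    )
    e_sub = (
        float(
            np.sum(
                nonprogressive_probability_subsequent(
                    params, partition, triplets[:, 0], triplets[:, 1], triplets[:, 2]
                )
            )
        )
        if triplets.size
        else 0.0
    )
    return e_prev, e_sub


def expected_npbc(
    cohort: Cohort,
    fit: FitResult | ModelParameters,
    partition: AgePartition | None = None,
) -> OverdiagnosisResult:
    """Point estimates of expected non-progressive detections per round class."""
    if isinstance(fit, FitResult):
        params = fit.params
        partition = partition or fit.partition
    else:
        params = fit
    partition = partition or AgePartition()
    prevalent_t1, triplets = _case_screen_ages(cohort, partition)
    n_prev, n_sub = prevalent_t1.size, triplets.shape[0]
    if n_prev + n_sub == 0:
        log.warning("no screen-detected cases in cohort; overdiagnosis is zero")
    e_prev, e_sub = _expected_from_params(params, partition, prevalent_t1, triplets)
    counts = {"prevalent": n_prev, "subsequent": n_sub, "overall": n_prev + n_sub}
    expected = {"prevalent": e_prev, "subsequent": e_sub, "overall": e_prev + e_sub}
    fraction = {
        c: (expected[c] / counts[c] if counts[c] > 0 else 0.0) for c in _CLASSES
    }
    return OverdiagnosisResult(counts, expected, fraction)


def overdiagnosis_ci(
    cohort: Cohort,
    fit: FitResult,
    partition: AgePartition | None = None,
    n_draws: int = 1000,
    seed: int = 0,
) -> OverdiagnosisResult:
    """Point estimates plus 95% percentile intervals from parameter draws.

    Parameter vectors are drawn from MVN(MLE, covariance) on the transformed
    scale, so every draw maps to valid natural parameters; the overdiagnosis
    fractions are recomputed for each draw and summarised by their 2.5 and
    97.5 percentiles.
    """
    if fit.cov_transformed is None:
        raise ValueError("fit has no covariance; cannot simulate parameter draws")
    partition = partition or fit.partition or AgePartition()
    result = expected_npbc(cohort, fit, partition)
    prevalent_t1, triplets = _case_screen_ages(cohort, partition)
    counts = result.screen_detected

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(fit.x, fit.cov_transformed, size=n_draws)
    fracs = {c: np.empty(n_draws) for c in _CLASSES}
    for d in range(n_draws):
        p = _unpack(draws[d], fit.params, fit.free_names, fit.model_kind)
        e_prev, e_sub = _expected_from_params(p, partition, prevalent_t1, triplets)
        e = {"prevalent": e_prev, "subsequent": e_sub, "overall": e_prev + e_sub}
        for c in _CLASSES:
            fracs[c][d] = e[c] / counts[c] if counts[c] > 0 else 0.0
    result.ci95 = {
        c: (
            float(np.percentile(fracs[c], 2.5)),
            float(np.percentile(fracs[c], 97.5)),
        )
        for c in _CLASSES
    }
    return result
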