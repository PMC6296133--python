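"""Observed-data likelihood for individual screening histories.

The latent four-state process is observed only through screening: at an
attended screen the observed finding is negative, screen-detected, or (between
screens) a clinical diagnosis.  A woman in the preclinical screen-detectable
phase (PCDP, latent states 2 or 4) is detected at an attended screen with
sensitivity ``S`` and missed with probability ``1 - S``.  Following the usual
simplification, a missed (false-negative) case is detected with certainty at
her next attended screen, unless a progressive case surfaces clinically first.

The per-woman likelihood is a forward recursion over a three-component belief
at the last attended screen: mass still free of cancer (state 1), mass in the
progressive PCDP missed at that screen, and mass in the non-progressive PCDP
missed at that screen.  Because a miss must resolve by the next attended
screen, two consecutive negative findings anchor the state-1 component at the
earlier screen, which keeps the recursion three-dimensional regardless of
history length.

Terminal factors:

* screen detection at age t:   newly entered PCDP mass × S, plus carried
  missed mass (detected with probability one);
* clinical diagnosis at age u: the exact surfacing time is observed, so the
  contribution is a density, λ23(u)·P12(prev, u) from the state-1 component
  plus λ23(u)·P22(prev, u) from carried progressive mass;
* censoring at age c:          probability of no clinical event by c with the
  latent whereabouts marginalised.

Non-participation is non-informative: invitations without attendance add no
factor, but the woman remains under clinical-incidence follow-up, which is how
interval and non-participant cancers inform the fit.
"""

from __future__ import annotations

import numpy as np

from .cohort import Cohort, ScreeningHistory
from .model import AgePartition, ModelParameters, transition_quantities

__all__ = [
    "misclassification_matrix",
    "clinical_onset_density",
    "history_loglik",
    "cohort_loglik",
    "Cohort",
    "ScreeningHistory",
]


def misclassification_matrix(S: float) -> np.ndarray:
    """4×3 emission matrix E[i, j] = Pr(observed j+1 | latent i+1).

    Observed states are (1) negative finding, (2) screen-detected, and
    (3) clinical case.  A woman free of cancer is never recorded as a cancer
    case (false positives are resolved at assessment), and progressive and
    non-progressive preclinical disease share the same sensitivity S.
    """
    if not 0.0 <= S <= 1.0:
        raise ValueError("sensitivity S must lie in [0, 1]")
    return np.array(
        [
            [1.0, 0.0, 0.0],
            [1.0 - S, S, 0.0],
            [0.0, 0.0, 1.0],
            [1.0 - S, S, 0.0],
        ]
    )


def clinical_onset_density(
    params: ModelParameters,
    partition: AgePartition,
    s,
    u,
    from_state: int = 1,
):
    """Density (per year) of clinical surfacing at age ``u``, from state at ``s``.

    For this acyclic chain the derivative of the cumulative clinical
    probability has the closed form λ23(u)·P12(s,u) for a woman in state 1 at
    ``s`` (``from_state=1``), and λ23(u)·P22(s,u) for a woman already in the
    progressive preclinical phase (``from_state=2``).  Vectorised over ``s``
    and ``u``.
    """
    s_arr = np.asarray(s, dtype=float)
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr <= s_arr):
        raise ValueError("u must be strictly greater than s")
    q = transition_quantities(params, partition, s_arr, u_arr)
    idx = partition.interval_index(u_arr)
    l23_u = np.asarray(params.lambda23)[idx]
    if from_state == 1:
        out = l23_u * q["P12"]
    elif from_state == 2:
        out = l23_u * q["P22"]
    else:
        raise ValueError("from_state must be 1 or 2")
    return out if out.ndim else float(out)


def _cohort_likelihoods(
    cohort: Cohort,
    params: ModelParameters,
    partition: AgePartition,
    condition_on_entry: bool = False,
) -> np.ndarray:
    """Per-woman likelihood values (linear scale), vectorised across the cohort."""
    A = cohort.arrays
    n = A.n
    one_minus_S = 1.0 - params.S
    a1 = np.ones(n)
    a2 = np.zeros(n)
    a4 = np.zeros(n)
    t_prev = np.full(n, partition.t0)

    for j in range(A.neg_ages.shape[1]):
        m = A.n_neg > j
        if not m.any():
            break
        t = A.neg_ages[m, j]
        q = transition_quantities(params, partition, t_prev[m], t)
        a1m = a1[m]
        # Carried missed mass resolves (is detected) at this screen, so it is
        # incompatible with the observed negative finding and drops out.
        a2[m] = a1m * q["P12"] * one_minus_S
        a4[m] = a1m * q["P14"] * one_minus_S
        a1[m] = a1m * q["P11"]
        t_prev[m] = t

    lik = np.empty(n)

    m0 = A.outcome_code == 0  # censored, no cancer
    if m0.any():
        q = transition_quantities(params, partition, t_prev[m0], A.censor_age[m0])
        lik[m0] = a1[m0] * (1.0 - q["P13"]) + a2[m0] * q["P22"] + a4[m0]

    m1 = A.outcome_code == 1  # screen-detected
    if m1.any():
        q = transition_quantities(params, partition, t_prev[m1], A.outcome_age[m1])
        lik[m1] = (
            a1[m1] * (q["P12"] + q["P14"]) * params.S
            + a2[m1] * q["P22"]
            + a4[m1]
        )

    m2 = A.outcome_code == 2  # clinical diagnosis at an exactly observed age
    if m2.any():
        u = A.outcome_age[m2]
        q = transition_quantities(params, partition, t_prev[m2], u)
        idx = partition.interval_index(u)
        l23_u = np.asarray(params.lambda23)[idx]
        lik[m2] = l23_u * (a1[m2] * q["P12"] + a2[m2] * q["P22"])

    if condition_on_entry:
        q = transition_quantities(params, partition, partition.t0, A.entry_age)
        lik = lik / (1.0 - q["P13"])
    return lik


def cohort_loglik(
    cohort: Cohort,
    params: ModelParameters,
    partition: AgePartition,
    condition_on_entry: bool = False,
) -> float:
    """Total log-likelihood of a cohort of screening histories.

    ``condition_on_entry`` divides each woman's contribution by her probability
    of being free of clinical cancer at first invitation (left-truncation
    adjustment); it is off by default, matching the model's plain state-1
    anchoring at the initiation age.
    """
    lik = _cohort_likelihoods(cohort, params, partition, condition_on_entry)
    if np.any(lik <= 0.0) or not np.all(np.isfinite(lik)):
        return -np.inf
    return float(np.log(lik).sum())


def history_loglik(
    history: ScreeningHistory,
    params: ModelParameters,
    partition: AgePartition,
    condition_on_entry: bool = False,
) -> float:
    """Log-likelihood contribution of a single woman's history."""
    return cohort_loglik(Cohort([history]), params, partition, condition_on_entry)
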