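"""Latent four-state continuous-time Markov model of breast-cancer natural history.

The disease process ``X(t)`` moves between four latent states:

1. free of breast cancer,
2. progressive preclinical screen-detectable phase (PCDP),
3. clinical phase (symptomatic disease), and
4. non-progressive PCDP (disease that would never surface clinically).

Transitions 1→2 (onset of progressive preclinical disease, rate ``λ12``),
2→3 (clinical surfacing, rate ``λ23``) and 1→4 (onset of non-progressive
disease, rate ``λ14 = r·λ12``) are the only ones allowed; states 3 and 4 are
absorbing.  Rates are piecewise constant on age intervals (by default
``[40, 50), [50, 60), [60, ∞)``) which makes the chain non-homogeneous in age.

Because the chain is acyclic, the transition probability matrix over a piece
with constant rates has a closed form; multi-interval probabilities are
products of piece matrices split at the age cut-points.  All probability
functions here are vectorised over arrays of ages, which is what makes
cohort-scale likelihood evaluation cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "AgePartition",
    "ModelParameters",
    "TransitionProbabilityMatrix",
    "REFERENCE_NONHOMOGENEOUS",
    "REFERENCE_HOMOGENEOUS",
    "rate_matrix_at_age",
    "piece_transition_matrix",
    "transition_matrix",
    "transition_quantities",
    "mean_sojourn_time",
]

# Switch-over band for the removable singularity at λ23 = λ12(1+r): inside the
# band the analytic limit form is used to avoid catastrophic cancellation.
_DEGENERATE_BAND = 1e-8


@dataclass(frozen=True)
class AgePartition:
    """Left-closed age intervals on which transition rates are constant.

    ``cutpoints`` are strictly increasing ages in years; the first cut-point is
    the initiation age ``t0`` of the disease process (women are assumed free of
    breast cancer before it).  The last interval is open-ended.
    """

    cutpoints: tuple[float, ...] = (40.0, 50.0, 60.0)

    def __post_init__(self) -> None:
        cp = tuple(float(c) for c in self.cutpoints)
        if len(cp) < 1:
            raise ValueError("at least one cutpoint (t0) is required")
        if any(b <= a for a, b in zip(cp, cp[1:])):
            raise ValueError(f"cutpoints must be strictly increasing, got {cp}")
        object.__setattr__(self, "cutpoints", cp)

    @property
    def t0(self) -> float:
        return self.cutpoints[0]

    @property
    def n_intervals(self) -> int:
        return len(self.cutpoints)

    def interval_index(self, age):
        """Index of the left-closed interval containing ``age`` (vectorised)."""
        age = np.asarray(age, dtype=float)
        if np.any(age < self.t0):
            raise ValueError(f"age below initiation age t0={self.t0}")
        idx = np.searchsorted(self.cutpoints, age, side="right") - 1
        return idx if idx.ndim else int(idx)


@dataclass(frozen=True)
class ModelParameters:
    """Piecewise-constant transition rates plus shared ratio and sensitivity.

    ``lambda12``/``lambda23`` hold one rate per age interval (events per
    woman-year).  ``r = λ14/λ12`` is a single dimensionless ratio shared across
    intervals, so the non-progressive onset rate is ``r·λ12(t)`` by
    construction.  ``S`` is the test (mammography) sensitivity.  ``fixed``
    names parameters held fixed during estimation; by default the pre-50 onset
    rate, which is identified from external incidence rather than screening
    data.
    """

    lambda12: tuple[float, ...]
    lambda23: tuple[float, ...]
    r: float
    S: float
    fixed: frozenset[str] = field(default_factory=lambda: frozenset({"lambda12_0"}))

    def __post_init__(self) -> None:
        l12 = tuple(float(x) for x in self.lambda12)
        l23 = tuple(float(x) for x in self.lambda23)
        if len(l12) != len(l23):
            raise ValueError("lambda12 and lambda23 must have one entry per interval")
        if any(x < 0 for x in l12 + l23):
            raise ValueError("transition rates must be nonnegative")
        if self.r < 0:
            raise ValueError("r must be nonnegative")
        if not 0.0 <= self.S <= 1.0:
            raise ValueError("sensitivity S must lie in [0, 1]")
        object.__setattr__(self, "lambda12", l12)
        object.__setattr__(self, "lambda23", l23)
        object.__setattr__(self, "fixed", frozenset(self.fixed))

    @property
    def n_intervals(self) -> int:
        return len(self.lambda12)

    def lambda14(self, interval: int) -> float:
        return self.r * self.lambda12[interval]

    def with_values(self, **kwargs) -> "ModelParameters":
        return replace(self, **kwargs)


#: Published non-homogeneous estimates for organized biennial mammography of
#: women 50-69 (Stockholm program): onset 276 and 381 per 1e5 woman-years for
#: 50-59 and 60-69, mean sojourn times 2.60/2.16/3.52 years, r = 0.00182,
#: sensitivity 88%.  The pre-50 onset rate is not separately published; 0.0015
#: per woman-year is this package's synthetic default (logged as such by the
#: simulator).
REFERENCE_NONHOMOGENEOUS = ModelParameters(
    lambda12=(0.0015, 0.00276, 0.00381),
    lambda23=(0.385, 0.464, 0.284),
    r=0.00182,
    S=0.880,
)

#: Matching homogeneous (age-constant) estimates: one onset rate 0.00306, one
#: sojourn rate 0.418, r = 9.999e-4, sensitivity 92.4%.
REFERENCE_HOMOGENEOUS = ModelParameters(
    lambda12=(0.00306,) * 3,
    lambda23=(0.418,) * 3,
    r=9.999e-4,
    S=0.924,
    fixed=frozenset(),
)


class TransitionProbabilityMatrix(np.ndarray):
    """4×4 row-stochastic matrix ``P_ij(s,t)`` over the latent states.

    Thin ndarray subclass: behaves as a plain array but validates the
    structural properties of the chain on construction.
    """

    def __new__(cls, entries):
        arr = np.asarray(entries, dtype=float).view(cls)
        if arr.shape != (4, 4):
            raise ValueError("transition probability matrix must be 4x4")
        if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
            raise ValueError("entries must lie in [0, 1]")
        if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows must sum to 1")
        return arr


def _check_rates_for(params: ModelParameters, partition: AgePartition) -> None:
    if params.n_intervals != partition.n_intervals:
        raise ValueError(
            f"parameters define {params.n_intervals} intervals but partition has "
            f"{partition.n_intervals}"
        )


def rate_matrix_at_age(
    params: ModelParameters, partition: AgePartition, age: float
) -> np.ndarray:
    """Generator (intensity) matrix Λ(t) of the latent chain at a given age.

    Row 1 carries the competing onset hazards λ12 and λ14 = r·λ12; row 2 the
    clinical-surfacing hazard λ23; states 3 and 4 are absorbing.
    """
    _check_rates_for(params, partition)
    k = partition.interval_index(age)
    l12 = params.lambda12[k]
    l23 = params.lambda23[k]
    l14 = params.r * l12
    return np.array(
        [
            [-(l12 + l14), l12, 0.0, l14],
            [0.0, -l23, l23, 0.0],
            [0.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0],
        ]
    )


def _piece_quantities(l12: float, l23: float, r: float, dt):
    """Closed-form P11, P12, P14, P22 for constant rates over elapsed time dt.

    With ``a = λ12(1+r)`` (total exit hazard from state 1):

        P11 = e^{-a·dt}
        P14 = (r·λ12/a)(1 − e^{-a·dt})
        P12 = λ12 (e^{-a·dt} − e^{-λ23·dt}) / (λ23 − a)
        P22 = e^{-λ23·dt}

    with the analytic limit ``P12 = λ12·dt·e^{-a·dt}`` inside a small band
    around the removable singularity λ23 = a, and P14 = 0 when a = 0.
    Vectorised over dt.
    """
    dt = np.asarray(dt, dtype=float)
    a = l12 * (1.0 + r)
    e_a = np.exp(-a * dt)
    e_m = np.exp(-l23 * dt)
    p11 = e_a
    p22 = e_m
    if a > 0.0:
        p14 = (r * l12 / a) * (1.0 - e_a)
    else:
        p14 = np.zeros_like(dt)
    if abs(l23 - a) < _DEGENERATE_BAND:
        p12 = l12 * dt * e_a
    else:
        p12 = l12 * (e_a - e_m) / (l23 - a)
    return p11, p12, p14, p22


def transition_quantities(
    params: ModelParameters, partition: AgePartition, s, t
) -> dict[str, np.ndarray]:
    """Vectorised P11, P12, P13, P14, P22, P23 between age arrays ``s`` and ``t``.

    ``s`` and ``t`` broadcast; each pair must satisfy ``t0 <= s <= t``.  The
    interval from s to t is split at every partition cut-point and the piece
    closed forms are composed in order, using the chain structure:

        P11(s,t) = P11(s,m)·P11(m,t)
        P12(s,t) = P11(s,m)·P12(m,t) + P12(s,m)·P22(m,t)
        P14(s,t) = P11(s,m)·P14(m,t) + P14(s,m)
        P22(s,t) = P22(s,m)·P22(m,t)
    """
    _check_rates_for(params, partition)
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    s, t = np.broadcast_arrays(s, t)
    if np.any(s < partition.t0):
        raise ValueError(f"start age below initiation age t0={partition.t0}")
    if np.any(t < s):
        raise ValueError("end age must be >= start age")

    cuts = partition.cutpoints
    p11 = np.ones_like(s, dtype=float)
    p12 = np.zeros_like(s, dtype=float)
    p14 = np.zeros_like(s, dtype=float)
    p22 = np.ones_like(s, dtype=float)
    for k in range(len(cuts)):
        lo = np.clip(s, cuts[k], None)
        hi = t if k == len(cuts) - 1 else np.clip(t, None, cuts[k + 1])
        dt = np.maximum(hi - lo, 0.0)
        q11, q12, q14, q22 = _piece_quantities(
            params.lambda12[k], params.lambda23[k], params.r, dt
        )
        p12 = p11 * q12 + p12 * q22
        p14 = p11 * q14 + p14
        p11 = p11 * q11
        p22 = p22 * q22
    p13 = np.clip(1.0 - p11 - p12 - p14, 0.0, 1.0)
    return {
        "P11": p11,
        "P12": p12,
        "P13": p13,
        "P14": p14,
        "P22": p22,
        "P23": 1.0 - p22,
    }


def _matrix_from_quantities(q) -> TransitionProbabilityMatrix:
    return TransitionProbabilityMatrix(
        [
            [float(q["P11"]), float(q["P12"]), float(q["P13"]), float(q["P14"])],
            [0.0, float(q["P22"]), float(q["P23"]), 0.0],
            [0.0, 0.0, 1.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def piece_transition_matrix(
    params: ModelParameters, interval_index: int, dt: float
) -> TransitionProbabilityMatrix:
    """Transition probability matrix over elapsed time ``dt`` within one interval."""
    if dt < 0:
        raise ValueError("dt must be nonnegative")
    l12 = params.lambda12[interval_index]
    l23 = params.lambda23[interval_index]
    p11, p12, p14, p22 = _piece_quantities(l12, l23, params.r, float(dt))
    q = {
        "P11": p11,
        "P12": p12,
        "P13": np.clip(1.0 - p11 - p12 - p14, 0.0, 1.0),
        "P14": p14,
        "P22": p22,
        "P23": 1.0 - p22,
    }
    return _matrix_from_quantities(q)


def transition_matrix(
    params: ModelParameters, partition: AgePartition, s: float, t: float
) -> TransitionProbabilityMatrix:
    """Transition probability matrix P(s,t) between two ages (scalar interface)."""
    q = transition_quantities(params, partition, float(s), float(t))
    return _matrix_from_quantities(q)


def mean_sojourn_time(lambda23: float) -> float:
    """Mean sojourn time in the progressive preclinical phase, 1/λ23, in years."""
    if lambda23 <= 0:
        raise ValueError("lambda23 must be positive")
    return 1.0 / lambda23
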