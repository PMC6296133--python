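"""Synthetic screening-cohort generator.

Emulates an organized biennial mammography program for women 50-69: each woman
receives invitations every two years from (a jittered) age 50 until age 69,
attends each independently with a fixed participation probability, and is
censored two years after her last invitation.  Latent disease follows the
four-state natural-history model: onset out of the cancer-free state with
hazard λ12(t)(1+r), destination non-progressive with probability r/(1+r),
and, for progressive disease, clinical surfacing with hazard λ23(t).

Two observation modes are supported:

* ``model_faithful`` — a case missed at an attended screen (probability 1-S)
  is detected with certainty at her next attended screen unless she surfaces
  clinically first.  This reproduces exactly the false-negative carry-forward
  simplification of the likelihood, so estimation on this mode is a clean
  parameter-recovery exercise.
* ``natural`` — every attended screen is an independent Bernoulli(S) test,
  i.e. repeated false negatives can occur; fitting the carry-forward
  likelihood to this mode quantifies the bias the simplification induces.

Women whose (progressive) cancer surfaces clinically before their first
invitation never enter the cohort, as in a screening register; they are
reported in the ground-truth sidecar with ``excluded=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, ScreeningHistory
from .model import AgePartition, ModelParameters, REFERENCE_NONHOMOGENEOUS

__all__ = [
    "SimulationConfig",
    "LatentTrajectory",
    "simulate_latent_trajectory",
    "simulate_latent_trajectories",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and truth parameters for cohort simulation.

    Defaults mirror the program the model is built for: biennial invitations
    at ages 50-69, 72.7% participation per invitation, ~2% benign recalls per
    attended screen, censoring two years after the last invitation.  The
    default truth parameters are the published non-homogeneous estimates
    (see :data:`screenmsm.model.REFERENCE_NONHOMOGENEOUS`).
    """

    n_women: int = 20_000
    params: ModelParameters = REFERENCE_NONHOMOGENEOUS
    partition: AgePartition = field(default_factory=AgePartition)
    first_invite_age: float = 50.0
    entry_jitter: float = 1.0  # first invitation uniform on ±jitter years
    invite_interval: float = 2.0
    last_invite_age: float = 69.0
    participation_prob: float = 0.727
    false_positive_recall_prob: float = 0.02
    study_end_age: float = np.inf
    mode: str = "model_faithful"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_women < 1:
            raise ValueError("n_women must be >= 1")
        for name in ("participation_prob", "false_positive_recall_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mode not in ("model_faithful", "natural"):
            raise ValueError("mode must be 'model_faithful' or 'natural'")
        if self.first_invite_age - self.entry_jitter < self.partition.t0:
            raise ValueError("first invitation (minus jitter) must be at or after t0")
        if self.last_invite_age < self.first_invite_age:
            raise ValueError("last_invite_age must be >= first_invite_age")
        if self.invite_interval <= 0:
            raise ValueError("invite_interval must be positive")


@dataclass(frozen=True)
class LatentTrajectory:
    """One woman's latent disease path."""

    onset_age: float | None
    destination: str | None  # "progressive" | "non_progressive"
    clinical_age: float | None

    def __post_init__(self) -> None:
        if self.destination not in (None, "progressive", "non_progressive"):
            raise ValueError(f"unknown destination {self.destination!r}")
        if self.destination == "non_progressive" and self.clinical_age is not None:
            raise ValueError("non-progressive disease never surfaces clinically")
        if self.clinical_age is not None and self.clinical_age <= self.onset_age:
            raise ValueError("clinical age must exceed onset age")


def _piecewise_exponential_ages(
    rates: np.ndarray, cuts: tuple[float, ...], start: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Event ages from a piecewise-constant hazard, by inversion of the
    cumulative hazard from per-element start ages; +inf where no event occurs."""
    n = start.shape[0]
    rem = rng.exponential(size=n)
    age = np.full(n, np.inf)
    done = np.zeros(n, dtype=bool)
    for k, rate in enumerate(rates):
        hi = cuts[k + 1] if k + 1 < len(cuts) else np.inf
        lo = np.clip(start, cuts[k], hi)
        width = hi - lo
        if rate <= 0.0:
            continue
        need = rem / rate
        hit = ~done & (need <= width)
        age[hit] = lo[hit] + need[hit]
        done |= hit
        if np.isfinite(hi):
            rem = np.where(~done, rem - rate * width, rem)
    return age


def simulate_latent_trajectories(
    params: ModelParameters,
    partition: AgePartition,
    n: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Vectorised latent paths for ``n`` women starting cancer-free at t0.

    Returns a frame with ``onset_age`` (inf if none), ``non_progressive``
    (bool) and ``clinical_age`` (inf for non-progressive or no onset).
    """
    cuts = partition.cutpoints
    exit_rates = np.array(params.lambda12) * (1.0 + params.r)
    start = np.full(n, partition.t0)
    onset = _piecewise_exponential_ages(exit_rates, cuts, start, rng)
    nonprog = rng.random(n) < (params.r / (1.0 + params.r) if params.r > 0 else 0.0)
    clinical = np.full(n, np.inf)
    prog = np.isfinite(onset) & ~nonprog
    if prog.any():
        clinical[prog] = _piecewise_exponential_ages(
            np.array(params.lambda23), cuts, onset[prog], rng
        )
    nonprog = nonprog & np.isfinite(onset)
    return pd.DataFrame(
        {"onset_age": onset, "non_progressive": nonprog, "clinical_age": clinical}
    )


def simulate_latent_trajectory(
    params: ModelParameters, partition: AgePartition, rng: np.random.Generator
) -> LatentTrajectory:
    """Single latent path (scalar convenience over the vectorised generator)."""
    row = simulate_latent_trajectories(params, partition, 1, rng).iloc[0]
    if not np.isfinite(row.onset_age):
        return LatentTrajectory(None, None, None)
    if row.non_progressive:
        return LatentTrajectory(float(row.onset_age), "non_progressive", None)
    clinical = float(row.clinical_age) if np.isfinite(row.clinical_age) else None
    return LatentTrajectory(float(row.onset_age), "progressive", clinical)


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, pd.DataFrame]:
    """Generate a cohort of screening histories plus a ground-truth sidecar.

    The sidecar has one row per simulated woman (including the excluded
    pre-entry clinical cases): latent onset age, destination, clinical age,
    whether and when she was screen-detected, and whether a detection was of
    non-progressive disease — the labels against which the overdiagnosis
    formula is validated.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_women
    latent = simulate_latent_trajectories(config.params, config.partition, n, rng)

    if config.entry_jitter > 0:
        entry = config.first_invite_age + rng.uniform(
            -config.entry_jitter, config.entry_jitter, size=n
        )
    else:
        entry = np.full(n, config.first_invite_age)
    max_rounds = (
        int(
            np.floor(
                (config.last_invite_age - (config.first_invite_age - config.entry_jitter))
                / config.invite_interval
            )
        )
        + 1
    )
    u_attend = rng.random((n, max_rounds))
    u_detect = rng.random((n, max_rounds))
    u_recall = rng.random((n, max_rounds))

    S = config.params.S
    faithful = config.mode == "model_faithful"
    onset = latent["onset_age"].to_numpy()
    nonprog = latent["non_progressive"].to_numpy()
    clin = latent["clinical_age"].to_numpy()

    histories: list[ScreeningHistory] = []
    truth_rows: list[dict] = []
    for i in range(n):
        row = {
            "woman_id": i,
            "onset_age": onset[i] if np.isfinite(onset[i]) else np.nan,
            "destination": (
                "non_progressive"
                if nonprog[i]
                else ("progressive" if np.isfinite(onset[i]) else None)
            ),
            "clinical_age": clin[i] if np.isfinite(clin[i]) else np.nan,
            "detected_age": np.nan,
            "detected_non_progressive": False,
            "excluded": False,
        }
        if clin[i] <= entry[i]:
            # diagnosed clinically before first invitation: never enters
            row["excluded"] = True
            truth_rows.append(row)
            continue

        invites: list[float] = []
        screens: list[float] = []
        recalls: list[float] = []
        outcome = "no_cancer"
        outcome_age: float | None = None
        missed = False
        t = entry[i]
        last_invite = entry[i]
        k = 0
        while t <= config.last_invite_age + 1e-9 and t <= config.study_end_age:
            if clin[i] <= t:
                break  # surfaced clinically before this invitation
            invites.append(t)
            last_invite = t
            if u_attend[i, k] < config.participation_prob:
                in_pcdp = onset[i] <= t and (nonprog[i] or clin[i] > t)
                if in_pcdp:
                    if (faithful and missed) or u_detect[i, k] < S:
                        screens.append(t)
                        outcome = "screen_detected"
                        outcome_age = t
                        row["detected_age"] = t
                        row["detected_non_progressive"] = bool(nonprog[i])
                        break
                    missed = True
                    screens.append(t)
                else:
                    screens.append(t)
                    if u_recall[i, k] < config.false_positive_recall_prob:
                        recalls.append(t)
            k += 1
            t = entry[i] + k * config.invite_interval

        censor = min(config.study_end_age, last_invite + config.invite_interval)
        if outcome == "no_cancer" and np.isfinite(clin[i]) and clin[i] <= censor:
            outcome = "clinical"
            outcome_age = float(clin[i])
            censor = float(clin[i]) if censor < clin[i] else censor
        if outcome_age is not None:
            censor = max(censor, outcome_age)
        histories.append(
            ScreeningHistory(
                woman_id=i,
                invited_ages=tuple(invites),
                screen_ages=tuple(screens),
                recall_ages=tuple(recalls),
                outcome=outcome,
                outcome_age=outcome_age,
                censor_age=float(censor),
            )
        )
        truth_rows.append(row)

    truth = pd.DataFrame(truth_rows)
    return Cohort(histories), truth
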