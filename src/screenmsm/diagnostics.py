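"""Observed versus expected cumulative incidence among ever-attenders.

The goodness-of-fit display for the fitted natural-history model: within an
age band (50-59 or 60 and above), annual breast-cancer detection rates
(screen-detected plus clinical) among women with at least one attended screen
are compared with the rates the fitted model predicts for the same women
given their actual invitation/attendance schedules and their observed
negative findings.

Expected events are accumulated per woman along her history: at each attended
screen, the model probability of a detection there given her belief state
(conditioned on her earlier negative findings); between anchors, the model
probability mass of a clinical surfacing falling in each one-year age bin.
Follow-up of a clinically detected case is extended to her next supposed
examination time (two years after the latest scheduled invitation), so that
expected detection mass the program would still have observed is not
truncated at her diagnosis.  Both curves share the observed person-year
denominators, and rates are cumulated over one-year age bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort
from .descriptives import person_years
from .inference import FitResult
from .model import AgePartition, ModelParameters, transition_quantities

__all__ = [
    "IncidenceCurve",
    "observed_cumulative_incidence",
    "expected_cumulative_incidence",
    "incidence_curves",
]

_AGE_TOL = 1e-9


@dataclass
class IncidenceCurve:
    """Annual event counts/rates on a common age grid, with cumulative rates."""

    bin_start: np.ndarray  # left edges of one-year age bins
    events: np.ndarray  # (expected) events per bin
    person_years: np.ndarray  # at-risk person-years per bin
    rate: np.ndarray  # annual rate per bin
    cumulative: np.ndarray  # cumulated annual rates

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age": self.bin_start,
                "events": self.events,
                "person_years": self.person_years,
                "rate": self.rate,
                "cumulative": self.cumulative,
            }
        )


def _resolve_band(age_band) -> tuple[float, float]:
    if isinstance(age_band, str):
        key = age_band.replace(" ", "")
        if key in ("50-59", "50–59"):
            return 50.0, 60.0
        if key in ("60+", "60plus", ">=60"):
            return 60.0, np.inf
        raise ValueError(f"unknown age band {age_band!r}")
    lo, hi = age_band
    return float(lo), float(hi)


def _grid(cohort: Cohort, lo: float, hi: float, study_end_age: float) -> np.ndarray:
    top = 0.0
    for h in cohort:
        if not h.ever_attended:
            continue
        top = max(top, h.entry_age + person_years(h, study_end_age))
    top = min(top, hi)
    if top <= lo:
        raise ValueError("no ever-attender person-time in the requested age band")
    return np.arange(np.floor(lo), np.ceil(top) + 1e-9)


def _person_years_per_bin(
    cohort: Cohort, bins: np.ndarray, study_end_age: float
) -> np.ndarray:
    py = np.zeros(len(bins))
    for h in cohort:
        if not h.ever_attended:
            continue
        end = h.entry_age + person_years(h, study_end_age)
        seg = np.maximum(
            np.minimum(end, bins + 1.0) - np.maximum(h.entry_age, bins), 0.0
        )
        py += seg
    return py


def _finish(bins, events, py) -> IncidenceCurve:
    rate = np.divide(events, py, out=np.zeros_like(events), where=py > 0)
    return IncidenceCurve(bins, events, py, rate, np.cumsum(rate))


def observed_cumulative_incidence(
    cohort: Cohort, age_band, study_end_age: float = np.inf
) -> IncidenceCurve:
    """Observed annual and cumulative detection rates among ever-attenders."""
    lo, hi = _resolve_band(age_band)
    bins = _grid(cohort, lo, hi, study_end_age)
    events = np.zeros(len(bins))
    for h in cohort:
        if not h.ever_attended or h.outcome == "no_cancer":
            continue
        u = h.outcome_age
        if bins[0] <= u < bins[-1] + 1.0 and u < hi:
            events[int(np.floor(u - bins[0]))] += 1.0
    py = _person_years_per_bin(cohort, bins, study_end_age)
    return _finish(bins, events, py)


def _add_clinical_mass(
    events, bins, hi, params, partition, anchor, lo, t_end, b1, b2
) -> None:
    """Spread the model's clinical-surfacing mass (belief held at ``anchor``)
    over the one-year bins intersecting the observable window (lo, t_end)."""
    if t_end <= lo:
        return
    # break at every whole-year age so no segment straddles a bin (or band) edge
    edges = np.arange(np.ceil(lo), t_end)
    edges = edges[edges > lo]
    pts = np.concatenate(([lo], edges, [t_end]))
    q = transition_quantities(params, partition, anchor, pts)
    mass = b1 * np.diff(q["P13"]) + b2 * np.diff(q["P23"])
    for k in range(len(mass)):
        age = pts[k]
        if bins[0] <= age < bins[-1] + 1.0 and age < hi:
            events[int(np.floor(age - bins[0]))] += mass[k]


def expected_cumulative_incidence(
    cohort: Cohort,
    fit: FitResult | ModelParameters,
    age_band,
    partition: AgePartition | None = None,
    study_end_age: float = np.inf,
) -> IncidenceCurve:
    """Model-expected annual and cumulative detection rates among ever-attenders."""
    if isinstance(fit, FitResult):
        params = fit.params
        partition = partition or fit.partition
    else:
        params = fit
    partition = partition or AgePartition()
    lo, hi = _resolve_band(age_band)
    bins = _grid(cohort, lo, hi, study_end_age)
    events = np.zeros(len(bins))
    S = params.S

    for h in cohort:
        if not h.ever_attended:
            continue
        if h.outcome == "clinical":
            # continue follow-up to the next supposed examination time
            sched = [a for a in h.invited_ages if a <= h.outcome_age + _AGE_TOL]
            end = (sched[-1] if sched else h.entry_age) + 2.0
            end = min(end, study_end_age)
        else:
            end = h.entry_age + person_years(h, study_end_age)
        b1, b2, b4 = 1.0, 0.0, 0.0
        t_prev = partition.t0
        # An ever-attender cannot, by construction, have a clinical diagnosis
        # before her first attended screen (it would have ended her screening
        # before she ever attended), so expected accrual starts at that screen
        # and the initial belief conditions on no clinical surfacing by then.
        first_screen = h.screen_ages[0]
        q1 = transition_quantities(params, partition, partition.t0, first_screen)
        w = 1.0 / (1.0 - float(q1["P13"]))
        for t in h.screen_ages:
            if t > end:
                break
            q = transition_quantities(params, partition, t_prev, t)
            p_detect = b1 * (q["P12"] + q["P14"]) * S + b2 * q["P22"] + b4
            if bins[0] <= t < bins[-1] + 1.0 and t < hi:
                events[int(np.floor(t - bins[0]))] += w * float(p_detect)
            if t_prev > partition.t0:  # no observable clinical mass before t1
                _add_clinical_mass(
                    events, bins, hi, params, partition, t_prev, t_prev,
                    min(t, end), w * b1, w * b2,
                )
            # condition on the observed negative finding at this screen
            a1 = b1 * q["P11"]
            a2 = b1 * q["P12"] * (1.0 - S)
            a4 = b1 * q["P14"] * (1.0 - S)
            tot = a1 + a2 + a4
            if tot <= 0:
                b1, b2, b4 = 1.0, 0.0, 0.0
            else:
                b1, b2, b4 = a1 / tot, a2 / tot, a4 / tot
            w = 1.0  # later contributions are conditional on this negative
            t_prev = t
        if end > t_prev and t_prev > partition.t0:
            _add_clinical_mass(
                events, bins, hi, params, partition, t_prev, t_prev, end,
                w * b1, w * b2,
            )
    py = _person_years_per_bin(cohort, bins, study_end_age)
    return _finish(bins, events, py)


def incidence_curves(
    cohort: Cohort,
    fit: FitResult | ModelParameters,
    age_band,
    partition: AgePartition | None = None,
    study_end_age: float = np.inf,
) -> pd.DataFrame:
    """Observed and expected cumulative incidence on a shared grid."""
    obs = observed_cumulative_incidence(cohort, age_band, study_end_age)
    exp = expected_cumulative_incidence(cohort, fit, age_band, partition, study_end_age)
    return pd.DataFrame(
        {
            "age": obs.bin_start,
            "observed_rate": obs.rate,
            "expected_rate": exp.rate,
            "observed_cumulative": obs.cumulative,
            "expected_cumulative": exp.cumulative,
            "person_years": obs.person_years,
        }
    )
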