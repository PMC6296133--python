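"""Program-level descriptive summaries and case classification.

Implements the standard service-screening summaries: participation and recall
rates per invitation round, person-years of follow-up, detection-mode
classification of cancer cases per the European screening guidelines
(prevalent/subsequent screen-detected, interval cancer, non-participant), the
interval-cancer ratio and age-group incidence rates.
"""

from __future__ import annotations

from enum import Enum

import numpy as np
import pandas as pd

from .cohort import Cohort, ScreeningHistory

__all__ = [
    "DetectionMode",
    "classify_detection_mode",
    "person_years",
    "program_summary",
    "age_group_summary",
    "participation_rate",
    "recall_rate",
    "ic_ratio",
    "incidence_per_100k",
]

_AGE_TOL = 1e-9


class DetectionMode(str, Enum):
    """Mode of detection of a breast-cancer case."""

    PSD = "PSD"  # screen-detected at the woman's first attended screen
    SSD = "SSD"  # screen-detected at a later attended screen
    IC = "IC"  # clinical diagnosis within 24 months after a negative screen
    NP = "NP"  # clinical diagnosis, most recent invitation not attended
    UNEXPOSED = "unexposed_clinical"  # clinical diagnosis at/before first invitation


# -- rate helpers (shared by the summary tables and arithmetic checks) -------


def participation_rate(invited: int, screened: int) -> float:
    """Attended screens per invitation, in percent."""
    if invited <= 0:
        return float("nan")
    return 100.0 * screened / invited


def recall_rate(screened: int, recalled: int) -> float:
    """Recalls for assessment per attended screen, in percent."""
    if screened <= 0:
        return float("nan")
    return 100.0 * recalled / screened


def ic_ratio(ic: int, psd: int, ssd: int) -> float:
    """Interval cancers over all screen-detected plus interval cancers, percent."""
    den = ic + psd + ssd
    return 100.0 * ic / den if den > 0 else float("nan")


def incidence_per_100k(cases: int, person_years_total: float) -> float:
    """Incidence rate per 100,000 woman-years."""
    if person_years_total <= 0:
        return float("nan")
    return 1e5 * cases / person_years_total


# -- per-history operations ---------------------------------------------------


def classify_detection_mode(history: ScreeningHistory) -> DetectionMode:
    """EU-guidelines detection mode of a cancer case."""
    if history.outcome == "no_cancer":
        raise ValueError(f"woman {history.woman_id}: history has no cancer outcome")
    if history.outcome == "screen_detected":
        if abs(history.outcome_age - history.screen_ages[0]) < _AGE_TOL:
            return DetectionMode.PSD
        return DetectionMode.SSD
    # clinical diagnosis
    u = history.outcome_age
    inv = np.asarray(history.invited_ages)
    prior_inv = inv[inv <= u + _AGE_TOL]
    if prior_inv.size == 0:
        return DetectionMode.UNEXPOSED
    last_inv = prior_inv[-1]
    attended_last = any(abs(a - last_inv) < _AGE_TOL for a in history.screen_ages)
    if attended_last and u - last_inv <= 2.0 + _AGE_TOL:
        return DetectionMode.IC
    return DetectionMode.NP


def person_years(history: ScreeningHistory, study_end_age: float = np.inf) -> float:
    """Follow-up time: first invitation to diagnosis, two years after the last
    invitation, or the end of study, whichever comes first (floored at 0)."""
    end = min(
        history.outcome_age if history.outcome_age is not None else np.inf,
        history.invited_ages[-1] + 2.0,
        study_end_age,
    )
    return max(end - history.entry_age, 0.0)


# -- cohort summaries ---------------------------------------------------------


def program_summary(cohort: Cohort, by_round: bool = True) -> pd.DataFrame:
    """Invitations, attended screens, participation and recall rates.

    Synthetic cohorts carry no calendar time, so the stratification unit is
    the invitation round (a woman's n-th invitation) rather than calendar
    year; the total row reproduces the program-level rates.
    """
    rows: list[tuple[int, int, int, int]] = []  # (round, invited, screened, recalled)
    counts: dict[int, list[int]] = {}
    for h in cohort:
        detected_age = h.outcome_age if h.outcome == "screen_detected" else None
        recalls = h.recall_ages
        for k, a in enumerate(h.invited_ages, start=1):
            c = counts.setdefault(k, [0, 0, 0])
            c[0] += 1
            attended = any(abs(sa - a) < _AGE_TOL for sa in h.screen_ages)
            if attended:
                c[1] += 1
                recalled = any(abs(ra - a) < _AGE_TOL for ra in recalls) or (
                    detected_age is not None and abs(detected_age - a) < _AGE_TOL
                )
                if recalled:
                    c[2] += 1
    records = []
    for k in sorted(counts):
        inv, scr, rec = counts[k]
        records.append(
            {
                "round": k,
                "invited": inv,
                "screened": scr,
                "participation_pct": participation_rate(inv, scr),
                "recalled": rec,
                "recall_pct": recall_rate(scr, rec),
            }
        )
    df = pd.DataFrame(records)
    total = {
        "round": "total",
        "invited": int(df["invited"].sum()),
        "screened": int(df["screened"].sum()),
        "recalled": int(df["recalled"].sum()),
    }
    total["participation_pct"] = participation_rate(total["invited"], total["screened"])
    total["recall_pct"] = recall_rate(total["screened"], total["recalled"])
    if not by_round:
        return pd.DataFrame([total])
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def age_group_summary(
    cohort: Cohort,
    age_edges: tuple[float, ...] = (50.0, 55.0, 60.0, 65.0, 70.0),
    study_end_age: float = np.inf,
) -> pd.DataFrame:
    """Person-years, cases by detection mode, IC ratio and incidence by age group.

    ``age_edges`` define left-closed groups; the last group absorbs all older
    person-time and cases (women followed past the nominal upper edge stay in
    the top group, mirroring how programs report 65-69), and person-time
    before the first edge (jittered entry) is folded into the first group.
    """
    edges = np.asarray(age_edges, dtype=float)
    n_groups = len(edges) - 1
    py = np.zeros(n_groups)
    modes = [m for m in DetectionMode if m != DetectionMode.UNEXPOSED]
    cases = {m: np.zeros(n_groups, dtype=int) for m in modes}
    for h in cohort:
        end_age = h.entry_age + person_years(h, study_end_age)
        hi = np.minimum(end_age, edges[1:])
        seg = np.maximum(hi - np.maximum(h.entry_age, edges[:-1]), 0.0)
        # fold person-time outside the edge span into the boundary groups
        seg[0] += max(min(end_age, edges[0]) - h.entry_age, 0.0)
        seg[-1] += max(end_age - edges[-1], 0.0)
        py += seg
        if h.outcome != "no_cancer":
            mode = classify_detection_mode(h)
            if mode == DetectionMode.UNEXPOSED:
                continue
            g = int(np.clip(np.searchsorted(edges, h.outcome_age, "right") - 1, 0, n_groups - 1))
            cases[mode][g] += 1
    labels = [
        f"{int(edges[i])}-{int(edges[i + 1]) - 1}" for i in range(n_groups)
    ]
    df = pd.DataFrame(
        {
            "age_group": labels,
            "person_years": py,
            "PSD": cases[DetectionMode.PSD],
            "SSD": cases[DetectionMode.SSD],
            "IC": cases[DetectionMode.IC],
            "NP": cases[DetectionMode.NP],
        }
    )
    total = {
        "age_group": "total",
        "person_years": py.sum(),
        **{m.value: int(cases[m].sum()) for m in modes},
    }
    df = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
    df["cases"] = df[["PSD", "SSD", "IC", "NP"]].sum(axis=1)
    df["ic_ratio_pct"] = [
        ic_ratio(int(r.IC), int(r.PSD), int(r.SSD)) for r in df.itertuples()
    ]
    df["incidence_per_100k"] = [
        incidence_per_100k(int(r.cases), float(r.person_years)) for r in df.itertuples()
    ]
    return df
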