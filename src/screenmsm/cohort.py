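"""Individual screening histories and the cohort container.

A :class:`ScreeningHistory` is one woman's ordered record of invitations,
attended screens, benign recalls, her outcome (none, screen-detected or
clinical diagnosis) and her censoring age, all in continuous decimal years of
age.  A :class:`Cohort` wraps many histories and compiles them once into flat
numpy arrays so that likelihood evaluation is vectorised across women.

The on-disk exchange format is a long CSV, one row per event::

    woman_id,event,age

with ``event`` one of ``invite``, ``screen_neg``, ``screen_pos_recall_benign``,
``screen_detected``, ``clinical_dx``, ``censor``.  Benign recalls count as
attended screens and collapse to negative findings for the likelihood (the
assessment rules out cancer, so the probability of a false cancer record is
zero); they are kept for program descriptives (recall rates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["ScreeningHistory", "Cohort", "EVENT_TYPES"]

EVENT_TYPES = (
    "invite",
    "screen_neg",
    "screen_pos_recall_benign",
    "screen_detected",
    "clinical_dx",
    "censor",
)

_OUTCOMES = ("no_cancer", "screen_detected", "clinical")
_AGE_TOL = 1e-9


@dataclass(frozen=True)
class ScreeningHistory:
    """One woman's screening record.

    ``screen_ages`` are the attended screens (a subset of ``invited_ages``),
    including the detection screen for a screen-detected case, which must be
    the last attended screen.  ``recall_ages`` flags which attended screens
    ended in a benign recall after assessment.
    """

    woman_id: int | str
    invited_ages: tuple[float, ...]
    screen_ages: tuple[float, ...] = ()
    recall_ages: tuple[float, ...] = ()
    outcome: str = "no_cancer"
    outcome_age: float | None = None
    censor_age: float = float("nan")

    def __post_init__(self) -> None:
        object.__setattr__(self, "invited_ages", tuple(float(a) for a in self.invited_ages))
        object.__setattr__(self, "screen_ages", tuple(float(a) for a in self.screen_ages))
        object.__setattr__(self, "recall_ages", tuple(float(a) for a in self.recall_ages))
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        wid = self.woman_id
        if self.outcome not in _OUTCOMES:
            raise ValueError(f"woman {wid}: unknown outcome {self.outcome!r}")
        if len(self.invited_ages) == 0:
            raise ValueError(f"woman {wid}: at least one invitation is required")
        for name, ages in (("invited", self.invited_ages), ("screen", self.screen_ages)):
            if any(b <= a for a, b in zip(ages, ages[1:])):
                raise ValueError(f"woman {wid}: {name} ages must be strictly increasing")
        inv = np.asarray(self.invited_ages)
        for a in self.screen_ages:
            if not np.any(np.abs(inv - a) < _AGE_TOL):
                raise ValueError(
                    f"woman {wid}: attended screen at {a} has no matching invitation"
                )
        scr = np.asarray(self.screen_ages)
        for a in self.recall_ages:
            if scr.size == 0 or not np.any(np.abs(scr - a) < _AGE_TOL):
                raise ValueError(f"woman {wid}: recall at {a} has no matching screen")
        if not np.isfinite(self.censor_age):
            raise ValueError(f"woman {wid}: censor age is required")
        if self.outcome == "no_cancer":
            if self.outcome_age is not None:
                raise ValueError(f"woman {wid}: no_cancer outcome cannot carry an age")
        else:
            if self.outcome_age is None:
                raise ValueError(f"woman {wid}: outcome {self.outcome} requires an age")
            if self.outcome_age > self.censor_age + _AGE_TOL:
                raise ValueError(f"woman {wid}: outcome after censoring")
        if self.outcome == "screen_detected":
            if len(self.screen_ages) == 0 or abs(self.screen_ages[-1] - self.outcome_age) > _AGE_TOL:
                raise ValueError(
                    f"woman {wid}: screen-detected outcome must coincide with the "
                    "last attended screen"
                )
        if self.screen_ages and self.censor_age < self.screen_ages[-1] - _AGE_TOL:
            raise ValueError(f"woman {wid}: censoring before last attended screen")

    # -- derived ------------------------------------------------------------
    @property
    def entry_age(self) -> float:
        """Age at first invitation."""
        return self.invited_ages[0]

    @property
    def negative_screen_ages(self) -> tuple[float, ...]:
        """Attended screens with a negative finding (benign recalls included)."""
        if self.outcome == "screen_detected":
            return self.screen_ages[:-1]
        return self.screen_ages

    @property
    def ever_attended(self) -> bool:
        return len(self.screen_ages) > 0


class _CohortArrays:
    """Flat, NaN-padded array view of a cohort for vectorised likelihoods."""

    def __init__(self, histories: Sequence[ScreeningHistory]):
        n = len(histories)
        n_neg = np.array([len(h.negative_screen_ages) for h in histories], dtype=np.int64)
        width = int(n_neg.max()) if n else 0
        neg_ages = np.full((n, width), np.nan)
        for i, h in enumerate(histories):
            neg = h.negative_screen_ages
            neg_ages[i, : len(neg)] = neg
        code = {"no_cancer": 0, "screen_detected": 1, "clinical": 2}
        self.n = n
        self.n_neg = n_neg
        self.neg_ages = neg_ages
        self.outcome_code = np.array([code[h.outcome] for h in histories], dtype=np.int64)
        self.outcome_age = np.array(
            [np.nan if h.outcome_age is None else h.outcome_age for h in histories]
        )
        self.censor_age = np.array([h.censor_age for h in histories])
        self.entry_age = np.array([h.entry_age for h in histories])


class Cohort:
    """An ordered collection of screening histories."""

    def __init__(self, histories: Iterable[ScreeningHistory]):
        self.histories: list[ScreeningHistory] = list(histories)
        if not self.histories:
            raise ValueError("cohort must contain at least one history")
        self._arrays: _CohortArrays | None = None

    def __len__(self) -> int:
        return len(self.histories)

    def __iter__(self):
        return iter(self.histories)

    def __getitem__(self, i):
        return self.histories[i]

    @property
    def arrays(self) -> _CohortArrays:
        if self._arrays is None:
            self._arrays = _CohortArrays(self.histories)
        return self._arrays

    # -- event-table conversion ---------------------------------------------
    def to_events(self) -> pd.DataFrame:
        """Long event table, one row per event, sorted by woman then age."""
        rows: list[tuple] = []
        for h in self.histories:
            recalls = set(h.recall_ages)
            detected_age = h.outcome_age if h.outcome == "screen_detected" else None
            for a in h.invited_ages:
                rows.append((h.woman_id, "invite", a))
            for a in h.screen_ages:
                if detected_age is not None and abs(a - detected_age) < _AGE_TOL:
                    rows.append((h.woman_id, "screen_detected", a))
                elif a in recalls:
                    rows.append((h.woman_id, "screen_pos_recall_benign", a))
                else:
                    rows.append((h.woman_id, "screen_neg", a))
            if h.outcome == "clinical":
                rows.append((h.woman_id, "clinical_dx", h.outcome_age))
            rows.append((h.woman_id, "censor", h.censor_age))
        df = pd.DataFrame(rows, columns=["woman_id", "event", "age"])
        order = {e: i for i, e in enumerate(EVENT_TYPES)}
        df["_o"] = df["event"].map(order)
        df = df.sort_values(["woman_id", "age", "_o"], kind="stable").drop(columns="_o")
        return df.reset_index(drop=True)

    @classmethod
    def from_events(cls, events: pd.DataFrame) -> "Cohort":
        """Build a cohort from a long event table (validating each history)."""
        required = {"woman_id", "event", "age"}
        missing = required - set(events.columns)
        if missing:
            raise ValueError(f"event table missing columns: {sorted(missing)}")
        bad = ~events["event"].isin(EVENT_TYPES)
        if bad.any():
            rows = events.index[bad].tolist()[:10]
            raise ValueError(f"unknown event types at rows {rows}")
        histories = []
        for wid, g in events.groupby("woman_id", sort=True):
            ev = g.sort_values("age", kind="stable")
            ages = ev["age"].to_numpy(dtype=float)
            kinds = ev["event"].to_numpy()
            invited = tuple(ages[kinds == "invite"])
            screen_mask = np.isin(
                kinds, ("screen_neg", "screen_pos_recall_benign", "screen_detected")
            )
            screens = tuple(ages[screen_mask])
            recalls = tuple(ages[kinds == "screen_pos_recall_benign"])
            detected = ages[kinds == "screen_detected"]
            clinical = ages[kinds == "clinical_dx"]
            censor = ages[kinds == "censor"]
            if len(censor) != 1:
                raise ValueError(f"woman {wid}: exactly one censor event required")
            if len(detected) + len(clinical) > 1:
                raise ValueError(f"woman {wid}: more than one cancer outcome")
            if len(detected):
                outcome, outcome_age = "screen_detected", float(detected[0])
            elif len(clinical):
                outcome, outcome_age = "clinical", float(clinical[0])
            else:
                outcome, outcome_age = "no_cancer", None
            histories.append(
                ScreeningHistory(
                    woman_id=wid,
                    invited_ages=invited,
                    screen_ages=screens,
                    recall_ages=recalls,
                    outcome=outcome,
                    outcome_age=outcome_age,
                    censor_age=float(censor[0]),
                )
            )
        return cls(histories)
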