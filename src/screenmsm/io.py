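"""Reading and writing cohort files, parameter mappings and fit results."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, EVENT_TYPES
from .inference import FitResult
from .model import AgePartition, ModelParameters

__all__ = [
    "read_cohort",
    "write_cohort",
    "params_to_mapping",
    "params_from_mapping",
    "fit_to_dict",
    "write_fit",
    "read_fit",
]


def read_cohort(path: str | Path, t0: float = 40.0) -> Cohort:
    """Read and validate a long-format cohort CSV (woman_id, event, age).

    Schema violations are reported with 1-based file line numbers (header is
    line 1).  Ages must be finite decimal years at or above the initiation
    age ``t0``; per-woman ordering and outcome consistency are enforced by the
    history validators.
    """
    df = pd.read_csv(path)
    missing = {"woman_id", "event", "age"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    lines = df.index + 2  # header occupies line 1
    ages = pd.to_numeric(df["age"], errors="coerce")
    bad = ~np.isfinite(ages) | (ages < t0)
    if bad.any():
        rows = lines[bad].tolist()[:20]
        raise ValueError(f"{path}: invalid or sub-t0 ages at lines {rows}")
    df["age"] = ages
    bad = ~df["event"].isin(EVENT_TYPES)
    if bad.any():
        rows = lines[bad].tolist()[:20]
        raise ValueError(f"{path}: unknown event types at lines {rows}")
    # ordering within each woman's stream
    shifted = df.groupby("woman_id")["age"].diff()
    bad = shifted < -1e-9
    if bad.any():
        rows = lines[bad].tolist()[:20]
        raise ValueError(f"{path}: out-of-order ages at lines {rows}")
    return Cohort.from_events(df)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort in the long event-per-row CSV dialect."""
    cohort.to_events().to_csv(path, index=False)


def params_to_mapping(params: ModelParameters, partition: AgePartition) -> dict:
    """Flat serialisable mapping of the model parameters."""
    return {
        "cutpoints": list(partition.cutpoints),
        "lambda12": list(params.lambda12),
        "lambda23": list(params.lambda23),
        "r": params.r,
        "S": params.S,
        "fixed": sorted(params.fixed),
    }


def params_from_mapping(mapping: dict) -> tuple[ModelParameters, AgePartition]:
    partition = AgePartition(tuple(mapping.get("cutpoints", (40.0, 50.0, 60.0))))
    params = ModelParameters(
        lambda12=tuple(mapping["lambda12"]),
        lambda23=tuple(mapping["lambda23"]),
        r=float(mapping["r"]),
        S=float(mapping["S"]),
        fixed=frozenset(mapping.get("fixed", ("lambda12_0",))),
    )
    return params, partition


def fit_to_dict(fit: FitResult) -> dict:
    """JSON-serialisable summary of a fit (estimates, CIs, covariance)."""
    from .inference import standard_errors

    out = {
        "model_kind": fit.model_kind,
        "free_names": list(fit.free_names),
        "minus2loglik": fit.minus2loglik,
        "converged": fit.converged,
        "kkt_ok": fit.kkt_ok,
        "n_eval": fit.n_eval,
        "grad_inf": fit.grad_inf,
        "params": params_to_mapping(fit.params, fit.partition or AgePartition()),
    }
    out["boundary"] = list(fit.boundary)
    if fit.cov_transformed is not None:
        out["cov_transformed"] = fit.cov_transformed.tolist()
        se = standard_errors(fit)

        def _num(x):
            return float(x) if np.isfinite(x) else None

        out["estimates"] = {
            name: {
                "estimate": _num(se.loc[name, "estimate"]),
                "se": _num(se.loc[name, "se"]),
                "ci_low": _num(se.loc[name, "ci_low"]),
                "ci_high": _num(se.loc[name, "ci_high"]),
            }
            for name in se.index
        }
    return out


def write_fit(fit: FitResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit_to_dict(fit), indent=2))


def read_fit(path: str | Path) -> FitResult:
    """Reconstruct a fit result written by :func:`write_fit`."""
    from .inference import _pack

    raw = json.loads(Path(path).read_text())
    params, partition = params_from_mapping(raw["params"])
    names = tuple(raw["free_names"])
    cov = raw.get("cov_transformed")
    return FitResult(
        model_kind=raw["model_kind"],
        params=params,
        free_names=names,
        x=_pack(params, names),
        minus2loglik=raw["minus2loglik"],
        converged=raw["converged"],
        kkt_ok=raw["kkt_ok"],
        n_eval=raw["n_eval"],
        grad_inf=raw["grad_inf"],
        cov_transformed=None if cov is None else np.asarray(cov),
        partition=partition,
        boundary=tuple(raw.get("boundary", ())),
    )
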