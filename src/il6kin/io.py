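"""Readers and writers for the package's text formats.

Everything is plain delimited text (tab-separated, unit-annotated headers)
or JSON/YAML; values round-trip at 17 significant digits.  Protocol and
parameter configs may give the distribution volume in litres (``V_l``) or
millilitres (``V_ml``); litres are converted on read so the in-memory value
is always ml.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .crossval import CrossValResult
from .estimate import DEFAULT_ASSAY_CV, FitResult, ObservationSeries
from .model import FREE_PARAMETER_NAMES, ExerciseProtocol, ModelParameters
from .presets import get_protocol
from .simulate import Trajectory

__all__ = [
    "load_protocol",
    "load_parameters",
    "read_series",
    "write_series",
    "write_trajectory",
    "fit_result_to_dict",
    "write_fit_json",
    "crossval_report_frame",
    "write_crossval_report",
]

_FLOAT_FMT = "%.17g"


def _load_config(source: str | Path | Mapping[str, Any]) -> dict[str, Any]:
    if isinstance(source, Mapping):
        return dict(source)
    text = Path(source).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {source} must be a mapping")
    return data


def load_protocol(source: str | Path | Mapping[str, Any]) -> ExerciseProtocol:
    """Build a protocol from a mapping / YAML / JSON config.

    Recognised keys: label, t_ex_start_min, t_ex_end_min, T_v_percent,
    IL6_b_pg_ml, basal_fraction_percent (optional).
    """
    cfg = _load_config(source)
    try:
        return ExerciseProtocol(
            label=str(cfg.get("label", "custom")),
            t_ex_start=float(cfg["t_ex_start_min"]),
            t_ex_end=float(cfg["t_ex_end_min"]),
            T_v=float(cfg["T_v_percent"]),
            IL6_b=float(cfg["IL6_b_pg_ml"]),
            basal_fraction=float(cfg.get("basal_fraction_percent", 8.0)),
        )
    except KeyError as exc:
        raise ValueError(f"protocol config is missing field {exc}") from None


def load_parameters(source: str | Path | Mapping[str, Any]) -> ModelParameters:
    """Build kinetic parameters from a mapping / YAML / JSON config.

    Recognised keys: SR_ex, k_m, k_e, ramp_rate (optional), and the volume
    as either ``V_ml`` or ``V_l`` (litres, converted to ml).
    """
    cfg = _load_config(source)
    kwargs: dict[str, float] = {}
    try:
        for name in FREE_PARAMETER_NAMES:
            kwargs[name] = float(cfg[name])
    except KeyError as exc:
        raise ValueError(f"parameter config is missing field {exc}") from None
    if "V_ml" in cfg and "V_l" in cfg:
        raise ValueError("give the volume as V_ml or V_l, not both")
    if "V_ml" in cfg:
        kwargs["V"] = float(cfg["V_ml"])
    elif "V_l" in cfg:
        kwargs["V"] = 1000.0 * float(cfg["V_l"])
    if "ramp_rate" in cfg:
        kwargs["ramp_rate"] = float(cfg["ramp_rate"])
    return ModelParameters(**kwargs)


def _resolve_protocol(protocol: str | Path | Mapping[str, Any] | ExerciseProtocol):
    if isinstance(protocol, ExerciseProtocol):
        return protocol
    if isinstance(protocol, str) and not Path(protocol).exists():
        return get_protocol(protocol)
    return load_protocol(protocol)


def read_series(
    path: str | Path,
    protocol: str | Path | Mapping[str, Any] | ExerciseProtocol,
    assay_cv: float = DEFAULT_ASSAY_CV,
) -> ObservationSeries:
    """Read an observation series (columns time_min, il6_pg_ml).

    ``protocol`` may be a preset name, a config path/mapping, or a built
    :class:`ExerciseProtocol`.
    """
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = {"time_min", "il6_pg_ml"} - set(frame.columns)
    if missing:
        raise ValueError(f"series file {path} lacks columns {sorted(missing)}")
    return ObservationSeries(
        times=frame["time_min"].to_numpy(dtype=float),
        il6_values=frame["il6_pg_ml"].to_numpy(dtype=float),
        protocol=_resolve_protocol(protocol),
        assay_cv=assay_cv,
    )


def write_series(series: ObservationSeries, path: str | Path) -> None:
    pd.DataFrame(
        {"time_min": series.times, "il6_pg_ml": series.il6_values}
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    traj.to_frame().to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def fit_result_to_dict(fit: FitResult, seed: int | None = None) -> dict[str, Any]:
    """JSON-serialisable view of a fit (parameters, CV%, convergence)."""
    p = fit.params
    out: dict[str, Any] = {
        "parameters": {
            "SR_ex": p.SR_ex,
            "k_m": p.k_m,
            "k_e": p.k_e,
            "V_ml": p.V,
            "ramp_rate": p.ramp_rate,
        },
        "cv_percent": {
            name: _json_float(v)
            for name, v in zip(FREE_PARAMETER_NAMES, fit.cv_percent)
        },
        "Ra_IL6_pg_min": fit.Ra_IL6,
        "wrss": fit.wrss,
        "converged": fit.converged,
        "identifiable": {
            name: bool(v)
            for name, v in zip(FREE_PARAMETER_NAMES, fit.precision.identifiable)
        },
        "n_function_evals": fit.n_function_evals,
        "message": fit.message,
    }
    if seed is not None:
        out["seed"] = seed
    return out


def _json_float(v: float) -> float | str:
    return float(v) if np.isfinite(v) else "inf"


def write_fit_json(fit: FitResult, path: str | Path, seed: int | None = None) -> None:
    Path(path).write_text(json.dumps(fit_result_to_dict(fit, seed), indent=2) + "\n")


def crossval_report_frame(result: CrossValResult) -> pd.DataFrame:
    """Stage-by-stage report shaped like the published selection table."""
    rows = []
    for s in result.stages:
        if s.failed:
            rows.append(
                {"stage": s.stage + 1, "training_set": s.training_label,
                 "error": s.error}
            )
            continue
        p = s.fit.params
        rows.append(
            {
                "stage": s.stage + 1,
                "training_set": s.training_label,
                "SR_ex": p.SR_ex,
                "SR_ex_cv_percent": s.fit.cv_percent[0],
                "k_m": p.k_m,
                "k_m_cv_percent": s.fit.cv_percent[1],
                "k_e": p.k_e,
                "k_e_cv_percent": s.fit.cv_percent[2],
                "Ra_IL6_pg_min": s.fit.Ra_IL6,
                "sum_cv_percent": float(np.sum(s.fit.cv_percent)),
                "CVPEE": s.cvpee,
                "best": s.stage == result.best_stage,
            }
        )
    return pd.DataFrame(rows)


def write_crossval_report(
    result: CrossValResult, txt_path: str | Path, json_path: str | Path | None = None
) -> None:
    frame = crossval_report_frame(result)
    frame.to_csv(txt_path, sep="\t", index=False, float_format=_FLOAT_FMT)
    if json_path is not None:
        payload = {
            "N": result.N,
            "best_stage": result.best_stage + 1,
            "stages": json.loads(frame.to_json(orient="records")),
        }
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
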