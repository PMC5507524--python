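"""Dataset-level K-fold cross-validation for parameter-set selection.

Each of the K observation series takes one turn as the training set: the
kinetic parameters are fitted to it, then every series (including the
training one — its term is a fit error) is predicted under its own protocol
and baseline, with the adipose production re-derived from the steady-state
relation per dataset.  Per-dataset mean squared prediction errors (MSPE) are
pooled into the observation-count-weighted Cross-Validation Prediction
Error Estimate

    CVPEE = (1/N) Σ_k n_k · MSPE_k,      N = Σ_k n_k,

which equals the plain mean of squared prediction errors over all N pooled
observations.  The best parameter set is the stage with the lowest CVPEE;
exact ties are broken by the lowest summed parameter CV%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .estimate import FitResult, ObservationSeries, wnls_fit
from .model import ModelParameters
from .simulate import predict_at

__all__ = ["StageResult", "CrossValResult", "mspe", "cvpee", "kfold"]


def mspe(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Mean squared prediction error (1/n)·Σ (y_j − y*_j)², pg²·ml⁻²."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError(
            f"length mismatch: {observed.shape} observed vs "
            f"{predicted.shape} predicted"
        )
    if observed.size == 0:
        raise ValueError("mspe needs at least one observation pair")
    return float(np.mean((observed - predicted) ** 2))


def cvpee(counts: Sequence[int], mspes: Sequence[float]) -> float:
    """Observation-count-weighted mean of per-dataset MSPEs."""
    counts = np.asarray(counts)
    mspes = np.asarray(mspes, dtype=float)
    if counts.size == 0 or counts.shape != mspes.shape:
        raise ValueError("counts and mspes must be equal-length and non-empty")
    if not np.all(counts > 0) or not np.issubdtype(counts.dtype, np.integer):
        raise ValueError("counts must be positive integers")
    return float(np.sum(counts * mspes) / np.sum(counts))


@dataclass(frozen=True)
class StageResult:
    """One cross-validation stage: fit on ``training_label``, predict all."""

    stage: int
    training_label: str
    fit: FitResult | None
    mspe_per_dataset: np.ndarray | None
    cvpee: float | None
    error: str | None = None

    @property
    def failed(self) -> bool:
        return self.fit is None


@dataclass(frozen=True)
class CrossValResult:
    """All stages plus the selected best parameter set."""

    stages: list[StageResult]
    best_stage: int
    N: int

    @property
    def best(self) -> StageResult:
        return self.stages[self.best_stage]


def kfold(
    datasets: Sequence[ObservationSeries],
    init: ModelParameters | None = None,
    include_training: bool = True,
    **fit_kwargs,
) -> CrossValResult:
    """Run the dataset-level cross-validation over K observation series.

    Parameters
    ----------
    datasets :
        K >= 2 series, each carrying its own protocol and baseline.
    init :
        Initial guess (and fixed V / ramp_rate) passed to every stage's fit.
    include_training :
        If True (default, matching the pooled-N definition above), the
        training dataset's own fit error enters its stage's CVPEE.
    fit_kwargs :
        Forwarded to :func:`il6kin.estimate.wnls_fit`.

    Stages whose fit fails are recorded with their error, excluded from
    best-stage selection, and the run continues.
    """
    if len(datasets) < 2:
        raise ValueError("cross-validation needs at least 2 datasets")
    counts = np.array([len(d) for d in datasets])
    N = int(counts.sum())

    stages: list[StageResult] = []
    for k, train in enumerate(datasets):
        try:
            fit = wnls_fit(train, init=init, **fit_kwargs)
        except Exception as exc:  # noqa: BLE001 — stage failure is recoverable
            warnings.warn(
                f"cross-validation stage {k} ({train.protocol.label!r}) "
                f"failed: {exc}",
                RuntimeWarning,
                stacklevel=2,
            )
            stages.append(
                StageResult(k, train.protocol.label, None, None, None, str(exc))
            )
            continue

        errors = np.empty(len(datasets))
        for j, ds in enumerate(datasets):
            # each dataset keeps its own protocol and baseline; Ra_IL6 is
            # re-derived inside predict_at from the stage's k_e and that
            # dataset's IL6_b
            pred = predict_at(ds.protocol, fit.params, ds.times)
            errors[j] = mspe(ds.il6_values, pred)

        if include_training:
            stage_cvpee = cvpee(counts, errors)
        else:
            keep = np.arange(len(datasets)) != k
            stage_cvpee = cvpee(counts[keep], errors[keep])

        stages.append(
            StageResult(k, train.protocol.label, fit, errors, stage_cvpee)
        )

    ok = [s for s in stages if not s.failed]
    if not ok:
        raise RuntimeError("every cross-validation stage failed")
    best_value = min(s.cvpee for s in ok)
    tied = [s for s in ok if s.cvpee == best_value]
    best = min(tied, key=lambda s: float(np.sum(s.fit.cv_percent)))
    return CrossValResult(stages=stages, best_stage=best.stage, N=N)
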