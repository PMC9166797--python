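"""Predictive-accuracy metrics and factorial evaluation across replicates.

Three metrics, all on the validation sample: R^2 as the square of the
Pearson correlation between observed and predicted outcome (a proportion in
[0, 1]; note this is not 1 - SSE/SST), MSE = (1/N) sum (Y_i - Yhat_i)^2 and
MAE = (1/N) sum |Y_i - Yhat_i|, in mmHg^2 and mmHg respectively.

``evaluate_replicate`` fits every method on a simulated derivation sample
with FIXED hyperparameters (tuned once on the base data, never re-tuned
per replicate) and scores its predictions on the simulated validation
sample. ``summarize`` aggregates per (DGP, method, metric) to mean and SD
over replicates (SD with the n-1 denominator). A failed fit is logged and
recorded as a missing record, never a silent zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .dgp import GeneratingProcess, ReplicatePair
from .learners import LearnerSpec, fit_learner, predict

__all__ = [
    "PerformanceRecord",
    "r2_pearson",
    "mse",
    "mae",
    "evaluate_replicate",
    "summarize",
    "records_to_frame",
]

logger = logging.getLogger("bpbench.evaluation")


@dataclass(frozen=True)
class PerformanceRecord:
    """One method's three metrics on one replicate of one DGP."""

    dgp_id: str
    method_id: str
    replicate: int
    r2: float
    mse: float
    mae: float


def _check_lengths(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    return y, yhat


def r2_pearson(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Square of the Pearson correlation between observed and predicted.

    Invariant to affine maps of the predictions with nonzero slope;
    undefined (raises) when either vector has zero variance.
    """
    y, yhat = _check_lengths(y, yhat)
    if y.size < 2:
        raise ValueError("need at least 2 observations")
    # ptp==0 detects an exactly constant vector; np.var of one can be a
    # nonzero rounding residue
    if np.ptp(y) == 0.0 or np.ptp(yhat) == 0.0:
        raise ValueError("R^2 undefined: zero variance in observed or predicted")
    r = np.corrcoef(y, yhat)[0, 1]
    return float(r**2)


def mse(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Mean squared prediction error, (1/N) sum (Y_i - Yhat_i)^2."""
    y, yhat = _check_lengths(y, yhat)
    if y.size < 1:
        raise ValueError("need at least 1 observation")
    return float(np.mean((y - yhat) ** 2))


def mae(y: Sequence[float], yhat: Sequence[float]) -> float:
    """Mean absolute prediction error, (1/N) sum |Y_i - Yhat_i|."""
    y, yhat = _check_lengths(y, yhat)
    if y.size < 1:
        raise ValueError("need at least 1 observation")
    return float(np.mean(np.abs(y - yhat)))


def evaluate_replicate(
    gp: GeneratingProcess,
    pair: ReplicatePair,
    method_specs: Iterable[LearnerSpec],
    seed: int = 0,
) -> list[PerformanceRecord]:
    """Fit each spec on the simulated derivation sample, score on validation.

    Returns one record per successfully fitted spec; failures are logged
    and omitted (the summary reports counts, so omissions are visible).
    """
    records: list[PerformanceRecord] = []
    for spec in method_specs:
        fit_rng = substream(seed, "fit", gp.dgp_id, spec.method, pair.index)
        fit_seed = int(fit_rng.integers(0, 2**31 - 1))
        try:
            fitted = fit_learner(spec, gp.derivation, pair.y_derivation, seed=fit_seed)
            yhat = predict(fitted, gp.validation)
            records.append(
                PerformanceRecord(
                    dgp_id=gp.dgp_id,
                    method_id=spec.method,
                    replicate=pair.index,
                    r2=r2_pearson(pair.y_validation, yhat),
                    mse=mse(pair.y_validation, yhat),
                    mae=mae(pair.y_validation, yhat),
                )
            )
        except Exception:
            logger.exception(
                "fit failed: dgp=%s method=%s replicate=%d (recorded as missing)",
                gp.dgp_id,
                spec.method,
                pair.index,
            )
    return records


def records_to_frame(records: Iterable[PerformanceRecord]) -> pd.DataFrame:
    """Long-format table: dgp, method, replicate, r2, mse, mae."""
    return pd.DataFrame(
        [
            {
                "dgp": r.dgp_id,
                "method": r.method_id,
                "replicate": r.replicate,
                "r2": r.r2,
                "mse": r.mse,
                "mae": r.mae,
            }
            for r in records
        ]
    )


def summarize(records: Sequence[PerformanceRecord]) -> pd.DataFrame:
    """Mean +/- SD per (dgp, method, metric) over replicates.

    SD uses the n-1 denominator and is reported as 0 for a single
    replicate (its count column flags n=1).
    """
    if len(records) == 0:
        raise ValueError("no performance records to summarize")
    long = records_to_frame(records)
    melted = long.melt(
        id_vars=["dgp", "method", "replicate"],
        value_vars=["r2", "mse", "mae"],
        var_name="metric",
    )
    out = (
        melted.groupby(["dgp", "method", "metric"], sort=False)["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n="count")
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out
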