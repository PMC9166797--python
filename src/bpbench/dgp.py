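"""Learner-anchored residual-bootstrap data-generating processes.

Each DGP is built from one fitted learner (the "anchor"): the anchor is fit
exactly once on the base derivation sample; its predictions on the
derivation covariates and on the bootstrap-expanded validation covariates
become the systematic part of the truth. Replicate outcomes are then

    y~_i = yhat_i + e_i

with e_i drawn iid with replacement from the pool of derivation residuals
(y_deriv - yhat_deriv) — except for the OLS-spline anchor, where e_i is
drawn Normal(0, sigma-hat^2) with sigma-hat estimated from that fit. The
base covariates are frozen across replicates; only outcomes are
re-simulated, so each replicate pair shares the covariates but has fresh
outcome noise in both samples.

The derivation residual pool also supplies the validation draws: residuals
are defined against observed derivation outcomes only, and reusing the pool
keeps the noise law identical in both samples. ``validation_pool`` switches
to a pool built from observed validation outcomes when those are supplied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .cohort import CovariateTable, bootstrap_expand
from .learners import FittedLearner, LearnerSpec, fit_learner, predict

__all__ = [
    "ResidualSource",
    "GeneratingProcess",
    "ReplicatePair",
    "build_dgp",
    "simulate_pair",
    "generate_replicates",
]


@dataclass(frozen=True)
class ResidualSource:
    """Where replicate noise comes from: an empirical pool or Normal(0, sigma)."""

    mode: Literal["empirical", "gaussian"]
    pool: np.ndarray | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.mode == "empirical":
            if self.pool is None or len(self.pool) == 0:
                raise ValueError("empirical residual source needs a nonempty pool")
        elif self.mode == "gaussian":
            if self.sigma is None or self.sigma < 0:
                raise ValueError("gaussian residual source needs sigma >= 0")
        else:
            raise ValueError(f"unknown residual mode {self.mode!r}")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.mode == "gaussian":
            return rng.normal(0.0, self.sigma, size=n)
        return rng.choice(self.pool, size=n, replace=True)

    def variance(self) -> float:
        if self.mode == "gaussian":
            return float(self.sigma**2)
        return float(np.var(self.pool))


@dataclass(frozen=True)
class GeneratingProcess:
    """One anchored DGP: fitted anchor, base predictions, residual source."""

    anchor_spec: LearnerSpec
    anchor: FittedLearner
    derivation: CovariateTable
    yhat_derivation: np.ndarray
    validation: CovariateTable
    yhat_validation: np.ndarray
    residual_source: ResidualSource
    # non-default noise law for the validation sample (rarely used; see
    # build_dgp(validation_pool=...)); None means reuse residual_source
    validation_source: ResidualSource | None = None

    @property
    def dgp_id(self) -> str:
        return self.anchor_spec.method

    def signal_proportion(self) -> float:
        """The DGP's theoretical validation R^2 ceiling.

        var(yhat_valid) / (var(yhat_valid) + var(noise)): the squared
        correlation any predictor of the systematic part can attain when
        outcome noise is independent of the covariates.
        """
        v_sig = float(np.var(self.yhat_validation))
        v_noise = self.residual_source.variance()
        if v_sig + v_noise == 0.0:
            return 0.0
        return v_sig / (v_sig + v_noise)


@dataclass(frozen=True)
class ReplicatePair:
    """One simulated derivation/validation outcome pair (covariates shared)."""

    index: int
    y_derivation: np.ndarray
    y_validation: np.ndarray
    seed: int


def build_dgp(
    anchor_spec: LearnerSpec,
    derivation: CovariateTable,
    y_derivation: Sequence[float] | pd.Series,
    validation: CovariateTable,
    expand_to: int = 100_000,
    seed: int = 0,
    validation_pool: bool = False,
    y_validation: Sequence[float] | pd.Series | None = None,
) -> GeneratingProcess:
    """Fit the anchor once and assemble the generating process.

    The validation covariates are bootstrap-expanded to ``expand_to`` rows
    (default 100,000) before the anchor predicts them. The residual source
    is Normal(0, sigma-hat) for the ``ols_rcs`` anchor and the empirical
    derivation residual pool otherwise (``validation_pool=True`` draws the
    validation noise from observed-validation residuals instead, when
    ``y_validation`` is given).
    """
    if expand_to < 1:
        raise ValueError("expand_to must be >= 1")
    y_deriv = np.asarray(y_derivation, dtype=float)
    if len(y_deriv) != derivation.n:
        raise ValueError("derivation outcome length does not match covariates")
    anchor = fit_learner(anchor_spec, derivation, y_deriv, seed=seed)
    yhat_deriv = predict(anchor, derivation)

    expanded = bootstrap_expand(validation, expand_to, seed=seed)
    yhat_valid = predict(anchor, expanded)

    if anchor_spec.method == "ols_rcs":
        source = ResidualSource(mode="gaussian", sigma=anchor.residual_sd)
        valid_source = source
    else:
        source = ResidualSource(mode="empirical", pool=y_deriv - yhat_deriv)
        valid_source = source
        if validation_pool:
            if y_validation is None:
                raise ValueError("validation_pool=True needs y_validation")
            y_val = np.asarray(y_validation, dtype=float)
            if len(y_val) != validation.n:
                raise ValueError("validation outcome length does not match covariates")
            valid_source = ResidualSource(
                mode="empirical", pool=y_val - predict(anchor, validation)
            )

    return GeneratingProcess(
        anchor_spec=anchor_spec,
        anchor=anchor,
        derivation=derivation,
        yhat_derivation=yhat_deriv,
        validation=expanded,
        yhat_validation=yhat_valid,
        residual_source=source,
        validation_source=None if valid_source is source else valid_source,
    )


def _validation_source(gp: GeneratingProcess) -> ResidualSource:
    return gp.validation_source or gp.residual_source


def simulate_pair(gp: GeneratingProcess, seed: int, index: int = 0) -> ReplicatePair:
    """Simulate one replicate pair: y~ = yhat + e in both samples.

    Derivation and validation draws use the same residual law but
    independent substreams; identical ``seed`` reproduces the pair.
    """
    rng_d = substream(seed, "residuals", gp.dgp_id, "derivation")
    rng_v = substream(seed, "residuals", gp.dgp_id, "validation")
    e_d = gp.residual_source.draw(len(gp.yhat_derivation), rng_d)
    e_v = _validation_source(gp).draw(len(gp.yhat_validation), rng_v)
    return ReplicatePair(
        index=index,
        y_derivation=gp.yhat_derivation + e_d,
        y_validation=gp.yhat_validation + e_v,
        seed=seed,
    )


def generate_replicates(
    gp: GeneratingProcess, R: int, base_seed: int = 0
) -> Iterator[ReplicatePair]:
    """Yield R independent replicate pairs (streaming; substream per r)."""
    if R < 1:
        raise ValueError("R must be >= 1")
    for r in range(1, R + 1):
        rng = substream(base_seed, "replicate", gp.dgp_id, r)
        rep_seed = int(rng.integers(0, 2**31 - 1))
        yield simulate_pair(gp, seed=rep_seed, index=r)
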