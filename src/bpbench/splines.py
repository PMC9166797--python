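"""Restricted cubic spline basis (natural cubic spline, Harrell form).

A restricted cubic spline with k knots t_1 < ... < t_k is a piecewise cubic
constrained to be linear beyond the boundary knots, spanned by k-1 columns:
the identity plus k-2 truncated-cubic contrasts

    s_j(x) = [ (x-t_j)+^3
               - (x-t_{k-1})+^3 (t_k - t_j)/(t_k - t_{k-1})
               + (x-t_k)+^3 (t_{k-1} - t_j)/(t_k - t_{k-1}) ] / (t_k - t_1)^2

for j = 1..k-2, with (u)+ = max(u, 0). The division by (t_k - t_1)^2 puts
the nonlinear columns on roughly the scale of x itself, which keeps the
least-squares design well conditioned.

Default knot placement follows the standard quantile convention for k in
3..7 (e.g. k=3 at the 10th/50th/90th percentiles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KnotSet", "DEFAULT_KNOT_QUANTILES", "place_knots", "rcs_basis"]

DEFAULT_KNOT_QUANTILES: dict[int, tuple[float, ...]] = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
    6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
    7: (0.025, 0.1833, 0.3417, 0.50, 0.6583, 0.8167, 0.975),
}


@dataclass(frozen=True)
class KnotSet:
    """Strictly increasing knot locations in the predictor's units."""

    knots: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.knots) < 3:
            raise ValueError("a restricted cubic spline needs at least 3 knots")
        diffs = np.diff(self.knots)
        if np.any(diffs <= 0):
            raise ValueError(f"knots must be strictly increasing, got {self.knots}")

    @property
    def k(self) -> int:
        return len(self.knots)


def place_knots(x: np.ndarray, k: int) -> KnotSet:
    """Place k knots at the default quantiles of ``x`` (k in 3..7).

    Raises if ``x`` has fewer than k distinct values (e.g. a binary column)
    or if the quantiles collide.
    """
    if k not in DEFAULT_KNOT_QUANTILES:
        raise ValueError(f"k must be in 3..7, got {k}")
    x = np.asarray(x, dtype=float)
    if np.unique(x).size < k:
        raise ValueError(
            f"need at least {k} distinct values to place {k} knots "
            f"(got {np.unique(x).size}; is this a binary column?)"
        )
    knots = np.quantile(x, DEFAULT_KNOT_QUANTILES[k])
    if np.any(np.diff(knots) <= 0):
        raise ValueError(
            f"tied knot quantiles {knots.tolist()}; data too discrete for k={k}"
        )
    return KnotSet(tuple(float(t) for t in knots))


def rcs_basis(x: np.ndarray, knots: KnotSet) -> np.ndarray:
    """Evaluate the k-1 column restricted cubic spline basis at ``x``."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots.knots)
    k = knots.k
    out = np.empty((x.size, k - 1))
    out[:, 0] = x
    denom = t[k - 1] - t[k - 2]
    scale = (t[k - 1] - t[0]) ** 2

    def plus3(u: np.ndarray) -> np.ndarray:
        return np.maximum(u, 0.0) ** 3

    for j in range(k - 2):
        term = (
            plus3(x - t[j])
            - plus3(x - t[k - 2]) * (t[k - 1] - t[j]) / denom
            + plus3(x - t[k - 1]) * (t[k - 2] - t[j]) / denom
        )
        out[:, j + 1] = term / scale
    return out
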