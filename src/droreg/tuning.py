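"""Regularization grids and validation-split selection by minimum MAD.

The protocol splits the training rows once (seeded) into a fit set and a
validation set, fits the estimator at every candidate regularization value on
the fit set, scores each by the median absolute validation residual, selects
the minimizer (ties toward the smaller value), and refits on all training rows
with the winner.  The median criterion hedges against large noise or leftover
outliers in the validation rows.

The candidate grid follows the classical LASSO recipe: values log-spaced from
a small fraction of ||X'y||_inf up to ||X'y||_inf, with an elementwise square
root applied for estimators built on the absolute-deviation loss (whose
single-sample loss is the square root of the squared loss).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Tuple

import numpy as np

from .datagen import RegressionData
from .solvers import RegressionResults


@dataclass
class TuningPlan:
    """Candidate grid plus the seeded split used to score it."""

    grid: np.ndarray
    split_fraction: float = 0.75
    split_seed: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float).ravel()
        if self.grid.size == 0:
            raise ValueError("grid is empty")
        if np.any(self.grid < 0):
            raise ValueError("grid values must be nonnegative")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must be in (0, 1)")

    def to_json(self) -> str:
        return json.dumps(
            {
                "grid": self.grid.tolist(),
                "split_fraction": self.split_fraction,
                "split_seed": self.split_seed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TuningPlan":
        d = json.loads(text)
        return cls(np.asarray(d["grid"]), d["split_fraction"], d["split_seed"])


def build_grid(
    X: np.ndarray,
    y: np.ndarray,
    n_points: int = 50,
    lo_frac: float = 0.005,
    apply_sqrt: bool = True,
) -> np.ndarray:
    """Log-spaced candidates from lo_frac*a to a, with a = ||X'y||_inf / N.

    The classical LASSO anchor ||X'y||_inf pairs with a sum-of-squares loss;
    all estimators here use mean losses, so the anchor is divided by the
    sample size to keep the candidates on the scale of the penalty's useful
    range.  ``apply_sqrt`` takes the elementwise square root of the grid, the
    adjustment used for absolute-deviation-loss estimators.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.size == 0 or y.size == 0:
        raise ValueError("X and y must be nonempty")
    if not 0 < lo_frac < 1:
        raise ValueError("lo_frac must be in (0, 1)")
    a = float(np.max(np.abs(X.T @ y))) / y.size
    if a == 0:
        raise ValueError("||X'y||_inf is zero: degenerate design, no usable grid")
    grid = np.geomspace(lo_frac * a, a, n_points)
    return np.sqrt(grid) if apply_sqrt else grid


def mad_score(residuals: np.ndarray) -> float:
    """Median absolute residual (the validation selection criterion)."""
    residuals = np.asarray(residuals, dtype=float).ravel()
    if residuals.size == 0:
        raise ValueError("residuals are empty")
    return float(np.median(np.abs(residuals)))


def split_data(
    data: RegressionData, split_fraction: float, split_seed: int
) -> Tuple[RegressionData, RegressionData]:
    """Deterministic seeded permutation split into (fit, validation)."""
    n = data.n
    n_fit = int(np.ceil(split_fraction * n))
    if not 0 < n_fit < n:
        raise ValueError("split leaves an empty fit or validation set")
    perm = np.random.default_rng(np.random.SeedSequence(split_seed)).permutation(n)
    idx_fit, idx_val = perm[:n_fit], perm[n_fit:]

    def take(idx):
        return RegressionData(
            data.X[idx],
            data.y[idx],
            None if data.labels is None else data.labels[idx],
            data.truth,
        )

    return take(idx_fit), take(idx_val)


def tune(
    data: RegressionData,
    fitter: Callable[[RegressionData, float], RegressionResults],
    plan: TuningPlan,
) -> Tuple[float, RegressionResults]:
    """Select the grid value minimizing validation MAD; refit on all rows.

    ``fitter(data, value)`` fits the estimator at one regularization value.
    Ties are broken toward the smaller value, so the selection is
    deterministic given (data, plan).
    """
    fit_set, val_set = split_data(data, plan.split_fraction, plan.split_seed)
    scores = np.empty(plan.grid.size)
    for i, value in enumerate(plan.grid):
        res = fitter(fit_set, float(value))
        scores[i] = mad_score(res.resid(val_set.X, val_set.y))
    best = int(np.argmin(scores))  # argmin returns the first (smallest) minimizer
    best_value = float(plan.grid[best])
    final = fitter(data, best_value)
    final.solver_meta["validation_scores"] = scores
    final.solver_meta["selected"] = best_value
    return best_value, final


def epsilon_from_rate(scale: float, n: int, m: int) -> float:
    """Ambiguity radius from the large-sample proportionality eps ~ N^(-1/m).

    ``m`` is the joint dimension of (x, y); ``scale`` is the user-supplied
    proportionality factor.  Offered as an alternative to validation tuning.
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be positive")
    return float(scale * n ** (-1.0 / m))
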