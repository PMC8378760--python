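"""Out-of-sample certificates for the robust estimator.

Rademacher-complexity arguments give finite-sample guarantees for the
absolute-residual loss under two boundedness assumptions: the joint vector
(x, y) has norm at most R almost surely, and the dual-norm penalty
||(-beta, 1)||_* is at most B_bar over the feasible set.  Writing L_hat for
the training mean absolute residual, with probability at least 1 - delta over
the sampling,

    E|y - x'beta_hat|  <=  L_hat + 2*B_bar*R/sqrt(N) + B_bar*R*sqrt(8*ln(2/delta)/N)

and for any zeta exceeding the two correction terms, the chance that a new
sample's absolute error exceeds L_hat + zeta is at most
(bound numerator) / (L_hat + zeta).  Inverting the first bound gives minimum
sample sizes guaranteeing a target relative accuracy.  Logarithms are natural.

B_bar and R are properties of the model class and the data support; the
helpers that estimate them from a sample are plug-ins, not almost-sure
bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .datagen import RegressionData
from .norms import NormSpec, dual_norm, transport_cost


@dataclass
class BoundInputs:
    """Inputs shared by the certificates; optional fields per bound."""

    n: int
    delta: float
    b_bar: float
    r: float
    avg_loss: float = 0.0
    zeta: Optional[float] = None
    tau: Optional[float] = None
    gamma: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be a positive integer")
        if not 0 < self.delta < 1:
            raise ValueError("delta must be in (0, 1)")
        if self.b_bar <= 0 or self.r <= 0:
            raise ValueError("b_bar and r must be positive")
        if self.avg_loss < 0:
            raise ValueError("avg_loss must be nonnegative")


def _correction(n: int, delta: float, br: float) -> float:
    return 2.0 * br / math.sqrt(n) + br * math.sqrt(8.0 * math.log(2.0 / delta) / n)


def generalization_bound(inputs: BoundInputs) -> float:
    """High-probability bound on the expected absolute loss of the fit."""
    return inputs.avg_loss + _correction(inputs.n, inputs.delta, inputs.b_bar * inputs.r)


def tail_bound(inputs: BoundInputs) -> float:
    """Bound on P(|y - x'beta_hat| >= avg_loss + zeta), clipped to [0, 1]."""
    if inputs.zeta is None:
        raise ValueError("zeta is required for the tail bound")
    corr = _correction(inputs.n, inputs.delta, inputs.b_bar * inputs.r)
    if inputs.zeta <= corr:
        raise ValueError(
            f"zeta must exceed the correction term {corr:.6g} "
            "(the bound is vacuous otherwise)"
        )
    val = (inputs.avg_loss + corr) / (inputs.avg_loss + inputs.zeta)
    return float(min(max(val, 0.0), 1.0))


def min_n_expected(delta: float, tau: float) -> int:
    """Samples needed so the relative generalization gap is at most tau."""
    if not 0 < delta < 1:
        raise ValueError("delta must be in (0, 1)")
    if tau <= 0:
        raise ValueError("tau must be positive")
    root = 2.0 * (1.0 + math.sqrt(2.0 * math.log(2.0 / delta))) / tau
    return int(math.ceil(root**2))


def min_n_tail(delta: float, tau: float, gamma: float) -> int:
    """Samples needed so P(relative excess error >= gamma) is at most tau."""
    if not 0 < delta < 1:
        raise ValueError("delta must be in (0, 1)")
    denom = tau * gamma + tau - 1.0
    if denom <= 0:
        raise ValueError(
            f"requires tau*gamma + tau - 1 > 0, got {denom:.6g}: "
            "the requested tail level is unattainable"
        )
    root = 2.0 * (1.0 + math.sqrt(2.0 * math.log(2.0 / delta))) / denom
    return int(math.ceil(root**2))


def estimate_support_radius(data: RegressionData, norm: NormSpec) -> float:
    """Plug-in for R: the largest observed norm of (x_i, y_i).

    A sample maximum, not an almost-sure bound; adequate for truncated or
    bounded designs only.
    """
    origin = np.zeros(data.p + 1)
    return max(
        transport_cost(norm, np.concatenate([x, [y]]), origin)
        for x, y in zip(data.X, data.y)
    )


def estimate_b_bar(beta_hat: np.ndarray, norm: NormSpec) -> float:
    """Plug-in for B_bar: the dual-norm penalty at the fitted coefficients."""
    return dual_norm(norm, beta_hat)
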