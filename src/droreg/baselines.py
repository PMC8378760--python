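"""Comparison estimators: squared-loss regression and IRLS M-estimation.

The squared-residual (SR) baselines minimize

    (1/N) sum_i (y_i - b0 - x_i'beta)^2 + lam * P(beta)

with P the squared l2 norm (ridge), the l1 norm (LASSO), or the elastic-net
mixture alpha*||beta||_1 + (1-alpha)*||beta||_2^2; OLS is lam = 0.  These are
delegated to scikit-learn with the penalty weights mapped onto its
parameterization.

M-estimation minimizes a symmetric residual loss by iteratively reweighted
least squares (IRLS): residuals are scaled by a robust scale estimate
(MAD/0.6745) times a tuning constant, converted to weights in [0, 1], and a
weighted least-squares refit is repeated to convergence.  Weight functions:

- huber:  w(u) = min(1, 1/|u|)           (tuning constant 1.345)
- talwar: w(u) = 1 if |u| <= 1 else 0    (tuning constant 2.795)
- fair:   w(u) = 1/(1 + |u|)             (tuning constant 1.4)

The tuning constants are the classical 95%-efficiency values from the robust
regression literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import linear_model

from .datagen import RegressionData
from .solvers import (
    RegressionResults,
    STATUS_FAILURE,
    STATUS_OPTIMAL,
    _LinearModel,
)

PSI_KINDS = ("huber", "talwar", "fair")
DEFAULT_TUNING = {"huber": 1.345, "talwar": 2.795, "fair": 1.4}


@dataclass
class MEstConfig:
    """IRLS settings: weight family, tuning constant, stopping rule."""

    psi: str = "huber"
    tuning_const: float | None = None
    max_iter: int = 50
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.psi not in PSI_KINDS:
            raise ValueError(f"psi must be one of {PSI_KINDS}")
        if self.tuning_const is None:
            self.tuning_const = DEFAULT_TUNING[self.psi]
        if self.tuning_const <= 0:
            raise ValueError("tuning_const must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


def irls_weights(psi: str, u: np.ndarray) -> np.ndarray:
    """Residual-dependent weights in [0, 1]; w(0) = 1 by continuity."""
    u = np.abs(np.asarray(u, dtype=float))
    if psi == "huber":
        with np.errstate(divide="ignore"):
            return np.minimum(1.0, np.where(u > 0, 1.0 / u, np.inf))
    if psi == "talwar":
        return (u <= 1.0).astype(float)
    if psi == "fair":
        return 1.0 / (1.0 + u)
    raise ValueError(f"psi must be one of {PSI_KINDS}")


class SquaredErrorBaseline(_LinearModel):
    """OLS / ridge / LASSO / elastic net under the mean-squared-error loss."""

    def __init__(self, y, X, kind="ols", lam=0.0, alpha=0.5, fit_intercept=True):
        super().__init__(y, X, fit_intercept)
        if kind not in ("ols", "ridge", "lasso", "en"):
            raise ValueError("kind must be one of ols/ridge/lasso/en")
        if lam < 0:
            raise ValueError("lam must be nonnegative")
        if kind == "en" and not 0 <= alpha <= 1:
            raise ValueError("elastic-net mixing alpha must be in [0, 1]")
        self.kind = kind
        self.lam = float(lam)
        self.alpha = float(alpha)

    def _objective(self, beta, b0) -> float:
        r = self.y - b0 - self.X @ beta
        loss = float(np.mean(r**2))
        if self.kind == "ridge":
            pen = float(beta @ beta)
        elif self.kind == "lasso":
            pen = float(np.sum(np.abs(beta)))
        elif self.kind == "en":
            pen = self.alpha * float(np.sum(np.abs(beta))) + (1 - self.alpha) * float(
                beta @ beta
            )
        else:
            pen = 0.0
        return loss + self.lam * pen

    def fit(self) -> RegressionResults:
        X, y = self.X, self.y
        N = y.size
        kind = self.kind if self.lam > 0 else "ols"
        if kind == "ols":
            # minimum-norm solution on rank-deficient designs (lstsq)
            Xd = np.hstack([X, np.ones((N, 1))]) if self.fit_intercept else X
            sol, *_ = np.linalg.lstsq(Xd, y, rcond=None)
            beta = sol[: X.shape[1]]
            b0 = sol[-1] if self.fit_intercept else 0.0
            meta = {"solver": "lstsq"}
        elif kind == "ridge":
            est = linear_model.Ridge(
                alpha=N * self.lam, fit_intercept=self.fit_intercept, tol=1e-12
            )
            est.fit(X, y)
            beta, b0 = est.coef_, est.intercept_ if self.fit_intercept else 0.0
            meta = {"solver": "sklearn.Ridge"}
        else:
            if kind == "lasso":
                a, l1r = self.lam / 2.0, 1.0
            else:
                # (1/N)sum r^2 + lam*(alpha*l1 + (1-alpha)*l2^2) mapped onto
                # sklearn's (1/2N)sum r^2 + a*l1r*l1 + a*(1-l1r)/2*l2^2
                a = self.lam * self.alpha / 2.0 + self.lam * (1 - self.alpha)
                l1r = self.lam * self.alpha / (2.0 * a) if a > 0 else 0.0
            est = linear_model.ElasticNet(
                alpha=a,
                l1_ratio=l1r,
                fit_intercept=self.fit_intercept,
                max_iter=100000,
                tol=1e-12,
            )
            est.fit(X, y)
            beta, b0 = est.coef_, est.intercept_ if self.fit_intercept else 0.0
            meta = {"solver": "sklearn.ElasticNet", "l1_ratio": l1r}
        return self._wrap(beta, b0, self._objective(beta, b0), STATUS_OPTIMAL, meta)


class MEstimator(_LinearModel):
    """Robust regression by IRLS with Huber, Talwar, or Fair weights."""

    def __init__(self, y, X, config: MEstConfig | None = None, fit_intercept=True):
        super().__init__(y, X, fit_intercept)
        self.config = config if config is not None else MEstConfig()

    def fit(self) -> RegressionResults:
        cfg = self.config
        X, y = self.X, self.y
        N, p = X.shape
        Xd = np.hstack([X, np.ones((N, 1))]) if self.fit_intercept else X
        sol, *_ = np.linalg.lstsq(Xd, y, rcond=None)  # OLS start
        n_iter = 0
        converged = False
        weights = np.ones(N)
        for n_iter in range(1, cfg.max_iter + 1):
            r = y - Xd @ sol
            mad = np.median(np.abs(r - np.median(r)))
            scale = mad / 0.6745
            if scale <= 0:  # (near-)perfect fit: weights are all 1, stop
                converged = True
                break
            u = r / (cfg.tuning_const * scale)
            weights = irls_weights(cfg.psi, u)
            sw = np.sqrt(weights)
            new, *_ = np.linalg.lstsq(Xd * sw[:, None], y * sw, rcond=None)
            delta = np.max(np.abs(new - sol))
            sol = new
            if delta < cfg.tol:
                converged = True
                break
        beta = sol[:p]
        b0 = sol[-1] if self.fit_intercept else 0.0
        r = y - Xd @ sol
        objective = float(np.mean(weights * r**2))  # weighted-LS surrogate value
        meta = {
            "solver": "irls",
            "iterations": n_iter,
            "converged": converged,
            "weights": weights,
        }
        status = STATUS_OPTIMAL if converged else STATUS_FAILURE
        return self._wrap(beta, b0, objective, status, meta)


def fit_sr_baseline(
    data: RegressionData,
    kind: str = "ols",
    lam: float = 0.0,
    alpha: float = 0.5,
    fit_intercept: bool = True,
) -> RegressionResults:
    return SquaredErrorBaseline(
        data.y, data.X, kind=kind, lam=lam, alpha=alpha, fit_intercept=fit_intercept
    ).fit()


def fit_mestimator(
    data: RegressionData, config: MEstConfig | None = None, fit_intercept: bool = True
) -> RegressionResults:
    return MEstimator(data.y, data.X, config=config, fit_intercept=fit_intercept).fit()
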