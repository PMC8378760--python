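"""Exact convex solvers for Wasserstein-robust and least-absolute-deviation fits.

The central estimator minimizes, over the regression coefficients beta (and an
optional unpenalized intercept),

    (1/N) sum_i |y_i - b0 - x_i' beta|  +  epsilon * ||(-beta, 1)||_*

where the dual norm is determined by the transport metric (:mod:`droreg.norms`)
and epsilon is the Wasserstein ambiguity radius.  Each metric admits an exact
convex reformulation:

- l1 metric: a linear program with epigraph variables a >= |beta_j|, a >= 1 and
  b_i >= |residual_i|, solved with HiGHS;
- l-inf metric: a linear program with coordinatewise |beta_j| epigraph
  variables (the penalty is ||beta||_1 + 1);
- l2 / M-weighted metrics: the penalty sqrt(beta'beta + 1), resp.
  sqrt((-beta,1)' M^{-1} (-beta,1)), is globally smooth (the response
  coordinate bounds it away from zero), so the problem is solved as a smooth
  program over the residual epigraph with SLSQP.  Convexity makes any local
  optimum global.

Plain LAD is the epsilon = 0 case; regularized LAD replaces the extended
penalty by lam * ||beta||_1 or lam * ||beta||_2 on the slope only.

Model classes follow the Model/Results convention: construct a model from
data, call ``fit()``, and read estimates off the returned
:class:`RegressionResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog, minimize

from .datagen import RegressionData
from .norms import NormSpec, dual_norm

STATUS_OPTIMAL = "optimal"
STATUS_INFEASIBLE = "infeasible"
STATUS_FAILURE = "numerical_failure"


@dataclass
class WDROConfig:
    """Wasserstein radius, transport metric, and optional l1 ball on beta."""

    epsilon: float = 0.0
    norm: NormSpec = field(default_factory=NormSpec)
    l1_ball: Optional[float] = None
    fit_intercept: bool = True

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be nonnegative")
        if self.l1_ball is not None and self.l1_ball <= 0:
            raise ValueError("l1_ball radius must be positive")


class RegressionResults:
    """Fit results: coefficients, objective value, and solver diagnostics."""

    def __init__(self, model, params, intercept, objective, status, solver_meta):
        self.model = model
        self.params = np.asarray(params, dtype=float).ravel()
        self.intercept = float(intercept)
        self.objective = float(objective)
        self.status = status
        self.solver_meta = dict(solver_meta)

    # spec field name
    @property
    def beta(self) -> np.ndarray:
        return self.params

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.params

    def resid(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        return np.asarray(y, dtype=float).ravel() - self.predict(X)

    def summary(self) -> str:
        lines = [
            f"{type(self.model).__name__} results",
            "-" * 40,
            f"status:     {self.status}",
            f"objective:  {self.objective:.6g}",
            f"intercept:  {self.intercept:.6g}",
            "coefficients:",
        ]
        lines += [f"  beta[{j}] = {b: .6g}" for j, b in enumerate(self.params)]
        extras = {k: v for k, v in self.solver_meta.items() if np.isscalar(v)}
        if extras:
            lines.append("diagnostics: " + ", ".join(f"{k}={v}" for k, v in extras.items()))
        return "\n".join(lines)


class _LinearModel:
    """Shared constructors: from arrays, RegressionData, or a DataFrame."""

    def __init__(self, y: np.ndarray, X: np.ndarray, fit_intercept: bool = True):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.y = np.asarray(y, dtype=float).ravel()
        if self.X.shape[0] != self.y.size:
            raise ValueError("X and y have incompatible shapes")
        if self.y.size < 1:
            raise ValueError("need at least one observation")
        self.fit_intercept = bool(fit_intercept)

    @classmethod
    def from_data(cls, data: RegressionData, **kwargs):
        return cls(data.y, data.X, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str = "y", **kwargs):
        if response not in df.columns:
            raise ValueError(f"response column {response!r} not in dataframe")
        X = df.drop(columns=[response]).to_numpy(dtype=float)
        return cls(df[response].to_numpy(dtype=float), X, **kwargs)

    def _wrap(self, beta, b0, objective, status, meta) -> RegressionResults:
        return RegressionResults(self, beta, b0, objective, status, meta)


def wdro_objective(
    data: RegressionData | tuple,
    beta: np.ndarray,
    intercept: float,
    config: WDROConfig,
) -> float:
    """Mean absolute residual plus epsilon times the dual-norm penalty."""
    X, y = (data.X, data.y) if isinstance(data, RegressionData) else data
    beta = np.asarray(beta, dtype=float).ravel()
    loss = float(np.mean(np.abs(y - intercept - X @ beta)))
    return loss + config.epsilon * dual_norm(config.norm, beta)


# ---------------------------------------------------------------------------
# LP reformulations (l1 / l-inf metrics, LAD, l1-regularized LAD)
# ---------------------------------------------------------------------------

def _residual_epigraph(X, y, has_b0, n_extra):
    """Constraint blocks b_i >= |y_i - b0 - x_i'beta| as A_ub z <= b_ub.

    Variable layout: [beta (p), (b0), b (N), extras (n_extra)].
    """
    N, p = X.shape
    nb0 = 1 if has_b0 else 0
    ncol = p + nb0 + N + n_extra
    ones = np.ones((N, 1)) if has_b0 else np.zeros((N, 0))
    eyeN = sparse.eye(N)
    zed = sparse.csr_matrix((N, n_extra))
    upper = sparse.hstack([sparse.csr_matrix(-X), sparse.csr_matrix(-ones), -eyeN, zed])
    lower = sparse.hstack([sparse.csr_matrix(X), sparse.csr_matrix(ones), -eyeN, zed])
    A = sparse.vstack([upper, lower], format="csr")
    b = np.concatenate([-y, y])
    return A, b, ncol, nb0


def _abs_rows(p, ncol, beta_off, t_off):
    """Rows enforcing t_j >= |beta_j|: beta_j - t_j <= 0 and -beta_j - t_j <= 0."""
    rows, cols, vals = [], [], []
    for j in range(p):
        rows += [2 * j, 2 * j, 2 * j + 1, 2 * j + 1]
        cols += [beta_off + j, t_off + j, beta_off + j, t_off + j]
        vals += [1.0, -1.0, -1.0, -1.0]
    return sparse.csr_matrix((vals, (rows, cols)), shape=(2 * p, ncol))


def _solve_lp(c, A, b, bounds, meta_extra=None):
    res = linprog(c, A_ub=A, b_ub=b, bounds=bounds, method="highs")
    if res.status == 2:
        status = STATUS_INFEASIBLE
    elif res.status == 0:
        status = STATUS_OPTIMAL
    else:
        status = STATUS_FAILURE
    meta = {"solver": "highs", "linprog_status": res.status, "message": res.message}
    if meta_extra:
        meta.update(meta_extra)
    return res, status, meta


def _fit_lp_l1_metric(X, y, epsilon, l1_ball, fit_intercept):
    """LP for the l1 transport metric: penalty epsilon * max(||beta||_inf, 1)."""
    N, p = X.shape
    n_extra = 1 + (p if l1_ball is not None else 0)  # a, then s_j for the l1 ball
    A, b, ncol, nb0 = _residual_epigraph(X, y, fit_intercept, n_extra)
    a_off = p + nb0 + N
    blocks = [A]
    rhs = [b]
    # a >= |beta_j| for every coordinate (a single shared epigraph variable)
    rows = np.repeat(np.arange(2 * p), 2)
    cols = np.empty(4 * p, dtype=int)
    cols[0::4] = np.arange(p)
    cols[1::4] = a_off
    cols[2::4] = np.arange(p)
    cols[3::4] = a_off
    vals = np.tile([1.0, -1.0, -1.0, -1.0], p)
    blocks.append(sparse.csr_matrix((vals, (rows, cols)), shape=(2 * p, ncol)))
    rhs.append(np.zeros(2 * p))
    if l1_ball is not None:
        s_off = a_off + 1
        As = _abs_rows(p, ncol, 0, s_off)
        row = np.zeros(ncol)
        row[s_off : s_off + p] = 1.0
        blocks += [As, sparse.csr_matrix(row)]
        rhs += [np.zeros(2 * p), np.array([l1_ball])]
    c = np.zeros(ncol)
    c[a_off] = epsilon
    c[p + nb0 : p + nb0 + N] = 1.0 / N
    bounds = [(None, None)] * (p + nb0) + [(0, None)] * N + [(1.0, None)]
    if l1_ball is not None:
        bounds += [(0, None)] * p
    res, status, meta = _solve_lp(c, sparse.vstack(blocks, format="csr"), np.concatenate(rhs), bounds)
    beta = res.x[:p] if res.x is not None else np.zeros(p)
    b0 = res.x[p] if (res.x is not None and nb0) else 0.0
    return beta, b0, status, meta


def _fit_lp_l1_penalty(X, y, lam, l1_ball, fit_intercept):
    """LP minimizing mean |resid| + lam * ||beta||_1.

    Covers the l-inf transport metric (lam=epsilon; the reported objective
    then adds the constant epsilon for the response coordinate) and
    l1-regularized LAD.
    """
    N, p = X.shape
    A, b, ncol, nb0 = _residual_epigraph(X, y, fit_intercept, p)
    t_off = p + nb0 + N
    At = _abs_rows(p, ncol, 0, t_off)
    blocks = [A, At]
    rhs = [b, np.zeros(2 * p)]
    if l1_ball is not None:
        row = np.zeros(ncol)
        row[t_off : t_off + p] = 1.0
        blocks.append(sparse.csr_matrix(row))
        rhs.append(np.array([l1_ball]))
    c = np.zeros(ncol)
    c[p + nb0 : p + nb0 + N] = 1.0 / N
    c[t_off:] = lam
    bounds = [(None, None)] * (p + nb0) + [(0, None)] * (N + p)
    res, status, meta = _solve_lp(c, sparse.vstack(blocks, format="csr"), np.concatenate(rhs), bounds)
    beta = res.x[:p] if res.x is not None else np.zeros(p)
    b0 = res.x[p] if (res.x is not None and nb0) else 0.0
    return beta, b0, status, meta


# ---------------------------------------------------------------------------
# Smooth epigraph solver (l2 / M-weighted metrics, l2-regularized LAD)
# ---------------------------------------------------------------------------

def _fit_smooth_penalty(X, y, weight, penalty_fn, l1_ball, fit_intercept, x0=None):
    """Minimize mean|resid| + weight * g(beta) for smooth convex g via SLSQP.

    ``penalty_fn(beta) -> (value, gradient)`` must be differentiable
    everywhere.  Variables: [beta (p), (b0), b (N), (s (p) if l1 ball)].
    """
    N, p = X.shape
    nb0 = 1 if fit_intercept else 0
    ns = p if l1_ball is not None else 0
    ncol = p + nb0 + N + ns
    b_off = p + nb0
    s_off = b_off + N

    def fun(z):
        val, grad = penalty_fn(z[:p])
        f = np.sum(z[b_off : b_off + N]) / N + weight * val
        g = np.zeros(ncol)
        g[:p] = weight * grad
        g[b_off : b_off + N] = 1.0 / N
        return f, g

    # b_i -+ (y_i - b0 - x_i'beta) >= 0, plus l1-ball rows when requested
    rows = [np.hstack([X, np.ones((N, nb0)), np.eye(N), np.zeros((N, ns))]),
            np.hstack([-X, -np.ones((N, nb0)), np.eye(N), np.zeros((N, ns))])]
    lhs = [y, -y]
    if l1_ball is not None:
        Zs = np.zeros((p, nb0 + N))
        rows += [np.hstack([-np.eye(p), Zs, np.eye(p)]),
                 np.hstack([np.eye(p), Zs, np.eye(p)])]
        lhs += [np.zeros(p), np.zeros(p)]
        ball = np.zeros((1, ncol))
        ball[0, s_off:] = -1.0
        rows.append(ball)
        lhs.append(np.array([-l1_ball]))
    A = np.vstack(rows)
    rhs = np.concatenate(lhs)
    cons = [{"type": "ineq", "fun": lambda z: A @ z - rhs, "jac": lambda z: A}]

    if x0 is None:
        x0 = np.zeros(ncol)
        x0[b_off : b_off + N] = np.abs(y - (np.median(y) if fit_intercept else 0.0))
        if fit_intercept:
            x0[p] = np.median(y)
    res = minimize(fun, x0, jac=True, constraints=cons, method="SLSQP",
                   options={"maxiter": 1000, "ftol": 1e-12})
    status = STATUS_OPTIMAL if res.success else STATUS_FAILURE
    if not res.success:
        # one cold restart from the origin; convexity means any converged
        # point is the global optimum
        res2 = minimize(fun, np.zeros(ncol), jac=True, constraints=cons,
                        method="SLSQP", options={"maxiter": 2000, "ftol": 1e-12})
        if res2.success or res2.fun < res.fun:
            res, status = res2, (STATUS_OPTIMAL if res2.success else STATUS_FAILURE)
    beta = res.x[:p]
    b0 = res.x[p] if fit_intercept else 0.0
    meta = {"solver": "slsqp", "iterations": int(res.nit), "message": res.message}
    return beta, b0, status, meta, res.x


def _l2_extended_penalty(beta):
    val = np.sqrt(beta @ beta + 1.0)
    return val, beta / val


def _weighted_penalty_factory(Minv, p):
    def g(beta):
        v = np.concatenate([-beta, [1.0]])
        w = Minv @ v
        val = np.sqrt(v @ w)
        return val, -w[:p] / val
    return g


# ---------------------------------------------------------------------------
# Model classes
# ---------------------------------------------------------------------------

class WassersteinDRO(_LinearModel):
    """Wasserstein-robust l1-loss linear regression.

    Parameters
    ----------
    y, X : response vector and predictor matrix.
    epsilon : Wasserstein ambiguity radius (regularization weight).
    norm : transport metric specification; its dual norm is the penalty.
    l1_ball : optional radius l of a hard constraint ||beta||_1 <= l.
    fit_intercept : include an unpenalized intercept outside the metric.
    """

    def __init__(self, y, X, epsilon=0.0, norm=None, l1_ball=None, fit_intercept=True):
        super().__init__(y, X, fit_intercept)
        self.config = WDROConfig(
            epsilon=epsilon,
            norm=norm if norm is not None else NormSpec("l2"),
            l1_ball=l1_ball,
            fit_intercept=fit_intercept,
        )

    def fit(self, x0: Optional[np.ndarray] = None) -> RegressionResults:
        cfg = self.config
        X, y = self.X, self.y
        kind = cfg.norm.kind
        if kind == "l1":
            beta, b0, status, meta = _fit_lp_l1_metric(
                X, y, cfg.epsilon, cfg.l1_ball, cfg.fit_intercept
            )
        elif kind == "linf":
            beta, b0, status, meta = _fit_lp_l1_penalty(
                X, y, cfg.epsilon, cfg.l1_ball, cfg.fit_intercept
            )
        else:
            if kind == "l2":
                g = _l2_extended_penalty
            else:
                Minv = cfg.norm.m_inverse()
                if Minv.shape[0] != X.shape[1] + 1:
                    raise ValueError("weight matrix must be (p+1) x (p+1)")
                g = _weighted_penalty_factory(Minv, X.shape[1])
            beta, b0, status, meta, full = _fit_smooth_penalty(
                X, y, cfg.epsilon, g, cfg.l1_ball, cfg.fit_intercept, x0=x0
            )
            meta["x_full"] = full
        objective = wdro_objective((X, y), beta, b0, cfg)
        return self._wrap(beta, b0, objective, status, meta)


class LAD(_LinearModel):
    """Least absolute deviation regression (mean |residual| minimization)."""

    def fit(self) -> RegressionResults:
        beta, b0, status, meta = _fit_lp_l1_metric(
            self.X, self.y, 0.0, None, self.fit_intercept
        )
        loss = float(np.mean(np.abs(self.y - b0 - self.X @ beta)))
        return self._wrap(beta, b0, loss, status, meta)


class RegularizedLAD(_LinearModel):
    """LAD with a lam * ||beta||_1 or lam * ||beta||_2 penalty on the slope.

    Penalizing beta alone (rather than the extended vector (-beta, 1))
    corresponds to a transport metric with infinite cost along the response
    axis; these are the classical regularized-LAD baselines.
    """

    def __init__(self, y, X, penalty="l1", lam=0.0, fit_intercept=True):
        super().__init__(y, X, fit_intercept)
        if penalty not in ("l1", "l2"):
            raise ValueError("penalty must be 'l1' or 'l2'")
        if lam < 0:
            raise ValueError("lam must be nonnegative")
        self.penalty = penalty
        self.lam = float(lam)

    def _objective(self, beta, b0) -> float:
        loss = float(np.mean(np.abs(self.y - b0 - self.X @ beta)))
        pen = np.sum(np.abs(beta)) if self.penalty == "l1" else np.linalg.norm(beta)
        return loss + self.lam * float(pen)

    def fit(self, x0: Optional[np.ndarray] = None) -> RegressionResults:
        X, y = self.X, self.y
        if self.penalty == "l1":
            beta, b0, status, meta = _fit_lp_l1_penalty(
                X, y, self.lam, None, self.fit_intercept
            )
        else:
            # sqrt(||beta||^2 + delta^2) surrogate keeps the program smooth;
            # an exact-zero polish below restores the beta = 0 solution when
            # the penalty dominates the loss subgradient.
            delta2 = 1e-20

            def g(beta):
                val = np.sqrt(beta @ beta + delta2)
                return val, beta / val

            beta, b0, status, meta, full = _fit_smooth_penalty(
                X, y, self.lam, g, None, self.fit_intercept, x0=x0
            )
            meta["x_full"] = full
            cand_b0 = float(np.median(y)) if self.fit_intercept else 0.0
            if self._objective(np.zeros(X.shape[1]), cand_b0) <= self._objective(beta, b0):
                beta = np.zeros(X.shape[1])
                b0 = cand_b0
                meta["polished_to_zero"] = True
        return self._wrap(beta, b0, self._objective(beta, b0), status, meta)


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------

def fit_wdro(data: RegressionData, config: WDROConfig) -> RegressionResults:
    """Fit the Wasserstein-robust regression described by ``config``."""
    return WassersteinDRO(
        data.y,
        data.X,
        epsilon=config.epsilon,
        norm=config.norm,
        l1_ball=config.l1_ball,
        fit_intercept=config.fit_intercept,
    ).fit()


def fit_lad(data: RegressionData, fit_intercept: bool = True) -> RegressionResults:
    return LAD(data.y, data.X, fit_intercept=fit_intercept).fit()


def fit_regularized_lad(
    data: RegressionData, penalty: str, lam: float, fit_intercept: bool = True
) -> RegressionResults:
    return RegularizedLAD(
        data.y, data.X, penalty=penalty, lam=lam, fit_intercept=fit_intercept
    ).fit()
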