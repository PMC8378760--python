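"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest
from hypothesis import settings
from scipy.optimize import linprog

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from droreg.datagen import RegressionData


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_instance(rng, p=None, n=20, noise=0.3):
    """Small random regression instance for solver cross-checks."""
    p = int(rng.integers(1, 3)) if p is None else p
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + noise * rng.normal(size=n)
    return RegressionData(X, y)


def grid_search_wdro(data, config, lo=-3.0, hi=3.0, coarse=301, refinements=3):
    """Dense grid search of the robust objective for 1- or 2-dim beta.

    Independent of the solvers: evaluates the objective definition on a grid,
    refining around the incumbent.  Intercept, when enabled, is searched as an
    extra coordinate.
    """
    dim = data.p + (1 if config.fit_intercept else 0)
    assert dim <= 3, "grid oracle is for tiny problems only"
    lo_v = np.full(dim, lo)
    hi_v = np.full(dim, hi)
    n_pts = coarse if dim == 1 else (61 if dim == 2 else 31)
    best_z, best_f = None, np.inf
    for _ in range(refinements + 1):
        axes = [np.linspace(lo_v[i], hi_v[i], n_pts) for i in range(dim)]
        mesh = np.meshgrid(*axes, indexing="ij")
        Z = np.stack([m.ravel() for m in mesh], axis=1)
        betas = Z[:, : data.p]
        b0s = Z[:, data.p] if config.fit_intercept else np.zeros(Z.shape[0])
        resid = data.y[None, :] - b0s[:, None] - betas @ data.X.T
        loss = np.mean(np.abs(resid), axis=1)
        if config.norm.kind == "l2":
            pen = np.sqrt(np.sum(betas**2, axis=1) + 1.0)
        elif config.norm.kind == "l1":
            pen = np.maximum(np.max(np.abs(betas), axis=1, initial=0.0), 1.0)
        elif config.norm.kind == "linf":
            pen = np.sum(np.abs(betas), axis=1) + 1.0
        else:
            Minv = np.linalg.inv(config.norm.M)
            V = np.hstack([-betas, np.ones((betas.shape[0], 1))])
            pen = np.sqrt(np.einsum("ij,jk,ik->i", V, Minv, V))
        f = loss + config.epsilon * pen
        k = int(np.argmin(f))
        if f[k] < best_f:
            best_f, best_z = float(f[k]), Z[k]
        span = (hi_v - lo_v) / (n_pts - 1)
        lo_v = best_z[:dim] - 2 * span
        hi_v = best_z[:dim] + 2 * span
    return best_z, best_f


def w1_lp_oracle(P, Q):
    """Order-1 Wasserstein by the transportation LP (independent oracle)."""
    cost = np.abs(P.atoms[:, None] - Q.atoms[None, :]).ravel()
    n, m = P.atoms.size, Q.atoms.size
    A_eq = []
    for i in range(n):
        row = np.zeros(n * m)
        row[i * m : (i + 1) * m] = 1
        A_eq.append(row)
    for j in range(m):
        row = np.zeros(n * m)
        row[j::m] = 1
        A_eq.append(row)
    b_eq = np.concatenate([P.weights, Q.weights])
    res = linprog(cost, A_eq=np.array(A_eq), b_eq=b_eq, bounds=(0, None), method="highs")
    assert res.status == 0
    return res.fun
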