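"""Transport metrics on (x, y) space and their dual-norm regularizers.

The robust estimator measures distributional ambiguity with an order-1
Wasserstein distance whose ground metric is a norm on the joint (predictor,
response) space.  The induced penalty on the regression coefficients is the
dual norm of the extended coefficient vector (-beta, 1):

    kappa(beta) = ||(-beta, 1)||_*

which is the growth rate (Lipschitz constant) of the absolute-residual loss
with respect to the chosen metric.  Closed forms per metric:

- l2 metric  -> kappa = sqrt(||beta||_2^2 + 1)
- l1 metric  -> dual is l-infinity: kappa = max(||beta||_inf, 1)
- l-inf metric -> dual is l1: kappa = ||beta||_1 + 1
- M-weighted metric ||v||_M = sqrt(v'Mv) -> kappa = sqrt((-beta,1)' M^{-1} (-beta,1))

Also provides discrete 1-D Wasserstein distances for the radius-selection
illustration: how far the empirical distribution of a contaminated sample sits
from the clean versus the outlying law as the contamination rate varies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import wasserstein_distance

KINDS = ("l1", "l2", "linf", "weighted")


@dataclass
class NormSpec:
    """Which norm induces the transport metric (and hence the regularizer)."""

    kind: str = "l2"
    M: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.kind = self.kind.lower()
        if self.kind not in KINDS:
            raise ValueError(f"unknown norm kind {self.kind!r}; one of {KINDS}")
        if self.kind == "weighted":
            if self.M is None:
                raise ValueError("kind='weighted' requires the weight matrix M")
            self.M = np.asarray(self.M, dtype=float)
            if not np.allclose(self.M, self.M.T, atol=1e-10):
                raise ValueError("M must be symmetric")
            if np.linalg.eigvalsh(self.M)[0] <= 0:
                raise ValueError("M must be positive definite")
        elif self.M is not None:
            raise ValueError(f"M is only meaningful for kind='weighted'")

    def m_inverse(self) -> np.ndarray:
        return np.linalg.inv(self.M)


def dual_norm(norm: NormSpec, beta: np.ndarray) -> float:
    """Growth-rate penalty kappa(beta) = ||(-beta, 1)||_* for the given metric."""
    beta = np.asarray(beta, dtype=float).ravel()
    if norm.kind == "l2":
        return float(np.sqrt(beta @ beta + 1.0))
    if norm.kind == "l1":  # dual norm is l-infinity
        return float(max(np.max(np.abs(beta), initial=0.0), 1.0))
    if norm.kind == "linf":  # dual norm is l1
        return float(np.sum(np.abs(beta)) + 1.0)
    v = np.concatenate([-beta, [1.0]])
    if norm.M.shape[0] != v.size:
        raise ValueError(
            f"M is {norm.M.shape[0]}x{norm.M.shape[0]} but (-beta, 1) has length {v.size}"
        )
    return float(np.sqrt(v @ np.linalg.solve(norm.M, v)))


def transport_cost(norm: NormSpec, p1: np.ndarray, p2: np.ndarray) -> float:
    """Ground-metric distance ||p1 - p2|| between two points of (x, y) space."""
    p1 = np.asarray(p1, dtype=float).ravel()
    p2 = np.asarray(p2, dtype=float).ravel()
    if p1.size != p2.size:
        raise ValueError("points have different dimensions")
    v = p1 - p2
    if norm.kind == "l2":
        return float(np.linalg.norm(v))
    if norm.kind == "l1":
        return float(np.sum(np.abs(v)))
    if norm.kind == "linf":
        return float(np.max(np.abs(v), initial=0.0))
    if norm.M.shape[0] != v.size:
        raise ValueError("weight matrix dimension does not match the points")
    return float(np.sqrt(v @ norm.M @ v))


@dataclass
class DiscreteDist1D:
    """Finitely supported distribution on the real line."""

    atoms: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=float).ravel()
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.atoms.size == 0:
            raise ValueError("distribution has empty support")
        if self.atoms.size != self.weights.size:
            raise ValueError("atoms and weights differ in length")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")

    @classmethod
    def from_samples(cls, x: np.ndarray) -> "DiscreteDist1D":
        x = np.asarray(x, dtype=float).ravel()
        return cls(x, np.full(x.size, 1.0 / x.size))


def w1_discrete_1d(P: DiscreteDist1D, Q: DiscreteDist1D) -> float:
    """Order-1 Wasserstein distance between two discrete distributions on R.

    Computed as the area between the two CDFs, which is exact in one
    dimension.
    """
    return float(
        wasserstein_distance(P.atoms, Q.atoms, P.weights, Q.weights)
    )


# Fixed pair of laws for the radius-selection experiment: a clean uniform law
# on ten points 0.1..1.0 and an outlying two-point law at {1, 2}.
CLEAN_LAW = DiscreteDist1D(np.linspace(0.1, 1.0, 10), np.full(10, 0.1))
OUTLYING_LAW = DiscreteDist1D(np.array([1.0, 2.0]), np.array([0.5, 0.5]))


def wdist_gap_curve(
    q_values: np.ndarray,
    n: int = 100,
    reps: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Mean W1 distances from a contaminated empirical law to clean/outlying laws.

    For each contamination rate q, draws ``n`` samples (each independently from
    the outlying law with probability q, else from the clean law), forms the
    empirical distribution, and measures its W1 distance to both laws,
    averaged over ``reps`` repetitions.

    Returns an array of shape (len(q_values), 2): columns are the mean
    distances (to clean law, to outlying law).  Below q = 0.5 the empirical
    law sits closer to the clean law, so a Wasserstein radius between the two
    curves excludes the outlying law from the ambiguity set.
    """
    q_values = np.asarray(q_values, dtype=float).ravel()
    if np.any((q_values < 0) | (q_values > 1)):
        raise ValueError("q values must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = np.zeros((q_values.size, 2))
    for i, q in enumerate(q_values):
        d_clean = np.zeros(reps)
        d_out = np.zeros(reps)
        for r in range(reps):
            from_out = rng.uniform(size=n) < q
            x = rng.choice(CLEAN_LAW.atoms, size=n, p=CLEAN_LAW.weights)
            x_out = rng.choice(OUTLYING_LAW.atoms, size=n, p=OUTLYING_LAW.weights)
            x[from_out] = x_out[from_out]
            emp = DiscreteDist1D.from_samples(x)
            d_clean[r] = w1_discrete_1d(emp, CLEAN_LAW)
            d_out[r] = w1_discrete_1d(emp, OUTLYING_LAW)
        out[i] = d_clean.mean(), d_out.mean()
    return out
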