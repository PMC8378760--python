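"""Synthetic contaminated-regression benchmark data.

Clean samples follow a Gaussian linear model: predictors x ~ N(0, Sigma) with a
compound-symmetric covariance (unit variances, constant correlation rho), and
response y ~ N(beta0 + x'beta, sigma^2).  Each training sample is independently
replaced, with probability ``q``, by a draw from an outlying distribution whose
form depends on the scenario family:

- ``dense_xy``:  x picks up an additive N(5e, I) shift, y a +5*sigma mean shift;
- ``dense_x``:   x shifted as above, y clean given x;
- ``sparse_xy``: x picks up additive N(0, 0.25 I) noise, y a +5*sigma mean shift;
- ``sparse_x``:  x shifted by N(5e, I), y clean given x;
- ``cloud``:     a tight, randomly placed cluster of predictor outliers whose
  responses sit at an exact offset ``delta_r`` from the regression plane (see
  :func:`generate_cloud_dataset`).

The dense families use intercept 0.3 and twenty coefficients of 0.5; the sparse
families use intercept 3 and coefficients (0.05, 0, 0.006, 0, -0.007, 0, 0.008,
0, ..., 0).  Noise level may be given directly (``sigma``) or through the
signal-to-noise ratio SNR = beta'Sigma beta / sigma^2.  Test splits contain
clean samples only: the estimators are judged on how well they track the clean
data-generating law.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FAMILIES = ("dense_xy", "dense_x", "sparse_xy", "sparse_x", "cloud")

#: Generating coefficients of the dense scenarios: intercept and 20 slopes.
DENSE_INTERCEPT = 0.3
DENSE_BETA = np.full(20, 0.5)

#: Generating coefficients of the sparse scenarios: 4 nonzero slopes out of 20.
SPARSE_INTERCEPT = 3.0
SPARSE_BETA = np.zeros(20)
SPARSE_BETA[[0, 2, 4, 6]] = (0.05, 0.006, -0.007, 0.008)

#: Cloud (outlier-detection) scenario: 30 predictors, N(7.5, 4^2) marginals.
CLOUD_INTERCEPT = 0.3
CLOUD_BETA = np.full(30, 0.5)
CLOUD_MEAN = 7.5
CLOUD_SD = 4.0


@dataclass
class GroundTruth:
    """Generating parameters of a synthetic dataset."""

    beta_star: np.ndarray
    intercept_star: float
    sigma: float
    Sigma: np.ndarray

    def __post_init__(self) -> None:
        self.beta_star = np.asarray(self.beta_star, dtype=float).ravel()
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        if self.sigma <= 0:
            raise ValueError("noise standard deviation sigma must be positive")
        if self.Sigma.shape != (self.beta_star.size, self.beta_star.size):
            raise ValueError("Sigma shape does not match beta_star length")
        if not np.allclose(self.Sigma, self.Sigma.T, atol=1e-10):
            raise ValueError("Sigma must be symmetric")
        if np.linalg.eigvalsh(self.Sigma)[0] <= -1e-10:
            raise ValueError("Sigma must be positive definite")

    @property
    def snr(self) -> float:
        """Signal-to-noise ratio beta'Sigma beta / sigma^2."""
        s = float(self.beta_star @ self.Sigma @ self.beta_star)
        return s / self.sigma**2


@dataclass
class RegressionData:
    """Predictor matrix, response vector, optional outlier labels and truth."""

    X: np.ndarray
    y: np.ndarray
    labels: Optional[np.ndarray] = None
    truth: Optional[GroundTruth] = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.shape[0] != self.y.size:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but y has {self.y.size} entries"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=bool).ravel()
            if self.labels.size != self.y.size:
                raise ValueError("labels length does not match y")
        if not (np.isfinite(self.X).all() and np.isfinite(self.y).all()):
            raise ValueError("data contain non-finite values")

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def p(self) -> int:
        return self.X.shape[1]


class TrainTest(NamedTuple):
    train: RegressionData
    test: RegressionData


@dataclass
class ScenarioSpec:
    """Full description of one synthetic experiment condition.

    Exactly one of ``snr``/``sigma`` must be given; the other is derived from
    SNR = beta'Sigma beta / sigma^2 for the family's fixed coefficients.
    """

    family: str
    q: float
    rho: float
    n_train: int
    n_test: int = 0
    snr: Optional[float] = None
    sigma: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; one of {FAMILIES}")
        if not 0 <= self.q < 1:
            raise ValueError("contamination probability q must be in [0, 1)")
        if self.q >= 0.5:
            logger.warning(
                "q=%.3g >= 0.5: outliers are assumed to be the minority; "
                "robust estimators target the majority (clean) distribution",
                self.q,
            )
        if (self.snr is None) == (self.sigma is None):
            raise ValueError("exactly one of snr / sigma must be set")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        p = self.n_predictors
        if not -1.0 / (p - 1) < self.rho < 1:
            raise ValueError(
                f"rho={self.rho} outside the positive-definite range "
                f"(-1/{p - 1}, 1) for {p} predictors"
            )
        if self.n_train < 1 or self.n_test < 0:
            raise ValueError("n_train must be >= 1 and n_test >= 0")

    @property
    def n_predictors(self) -> int:
        return 30 if self.family == "cloud" else 20

    def to_json(self) -> str:
        return json.dumps({k: getattr(self, k) for k in self.__dataclass_fields__})

    @classmethod
    def from_json(cls, text: str) -> "ScenarioSpec":
        return cls(**json.loads(text))


def build_sigma(p: int, rho: float) -> np.ndarray:
    """Compound-symmetric covariance: unit diagonal, ``rho`` off-diagonal.

    Positive definite iff rho in (-1/(p-1), 1): the eigenvalues are
    1 + (p-1)rho (once) and 1 - rho (p-1 times).
    """
    if p < 1:
        raise ValueError("p must be a positive integer")
    if p > 1 and not -1.0 / (p - 1) < rho < 1:
        raise ValueError(
            f"rho={rho} gives a non-positive-definite matrix: "
            f"requires rho in (-1/{p - 1}, 1)"
        )
    return np.full((p, p), rho) + (1 - rho) * np.eye(p)


def sigma_from_snr(beta_star: np.ndarray, Sigma: np.ndarray, snr: float) -> float:
    """Noise s.d. realizing a target SNR: sigma = sqrt(beta'Sigma beta / SNR)."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    beta_star = np.asarray(beta_star, dtype=float).ravel()
    signal = float(beta_star @ np.asarray(Sigma, dtype=float) @ beta_star)
    if signal <= 0:
        raise ValueError("beta_star carries no signal (beta'Sigma beta <= 0)")
    return float(np.sqrt(signal / snr))


def gamma_matrix(Sigma: np.ndarray, beta_star: np.ndarray, sigma: float) -> np.ndarray:
    """Joint covariance of (x, y): [[Sigma, Sigma b], [b'Sigma, b'Sigma b + sigma^2]]."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    Sigma = np.asarray(Sigma, dtype=float)
    b = np.asarray(beta_star, dtype=float).ravel()
    cross = Sigma @ b
    corner = float(b @ cross) + sigma**2
    top = np.hstack([Sigma, cross[:, None]])
    bottom = np.hstack([cross[None, :], [[corner]]])
    return np.vstack([top, bottom])


def _family_truth(spec: ScenarioSpec) -> GroundTruth:
    if spec.family.startswith("dense"):
        beta, b0 = DENSE_BETA, DENSE_INTERCEPT
    elif spec.family.startswith("sparse"):
        beta, b0 = SPARSE_BETA, SPARSE_INTERCEPT
    else:
        raise ValueError(
            "family 'cloud' has its own generator: use generate_cloud_dataset"
        )
    Sigma = build_sigma(beta.size, spec.rho)
    sigma = spec.sigma if spec.sigma is not None else sigma_from_snr(
        beta, Sigma, spec.snr
    )
    return GroundTruth(beta, b0, sigma, Sigma)


def generate_dataset(spec: ScenarioSpec) -> TrainTest:
    """Draw one train/test pair under a mixture-contamination scenario.

    Per training sample an independent Uniform(0,1) draw decides clean vs
    outlier (so the outlier count is Binomial(N, q), not a fixed quota).  The
    test split contains clean samples only.
    """
    if spec.family == "cloud":
        raise ValueError("family 'cloud' is handled by generate_cloud_dataset")
    truth = _family_truth(spec)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    p = truth.beta_star.size
    L = np.linalg.cholesky(truth.Sigma)

    def clean_x(n: int) -> np.ndarray:
        return rng.standard_normal((n, p)) @ L.T

    n = spec.n_train
    u = rng.uniform(size=n)
    outlier = u > 1 - spec.q
    X = clean_x(n)
    # additive predictor shift for the contaminated rows
    if spec.family in ("dense_xy", "dense_x", "sparse_x"):
        shift = 5.0 + rng.standard_normal((n, p))
    else:  # sparse_xy: pure extra noise, no mean shift
        shift = 0.5 * rng.standard_normal((n, p))
    X[outlier] += shift[outlier]
    y = truth.intercept_star + X @ truth.beta_star + truth.sigma * rng.standard_normal(n)
    if spec.family.endswith("_xy"):
        y[outlier] += 5.0 * truth.sigma
    train = RegressionData(X, y, labels=outlier, truth=truth)

    m = spec.n_test
    Xt = clean_x(m)
    yt = (
        truth.intercept_star
        + Xt @ truth.beta_star
        + truth.sigma * rng.standard_normal(m)
    )
    test = RegressionData(Xt, yt, labels=np.zeros(m, dtype=bool), truth=truth)
    return TrainTest(train, test)


def generate_cloud_dataset(
    n: int, q: float, sigma: float, delta_r: float, seed: int = 0
) -> RegressionData:
    """Outlier-detection scenario: a tight predictor cloud off the plane.

    Clean rows: 30 i.i.d. N(7.5, 4^2) predictors, y = 0.3 + 0.5*sum(x) + noise.
    Outlier rows: one center u ~ Uniform(7.5 - 12, 7.5 + 12) per row, predictors
    Uniform(u - 0.125, u + 0.125), and the response sits exactly ``delta_r``
    above the regression plane (no noise): the anomaly is the offset itself.
    """
    if not 0 <= q < 1:
        raise ValueError("q must be in [0, 1)")
    if q >= 0.5:
        logger.warning("q=%.3g >= 0.5: outliers are assumed to be the minority", q)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    p = CLOUD_BETA.size
    u = rng.uniform(size=n)
    outlier = u > 1 - q
    X = CLOUD_MEAN + CLOUD_SD * rng.standard_normal((n, p))
    centers = rng.uniform(CLOUD_MEAN - 3 * CLOUD_SD, CLOUD_MEAN + 3 * CLOUD_SD, size=n)
    Xout = centers[:, None] + rng.uniform(-0.125, 0.125, size=(n, p))
    X[outlier] = Xout[outlier]
    plane = CLOUD_INTERCEPT + X @ CLOUD_BETA
    y = plane + sigma * rng.standard_normal(n)
    y[outlier] = plane[outlier] + delta_r
    truth = GroundTruth(CLOUD_BETA, CLOUD_INTERCEPT, sigma, CLOUD_SD**2 * np.eye(p))
    return RegressionData(X, y, labels=outlier, truth=truth)


# ---------------------------------------------------------------------------
# CSV / JSON persistence
# ---------------------------------------------------------------------------

def write_dataset(data: RegressionData, path: str | Path, sidecar: dict | None = None) -> None:
    """Write a dataset as CSV (x1..xK, y[, is_outlier]) plus a JSON sidecar.

    The sidecar (``<path>.json``) records the generating truth when present,
    merged with any extra entries supplied by the caller.
    """
    path = Path(path)
    cols = {f"x{j + 1}": data.X[:, j] for j in range(data.p)}
    cols["y"] = data.y
    if data.labels is not None:
        cols["is_outlier"] = data.labels.astype(int)
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    meta: dict = dict(sidecar or {})
    if data.truth is not None:
        meta.update(
            beta_star=data.truth.beta_star.tolist(),
            intercept_star=data.truth.intercept_star,
            sigma=data.truth.sigma,
            Sigma=data.truth.Sigma.tolist(),
        )
    if meta:
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_dataset(path: str | Path) -> RegressionData:
    """Read a dataset written by :func:`write_dataset` (sidecar optional)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if "y" not in df.columns:
        raise ValueError(f"{path}: missing required response column 'y'")
    xcols = [c for c in df.columns if c.startswith("x")]
    if not xcols:
        raise ValueError(f"{path}: no predictor columns (expected x1, x2, ...)")
    xcols = sorted(xcols, key=lambda c: int(c[1:]))
    for c in xcols + ["y"]:
        if not pd.api.types.is_numeric_dtype(df[c]):
            raise ValueError(f"{path}: column {c!r} contains non-numeric values")
    labels = None
    if "is_outlier" in df.columns:
        labels = df["is_outlier"].to_numpy().astype(bool)
    truth = None
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if "beta_star" in meta:
            truth = GroundTruth(
                np.asarray(meta["beta_star"]),
                float(meta["intercept_star"]),
                float(meta["sigma"]),
                np.asarray(meta["Sigma"]),
            )
    return RegressionData(df[xcols].to_numpy(), df["y"].to_numpy(), labels, truth)
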