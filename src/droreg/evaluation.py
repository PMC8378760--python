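"""Estimation-accuracy metrics and residual-based outlier detection.

Against a known generating truth (beta*, Sigma, sigma), an estimate beta_hat
with error Delta = beta_hat - beta* is scored by

- MSE:  mean squared prediction error on a clean test set;
- RR:   Delta'Sigma Delta / beta*'Sigma beta*        (perfect 0, null 1);
- RTE:  (Delta'Sigma Delta + sigma^2) / sigma^2      (perfect 1, null SNR+1);
- PVE:  1 - (Delta'Sigma Delta + sigma^2) / (beta*'Sigma beta* + sigma^2)
        (perfect SNR/(SNR+1), null 0).

RTE = RR * SNR + 1 holds as an algebraic identity.

Outlier detection flags training rows whose absolute residual exceeds a
threshold multiple of the residual standard deviation; sweeping the threshold
yields a ROC curve and its AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from sklearn import metrics as _skmetrics

from .datagen import GroundTruth, RegressionData


@dataclass
class MetricsReport:
    """MSE/RR/RTE/PVE for one fitted estimator against the generating truth."""

    rr: float
    rte: float
    pve: float
    mse: Optional[float] = None

    def to_dict(self) -> dict:
        return {"mse": self.mse, "rr": self.rr, "rte": self.rte, "pve": self.pve}


@dataclass
class DetectionResult:
    """Flags at one threshold plus the full ROC sweep."""

    flags: np.ndarray
    sigma_hat: float
    threshold: float
    roc: np.ndarray  # (n_points, 2) columns (fpr, tpr)
    auc: float

    def roc_csv(self) -> str:
        lines = ["fpr,tpr"] + [f"{f:.10g},{t:.10g}" for f, t in self.roc]
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        return {
            "flags": self.flags.astype(int).tolist(),
            "sigma_hat": self.sigma_hat,
            "threshold": self.threshold,
            "roc": self.roc.tolist(),
            "auc": self.auc,
        }


def score_estimate(
    beta_hat: np.ndarray,
    intercept_hat: float,
    truth: GroundTruth,
    test: Optional[RegressionData] = None,
) -> MetricsReport:
    """Score an estimate against the generating truth (MSE needs a test set)."""
    beta_hat = np.asarray(beta_hat, dtype=float).ravel()
    signal = float(truth.beta_star @ truth.Sigma @ truth.beta_star)
    if signal <= 0:
        raise ValueError("relative metrics undefined: beta* carries no signal")
    delta = beta_hat - truth.beta_star
    d2 = float(delta @ truth.Sigma @ delta)
    s2 = truth.sigma**2
    rr = d2 / signal
    rte = (d2 + s2) / s2
    pve = 1.0 - (d2 + s2) / (signal + s2)
    mse = None
    if test is not None and test.n > 0:
        resid = test.y - intercept_hat - test.X @ beta_hat
        mse = float(np.mean(resid**2))
    return MetricsReport(rr=rr, rte=rte, pve=pve, mse=mse)


def residual_sigma(residuals: np.ndarray) -> float:
    """Sample (n-1) standard deviation of the residuals."""
    residuals = np.asarray(residuals, dtype=float).ravel()
    if residuals.size < 2:
        raise ValueError("need at least two residuals")
    s = float(np.std(residuals, ddof=1))
    if s == 0:
        warnings.warn(
            "residuals are constant: sigma_hat = 0 makes flagging all-or-nothing",
            RuntimeWarning,
        )
    return s


def flag_outliers(
    residuals: np.ndarray, sigma_hat: float, threshold: float
) -> np.ndarray:
    """Flag rows with |residual| > threshold * sigma_hat."""
    if sigma_hat < 0 or threshold < 0:
        raise ValueError("sigma_hat and threshold must be nonnegative")
    return np.abs(np.asarray(residuals, dtype=float)) > threshold * sigma_hat


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> Tuple[np.ndarray, float]:
    """ROC curve (all distinct score thresholds) and rank-statistic AUC.

    Ties in the scores contribute 1/2 to the AUC, per the Mann-Whitney
    convention.  Requires both classes to be present.
    """
    labels = np.asarray(labels).astype(bool).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if labels.all() or not labels.any():
        raise ValueError("ROC needs at least one positive and one negative label")
    fpr, tpr, _ = _skmetrics.roc_curve(labels, scores, drop_intermediate=False)
    auc = float(_skmetrics.roc_auc_score(labels, scores))
    return np.column_stack([fpr, tpr]), auc


def detect_outliers(
    residuals: np.ndarray,
    labels: Optional[np.ndarray] = None,
    threshold: float = 3.0,
) -> DetectionResult:
    """Full detection report: sigma_hat, flags at ``threshold``, ROC/AUC.

    The detection score of a row is |residual| / sigma_hat; the ROC sweeps
    that score over all its distinct values.  When true labels are absent the
    ROC/AUC fields are empty/NaN.
    """
    residuals = np.asarray(residuals, dtype=float).ravel()
    s = residual_sigma(residuals)
    flags = flag_outliers(residuals, s, threshold)
    if labels is None:
        roc = np.empty((0, 2))
        auc = float("nan")
    else:
        scores = np.abs(residuals) / s if s > 0 else np.abs(residuals)
        roc, auc = roc_auc(labels, scores)
    return DetectionResult(flags=flags, sigma_hat=s, threshold=threshold, roc=roc, auc=auc)
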