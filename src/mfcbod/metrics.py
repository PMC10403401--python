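"""Evaluation statistics: MSE training losses, MAPE, MAX, R2, and
pollution classification scores (sensitivity / specificity / accuracy)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np


@dataclass(frozen=True)
class MetricsReport:
    """Regression metrics for one evaluation."""

    mape: float  # percent
    max_abs_error: float  # mg
    r2: float
    n: int

    def __post_init__(self) -> None:
        if self.mape < 0 or self.max_abs_error < 0:
            raise ValueError("mape and max_abs_error must be non-negative")
        if self.r2 > 1 + 1e-12:
            raise ValueError("r2 cannot exceed 1")


@dataclass(frozen=True)
class ClassificationReport:
    """Pollution classification scores; a score is None when its class is absent."""

    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: float
    threshold: float

    def __post_init__(self) -> None:
        for value in (self.sensitivity, self.specificity, self.accuracy):
            if value is not None and not 0 <= value <= 1:
                raise ValueError("scores must lie in [0, 1]")


def _pair(true: Sequence[float], pred: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(true, dtype=float)
    p = np.asarray(pred, dtype=float)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {p.shape}")
    if t.size == 0:
        raise ValueError("empty input")
    return t, p


def mape(true: Sequence[float], pred: Sequence[float]) -> float:
    """Mean absolute percentage error, in percent."""
    t, p = _pair(true, pred)
    zeros = np.nonzero(t == 0)[0]
    if zeros.size:
        raise ZeroDivisionError(
            f"MAPE undefined: true value is 0 at position(s) {zeros.tolist()}"
        )
    return float(np.mean(np.abs(t - p) / np.abs(t)) * 100.0)


def max_abs_error(true: Sequence[float], pred: Sequence[float]) -> float:
    """Maximum absolute error."""
    t, p = _pair(true, pred)
    return float(np.max(np.abs(t - p)))


def r_squared(true: Sequence[float], pred: Sequence[float]) -> float:
    """Coefficient of determination about the mean of the true values."""
    t, p = _pair(true, pred)
    if t.size < 2:
        raise ValueError("need at least 2 points for R^2")
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: true values have zero variance")
    return 1.0 - float(np.sum((p - t) ** 2)) / ss_tot


def mse_direct(true: Sequence[float], pred: Sequence[float]) -> float:
    """Training loss of the direct approach: mean squared error over experiments."""
    t, p = _pair(true, pred)
    return float(np.mean((t - p) ** 2))


def mse_indirect(true: np.ndarray, pred: np.ndarray) -> float:
    """Training loss of the indirect approach.

    Averages squared voltage errors over n experiments x n2 time points,
    i.e. the per-element mean over the (n, n2) matrices.
    """
    t = np.asarray(true, dtype=float)
    p = np.asarray(pred, dtype=float)
    if t.shape != p.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {p.shape}")
    if t.ndim != 2 or t.size == 0:
        raise ValueError("expected non-empty 2-D matrices")
    return float(np.mean((t - p) ** 2))


def evaluate(true: Sequence[float], pred: Sequence[float]) -> MetricsReport:
    """MAPE + MAX + R2 in one report."""
    t, p = _pair(true, pred)
    return MetricsReport(
        mape=mape(t, p),
        max_abs_error=max_abs_error(t, p),
        r2=r_squared(t, p),
        n=int(t.size),
    )


def classify_and_score(
    true_bod: Sequence[float],
    pred_bod: Sequence[float],
    threshold: float,
) -> ClassificationReport:
    """Binary pollution scoring: a sample is polluted iff BOD >= threshold.

    The label rule is applied to both the true and the predicted values.
    Sensitivity (recall on polluted) or specificity (recall on unpolluted)
    is reported as None when the corresponding class is absent, rather
    than silently as 0.  The threshold scale (mg vs mg/L) is the caller's
    choice and must match the scale of the inputs.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    t, p = _pair(true_bod, pred_bod)
    true_pos = t >= threshold
    pred_pos = p >= threshold
    n_pos = int(true_pos.sum())
    n_neg = int((~true_pos).sum())
    sensitivity = (
        float((true_pos & pred_pos).sum() / n_pos) if n_pos > 0 else None
    )
    specificity = (
        float((~true_pos & ~pred_pos).sum() / n_neg) if n_neg > 0 else None
    )
    accuracy = float((true_pos == pred_pos).sum() / t.size)
    return ClassificationReport(
        sensitivity=sensitivity,
        specificity=specificity,
        accuracy=accuracy,
        threshold=threshold,
    )
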