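"""Evaluation metrics: confusion-derived statistics, AUC, calibration, DCA.

All metrics take plain arrays.  Ratios with empty denominators are
reported as ``None`` (missing) rather than coerced to zero.  AUC is
the Mann-Whitney rank statistic with ties counted half; the expected
calibration error (ECE) uses equal-width, count-weighted bins; the
Brier score is the mean squared probability error; decision-curve net
benefit trades true positives against false positives weighted by the
odds of the decision threshold:

    NB(p_t) = TP/N - (FP/N) * p_t / (1 - p_t).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "EvalResult",
    "auc",
    "brier",
    "confusion_metrics",
    "ece",
    "net_benefit",
    "net_benefit_curve",
]


@dataclass
class EvalResult:
    """Bundle of evaluation metrics; unavailable entries are ``None``."""

    accuracy: Optional[float] = None
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    ppv: Optional[float] = None
    npv: Optional[float] = None
    f1: Optional[float] = None
    mcc: Optional[float] = None
    auc: Optional[float] = None
    ece: Optional[float] = None
    brier: Optional[float] = None
    net_benefit: list[tuple[float, float]] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "f1": self.f1,
            "mcc": self.mcc,
            "auc": self.auc,
            "ece": self.ece,
            "brier": self.brier,
            "net_benefit": [list(pair) for pair in self.net_benefit],
        }


def _ratio(num: float, den: float) -> Optional[float]:
    return num / den if den > 0 else None


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> EvalResult:
    """Standard confusion-matrix statistics; zero denominators give ``None``."""
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0 or v != int(v):
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    n = tp + fp + tn + fn
    if n < 1:
        raise ValueError("at least one count must be positive")
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    ppv = _ratio(tp, tp + fp)
    npv = _ratio(tn, tn + fn)
    f1 = None
    if ppv is not None and sens is not None and (ppv + sens) > 0:
        f1 = 2 * ppv * sens / (ppv + sens)
    mcc_den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(mcc_den) if mcc_den > 0 else None
    return EvalResult(
        accuracy=(tp + tn) / n,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        f1=f1,
        mcc=None if mcc is None else float(mcc),
    )


def _paired(probs, labels, name: str = "probs") -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape or p.ndim != 1 or p.size == 0:
        raise ValueError(f"{name} and labels must be equal-length non-empty 1-D arrays")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("labels must be binary (0/1)")
    return p, y


def ece(probs, labels, n_bins: int = 10) -> float:
    """Expected calibration error over equal-width, count-weighted bins."""
    p, y = _paired(probs, labels)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1], right=False), 0, n_bins - 1)
    total = 0.0
    for b in range(n_bins):
        sel = idx == b
        if not np.any(sel):
            continue
        gap = abs(p[sel].mean() - y[sel].mean())
        total += sel.sum() / p.size * gap
    return float(total)


def brier(probs, labels) -> float:
    """Mean squared error between probabilities and binary outcomes."""
    p, y = _paired(probs, labels)
    return float(np.mean((p - y) ** 2))


def auc(scores, labels) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    Ties count half.  Raises if only one class is present.
    """
    s, y = _paired(scores, labels, name="scores")
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC is undefined when only one class is present")
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def net_benefit(probs, labels, threshold: float) -> float:
    """Decision-curve net benefit at one threshold probability.

    Classifies positive at ``prob >= threshold`` and returns
    ``TP/N - (FP/N) * threshold / (1 - threshold)``.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie strictly inside (0, 1)")
    p, y = _paired(probs, labels)
    pred = p >= threshold
    tp = float(np.sum(pred & (y == 1)))
    fp = float(np.sum(pred & (y == 0)))
    n = p.size
    return tp / n - (fp / n) * threshold / (1.0 - threshold)


def net_benefit_curve(
    probs, labels, thresholds: Sequence[float]
) -> list[tuple[float, float]]:
    """Net benefit evaluated over a grid of thresholds."""
    return [(float(t), net_benefit(probs, labels, t)) for t in thresholds]
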