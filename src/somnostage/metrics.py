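"""Evaluation suite for five-class sleep staging.

Confusion matrices (rows = actual, columns = predicted), per-class precision /
recall / F1, overall accuracy, macro-F1 (the unweighted mean of the five
per-class F1 scores) and Cohen's chance-corrected agreement kappa.  Metric
values are kept at full precision internally; display helpers round half-up to
one decimal, matching the convention of published sleep-staging tables, and
kappa is reported on the x100 percent scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from somnostage.stages import N_STAGES, STAGE_NAMES


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (1.25 -> 1.3), unlike banker's rounding."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ClassMetrics:
    """Precision / recall / F1 of one stage, as percentages."""

    precision: float
    recall: float
    f1: float


@dataclass
class MetricsReport:
    """Overall and per-class performance, all on the percent scale."""

    acc: float
    mf1: float
    kappa: float
    per_class: dict[str, ClassMetrics]

    def rounded(self) -> dict:
        """One-decimal half-up display dict."""
        return {
            "ACC": round_half_up(self.acc),
            "MF1": round_half_up(self.mf1),
            "kappa": round_half_up(self.kappa),
            "per_class": {
                name: {
                    "precision": round_half_up(m.precision),
                    "recall": round_half_up(m.recall),
                    "f1": round_half_up(m.f1),
                }
                for name, m in self.per_class.items()
            },
        }


def confusion(truth, pred, n_classes: int = N_STAGES) -> np.ndarray:
    """Count matrix with rows = actual stage, columns = predicted stage."""
    truth = np.asarray(truth, dtype=np.int64)
    pred = np.asarray(pred, dtype=np.int64)
    if truth.shape != pred.shape or truth.ndim != 1:
        raise ValueError(
            f"truth and pred must be equal-length 1-D sequences; got {truth.shape} vs {pred.shape}"
        )
    if truth.size == 0:
        raise ValueError("empty label sequences")
    if truth.min() < 0 or truth.max() >= n_classes or pred.min() < 0 or pred.max() >= n_classes:
        raise ValueError(f"labels must lie in [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (truth, pred), 1)
    return cm


def _validate_cm(cm) -> np.ndarray:
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError(f"confusion matrix must be square, got shape {cm.shape}")
    if (cm < 0).any() or cm.sum() <= 0:
        raise ValueError("confusion matrix must be non-negative with positive total")
    return cm.astype(np.float64)


def per_class_metrics(cm) -> dict[str, ClassMetrics]:
    """Precision, recall and F1 per stage (percent); zero denominators give 0."""
    cmf = _validate_cm(cm)
    n = cmf.shape[0]
    names = STAGE_NAMES if n == N_STAGES else tuple(str(i) for i in range(n))
    out: dict[str, ClassMetrics] = {}
    for c in range(n):
        tp = cmf[c, c]
        colsum = cmf[:, c].sum()
        rowsum = cmf[c, :].sum()
        if colsum == 0 or rowsum == 0:
            warnings.warn(f"stage {names[c]} absent from truth or predictions; metrics set to 0")
        precision = tp / colsum if colsum > 0 else 0.0
        recall = tp / rowsum if rowsum > 0 else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
        out[names[c]] = ClassMetrics(100 * precision, 100 * recall, 100 * f1)
    return out


def cohen_kappa(cm) -> float:
    """Chance-corrected agreement on the [-1, 1] scale."""
    cmf = _validate_cm(cm)
    total = cmf.sum()
    p_o = np.trace(cmf) / total
    p_e = float((cmf.sum(axis=1) * cmf.sum(axis=0)).sum()) / total**2
    if p_e == 1.0:
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def overall_metrics(cm) -> MetricsReport:
    """ACC, macro-F1 and kappa (percent scale) plus per-class metrics."""
    cmf = _validate_cm(cm)
    per_class = per_class_metrics(cm)
    acc = 100.0 * np.trace(cmf) / cmf.sum()
    mf1 = float(np.mean([m.f1 for m in per_class.values()]))
    kappa = 100.0 * cohen_kappa(cm)
    return MetricsReport(acc=acc, mf1=mf1, kappa=kappa, per_class=per_class)
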