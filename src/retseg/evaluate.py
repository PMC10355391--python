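"""Segmentation scoring against manual ground truth, inside the FOV.

Sensitivity Se = TP/(TP+FN), specificity Sp = TN/(TN+FP), accuracy
AC = (TP+TN)/|FOV|, and the summary AUC = (Se+Sp)/2 — the balanced
accuracy of the binary map, not a trapezoidal ROC integral.  A full ROC
curve over response thresholds is also provided.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._util import as_float_image, check_binary
from .exceptions import ParameterError

__all__ = ["SegmentationMetrics", "RocCurve", "confusion_metrics", "roc_curve"]


def round3(x: float) -> float:
    """Round half away from zero to 3 decimals (table convention)."""
    return float(np.sign(x) * np.floor(abs(x) * 1000.0 + 0.5) / 1000.0)


@dataclass
class SegmentationMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    warnings: tuple[str, ...] = ()

    def rounded(self) -> dict[str, float]:
        return {k: round3(getattr(self, k))
                for k in ("sensitivity", "specificity", "accuracy", "auc")}

    def to_dict(self) -> dict:
        d = {k: int(getattr(self, k)) for k in ("tp", "fp", "tn", "fn")}
        d.update({k: float(getattr(self, k))
                  for k in ("sensitivity", "specificity", "accuracy", "auc")})
        if self.warnings:
            d["warnings"] = list(self.warnings)
        return d


@dataclass
class RocCurve:
    """(FPR, TPR) pairs ordered by decreasing threshold, from (0,0) to (1,1)."""

    points: list = field(default_factory=list)
    thresholds: list = field(default_factory=list)

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["threshold", "fpr", "tpr"])
            for tau, (fpr, tpr) in zip(self.thresholds, self.points):
                writer.writerow([tau, fpr, tpr])


def confusion_metrics(pred: np.ndarray, truth: np.ndarray,
                      fov: np.ndarray) -> SegmentationMetrics:
    """Confusion counts and Se/Sp/AC/AUC over FOV pixels only.

    An empty-denominator rate (no vessel pixels, or no background pixels)
    is reported as 1 with a warning flag.
    """
    pred = check_binary(pred, "pred")
    truth = check_binary(truth, "truth")
    fov = check_binary(fov, "fov")
    if not (pred.shape == truth.shape == fov.shape):
        raise ParameterError("pred, truth and FOV dimensions differ")
    p = pred[fov]
    t = truth[fov]
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))

    warnings = []
    if tp + fn > 0:
        se = tp / (tp + fn)
    else:
        se, warnings = 1.0, warnings + ["empty truth: sensitivity reported as 1"]
    if tn + fp > 0:
        sp = tn / (tn + fp)
    else:
        sp, warnings = 1.0, warnings + ["empty background: specificity reported as 1"]
    ac = (tp + tn) / (tp + fp + tn + fn)
    return SegmentationMetrics(tp=tp, fp=fp, tn=tn, fn=fn,
                               sensitivity=se, specificity=sp, accuracy=ac,
                               auc=(se + sp) / 2.0, warnings=tuple(warnings))


def roc_curve(response: np.ndarray, truth: np.ndarray, fov: np.ndarray,
              n_thresholds: int = 100) -> RocCurve:
    """ROC of a soft response swept over evenly spaced thresholds in [0,1].

    Thresholding at tau classifies response >= tau as vessel; endpoints
    (0,0) (tau above the maximum) and (1,1) (tau = 0) are included.
    """
    if n_thresholds < 2:
        raise ParameterError("n_thresholds must be >= 2")
    response = as_float_image(response)
    truth = check_binary(truth, "truth")
    fov = check_binary(fov, "fov")
    r = response[fov]
    t = truth[fov]
    n_pos = max(int(t.sum()), 1)
    n_neg = max(int((~t).sum()), 1)

    taus = [float(r.max()) + 1e-9] + list(np.linspace(1.0, 0.0, n_thresholds))
    points, thresholds = [], []
    for tau in taus:
        pred = r >= tau
        tpr = float(np.count_nonzero(pred & t)) / n_pos
        fpr = float(np.count_nonzero(pred & ~t)) / n_neg
        points.append((fpr, tpr))
        thresholds.append(tau)
    return RocCurve(points=points, thresholds=thresholds)


def metrics_to_json(metrics: SegmentationMetrics, path: str | Path) -> None:
    Path(path).write_text(json.dumps(metrics.to_dict(), indent=2) + "\n")


def metrics_table(rows: dict[str, SegmentationMetrics]) -> str:
    """Human-readable fixed-width table of rounded metrics."""
    lines = [f"{'image':<20} {'Se':>7} {'Sp':>7} {'AC':>7} {'AUC':>7}"]
    for name, m in rows.items():
        r = m.rounded()
        lines.append(f"{name:<20} {r['sensitivity']:>7.3f} {r['specificity']:>7.3f} "
                     f"{r['accuracy']:>7.3f} {r['auc']:>7.3f}")
    return "\n".join(lines)
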