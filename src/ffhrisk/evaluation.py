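"""Regression error, 9 g risk classification, and per-movement summaries.

The regression metrics are MAE = (1/N) sum |yhat_i - y_i| (g) and
MSE = (1/N) sum (yhat_i - y_i)^2 (g^2).  Risk classification calls a trial a
fall-from-height (FFH) when its peak acceleration reaches 9 g or higher; the
ground-truth label uses the measured peak, the predicted label the model's
predicted peak, and sensitivity / specificity / accuracy are the usual
percentage rates of that 2x2 confusion table.  Zero-denominator rates are
reported as undefined, never silently as zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

FFH_THRESHOLD_G = 9.0

__all__ = ["PredictionSet", "ConfusionCounts", "EvaluationReport",
           "mae", "mse", "classify_risk", "confusion_metrics",
           "per_movement_summary", "evaluate", "FFH_THRESHOLD_G"]


@dataclass(frozen=True)
class PredictionSet:
    """Paired measured/predicted peaks (g) with movement labels."""

    y_true: np.ndarray
    y_pred: np.ndarray
    movement_codes: tuple = ()
    categories: tuple = ()

    def __post_init__(self) -> None:
        yt = np.asarray(self.y_true, dtype=float)
        yp = np.asarray(self.y_pred, dtype=float)
        object.__setattr__(self, "y_true", yt)
        object.__setattr__(self, "y_pred", yp)
        if yt.shape != yp.shape or yt.ndim != 1:
            raise ValueError("y_true and y_pred must be 1-D arrays of equal length")
        if yt.size < 1:
            raise ValueError("a PredictionSet needs at least one pair")
        if not (np.isfinite(yt).all() and np.isfinite(yp).all()):
            raise ValueError("non-finite values in PredictionSet")
        for name in ("movement_codes", "categories"):
            labels = getattr(self, name)
            if labels and len(labels) != yt.size:
                raise ValueError(f"{name} length mismatch")

    @property
    def n(self) -> int:
        return int(self.y_true.size)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class EvaluationReport:
    mae_g: float
    mse_g2: float
    threshold_g: float
    confusion: ConfusionCounts
    sensitivity_pct: float | None
    specificity_pct: float | None
    accuracy_pct: float
    undefined_metrics: tuple = ()
    per_movement: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = {
            "mae_g": self.mae_g, "mse_g2": self.mse_g2,
            "threshold_g": self.threshold_g,
            "confusion": {"tp": self.confusion.tp, "fp": self.confusion.fp,
                          "tn": self.confusion.tn, "fn": self.confusion.fn},
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "accuracy_pct": self.accuracy_pct,
            "undefined_metrics": list(self.undefined_metrics),
        }
        if self.per_movement is not None:
            d["per_movement"] = json.loads(
                self.per_movement.to_json(orient="records"))
        return d

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def mae(predictions: PredictionSet) -> float:
    """Mean absolute error in g."""
    return float(np.mean(np.abs(predictions.y_pred - predictions.y_true)))


def mse(predictions: PredictionSet) -> float:
    """Mean squared error in g^2."""
    return float(np.mean((predictions.y_pred - predictions.y_true) ** 2))


def classify_risk(peak_g: float, threshold_g: float = FFH_THRESHOLD_G) -> str:
    """'FFH' when the peak reaches the threshold (9 g or higher), else 'non-FFH'."""
    if not np.isfinite(peak_g):
        raise ValueError("peak must be finite")
    return "FFH" if peak_g >= threshold_g else "non-FFH"


def confusion_metrics(predictions: PredictionSet,
                      threshold_g: float = FFH_THRESHOLD_G
                      ) -> tuple[ConfusionCounts, dict]:
    """Confusion counts and percentage rates at the risk threshold.

    Truth is `y_true >= threshold`, prediction `y_pred >= threshold`.  Rates
    with a zero denominator come back as None and are listed under
    'undefined'.
    """
    truth = predictions.y_true >= threshold_g
    pred = predictions.y_pred >= threshold_g
    tp = int(np.sum(truth & pred))
    fn = int(np.sum(truth & ~pred))
    fp = int(np.sum(~truth & pred))
    tn = int(np.sum(~truth & ~pred))
    counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)

    undefined = []
    if tp + fn > 0:
        sens = 100.0 * tp / (tp + fn)
    else:
        sens = None
        undefined.append("sensitivity")
    if tn + fp > 0:
        spec = 100.0 * tn / (tn + fp)
    else:
        spec = None
        undefined.append("specificity")
    acc = 100.0 * (tp + tn) / counts.n
    return counts, {"sensitivity_pct": sens, "specificity_pct": spec,
                    "accuracy_pct": acc, "undefined": tuple(undefined)}


def per_movement_summary(predictions: PredictionSet) -> pd.DataFrame:
    """Per-movement n, true mean/sd and predicted mean/sd (sd with n-1; NaN at n=1)."""
    if not predictions.movement_codes:
        raise ValueError("per-movement summary needs movement codes")
    df = pd.DataFrame({
        "movement_code": list(predictions.movement_codes),
        "y_true": predictions.y_true, "y_pred": predictions.y_pred,
    })
    g = df.groupby("movement_code")
    out = pd.DataFrame({
        "n": g.size(),
        "true_mean_g": g["y_true"].mean(),
        "true_sd_g": g["y_true"].std(ddof=1),
        "pred_mean_g": g["y_pred"].mean(),
        "pred_sd_g": g["y_pred"].std(ddof=1),
    }).reset_index()
    return out.sort_values("movement_code").reset_index(drop=True)


def evaluate(predictions: PredictionSet,
             threshold_g: float = FFH_THRESHOLD_G) -> EvaluationReport:
    """Full report: errors, confusion, rates and per-movement table."""
    m_abs = mae(predictions)
    m_sq = mse(predictions)
    # mean |e| can never exceed the root mean square error
    assert m_abs <= math.sqrt(m_sq) + 1e-9, "MAE exceeded RMSE: metric bug"
    counts, rates = confusion_metrics(predictions, threshold_g)
    per_mov = (per_movement_summary(predictions)
               if predictions.movement_codes else None)
    return EvaluationReport(
        mae_g=m_abs, mse_g2=m_sq, threshold_g=threshold_g, confusion=counts,
        sensitivity_pct=rates["sensitivity_pct"],
        specificity_pct=rates["specificity_pct"],
        accuracy_pct=rates["accuracy_pct"],
        undefined_metrics=rates["undefined"], per_movement=per_mov)
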