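"""Agreement and classification accuracy analysis.

Estimated volumes are compared with actual voided volumes three ways:

* linear regression forced through the origin (slope β near 1 means
  unbiased estimation), with the uncentered coefficient of
  determination R² = 1 − Σ(y − βx)² / Σy² appropriate for no-intercept
  models;
* 2x2 confusion matrices at clinical thresholds (50 and 100 ml), with
  "positive" meaning volume ≥ threshold on both axes;
* sensitivity = tp/(tp+fn) and specificity = tn/(tn+fp), reported as
  percentages rounded half-up to one decimal.

A Dice overlap metric for segmentation masks is included for phantom
experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np


@dataclass(frozen=True)
class AgreementStats:
    """Through-origin regression summary of estimated vs actual volume."""

    beta: float
    r_squared: float
    n: int
    r_squared_centered: float = float("nan")


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    tp: int
    fp: int
    fn: int
    tn: int
    threshold_ml: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class EvaluationReport:
    agreement: AgreementStats
    confusion: Dict[float, ConfusionMatrix2x2]
    sensitivity_pct: Dict[float, float]
    specificity_pct: Dict[float, float]
    dice_summary: Optional[Dict[str, float]] = None


def regression_through_origin(pairs: Sequence[Tuple[float, float]]) -> AgreementStats:
    """Fit estimated = β · actual with no intercept.

    ``pairs`` is a sequence of (estimated_ml, actual_ml).  The actual
    volume is the predictor (x) and the estimate the response (y);
    β = Σxy / Σx², and R² uses the uncentered total sum of squares Σy²
    (the centered R², which can be negative for origin-forced fits, is
    carried along for reference).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (estimated, actual) pairs")
    y, x = arr[:, 0], arr[:, 1]
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        raise ValueError("actual volumes are all zero; slope undefined")
    beta = float(np.sum(x * y) / sxx)
    resid = y - beta * x
    ss_res = float(np.sum(resid**2))
    ss_tot_uncentered = float(np.sum(y**2))
    r2 = 1.0 - ss_res / ss_tot_uncentered if ss_tot_uncentered > 0 else float("nan")
    ss_tot_centered = float(np.sum((y - y.mean()) ** 2))
    r2c = 1.0 - ss_res / ss_tot_centered if ss_tot_centered > 0 else float("nan")
    return AgreementStats(beta=beta, r_squared=r2, n=len(y), r_squared_centered=r2c)


def confusion_at_threshold(
    pairs: Sequence[Tuple[float, float]], threshold_ml: float
) -> ConfusionMatrix2x2:
    """Tally estimated-vs-actual dichotomised at a threshold.

    Positive means "≥ threshold" on both axes (boundary inclusive).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
        raise ValueError("need at least one (estimated, actual) pair")
    est_pos = arr[:, 0] >= threshold_ml
    act_pos = arr[:, 1] >= threshold_ml
    return ConfusionMatrix2x2(
        tp=int(np.sum(est_pos & act_pos)),
        fp=int(np.sum(est_pos & ~act_pos)),
        fn=int(np.sum(~est_pos & act_pos)),
        tn=int(np.sum(~est_pos & ~act_pos)),
        threshold_ml=threshold_ml,
    )


def round_half_up_pct(fraction: float, decimals: int = 1) -> float:
    """Fraction -> percentage rounded half-up (table convention)."""
    q = Decimal(10) ** -decimals
    # scale in decimal arithmetic so that e.g. 0.8845 becomes exactly 88.45
    pct = Decimal(repr(float(fraction))) * 100
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def sensitivity_specificity(cm: ConfusionMatrix2x2) -> Tuple[float, float]:
    """Sensitivity and specificity of a confusion matrix, as fractions."""
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise ValueError("undefined metric: empty confusion-matrix margin")
    return cm.tp / (cm.tp + cm.fn), cm.tn / (cm.tn + cm.fp)


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); two empty masks score 1.0."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("mask shapes differ")
    denom = int(pred.sum()) + int(truth.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(pred, truth).sum()) / denom


def evaluate(
    pairs: Sequence[Tuple[float, float]],
    thresholds_ml: Iterable[float] = (50.0, 100.0),
    dice_values: Optional[Sequence[float]] = None,
) -> EvaluationReport:
    """Full accuracy report: regression, confusion and rates per threshold."""
    agreement = regression_through_origin(pairs)
    confusion: Dict[float, ConfusionMatrix2x2] = {}
    sens: Dict[float, float] = {}
    spec: Dict[float, float] = {}
    for thr in thresholds_ml:
        cm = confusion_at_threshold(pairs, thr)
        confusion[thr] = cm
        try:
            se, sp = sensitivity_specificity(cm)
        except ValueError:
            continue  # an empty margin leaves the rates undefined for this threshold
        sens[thr] = round_half_up_pct(se)
        spec[thr] = round_half_up_pct(sp)
    dsum = None
    if dice_values is not None and len(dice_values) > 0:
        arr = np.asarray(dice_values, dtype=float)
        dsum = {"mean": float(arr.mean()), "median": float(np.median(arr)), "min": float(arr.min())}
    return EvaluationReport(
        agreement=agreement,
        confusion=confusion,
        sensitivity_pct=sens,
        specificity_pct=spec,
        dice_summary=dsum,
    )
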