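"""Evaluation statistics and the orientation-bias diagnostic.

Regression quality is summarized by Pearson r, RMSE, MAE and MSE between
experimental and predicted ΔΔG.  Two predictors are compared per record with
a head/tail scheme — "head" when the first predictor's absolute error is
strictly smaller — followed by an exact two-sided binomial test of the head
count against a fair coin (exact ties are discarded).

The bias scan rotates a WT/MT structure pair into 120 fixed orientations
(10 icosahedral axes × 12 angles), runs the full featurize-and-predict
pipeline on each, and reports the spread of the 120 predictions.  With
orientation standardization the spread collapses to numerical noise for any
fixed model; with standardization disabled it does not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .featurize import FeaturizationError, featurize_mutation
from .rotations import bias_scan_rotations, rotate_structure
from .structures import MutationRecord, Structure

__all__ = [
    "MetricReport",
    "ComparisonResult",
    "ClassificationReport",
    "BiasScanReport",
    "regression_metrics",
    "binomial_comparison",
    "classification_metrics",
    "bias_scan",
]


@dataclass(frozen=True)
class MetricReport:
    pearson_r: float
    rmse: float
    mae: float
    mse: float
    n: int
    r_defined: bool = True


@dataclass(frozen=True)
class ComparisonResult:
    heads: int
    n_effective: int
    p_value: float
    ties_discarded: int

    def __post_init__(self) -> None:
        if not (0 <= self.heads <= self.n_effective):
            raise ValueError("head count outside [0, n_effective]")


@dataclass(frozen=True)
class ClassificationReport:
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    f1: float
    accuracy: float


@dataclass(frozen=True)
class BiasScanReport:
    predictions: np.ndarray  # kcal/mol, one per orientation
    range: float  # max − min
    sign_consistent: bool  # all predictions share one sign (0 counts as +)
    n_failed: int = 0


def regression_metrics(y_true, y_pred) -> MetricReport:
    """Pearson r, RMSE, MAE and MSE of predictions against labels."""
    y_true = np.asarray(y_true, dtype=float).reshape(-1)
    y_pred = np.asarray(y_pred, dtype=float).reshape(-1)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if len(y_true) == 0:
        raise ValueError("empty input")
    diff = y_pred - y_true
    mse = float(np.mean(diff**2))
    report = dict(
        rmse=float(np.sqrt(mse)),
        mae=float(np.mean(np.abs(diff))),
        mse=mse,
        n=len(y_true),
    )
    if len(y_true) >= 2 and np.std(y_pred) > 0 and np.std(y_true) > 0:
        r = float(stats.pearsonr(y_true, y_pred).statistic)
        return MetricReport(pearson_r=r, r_defined=True, **report)
    return MetricReport(pearson_r=float("nan"), r_defined=False, **report)


def binomial_comparison(y_true, pred_a, pred_b) -> ComparisonResult:
    """Exact two-sided binomial head/tail test of predictor A against B.

    "Head" when |y − a| < |y − b| (strict); exact ties are removed from the
    effective count.  The two-sided p-value doubles the smaller tail
    probability of Bin(n, ½), capped at 1; an empty effective set gives p=1.
    """
    y_true = np.asarray(y_true, dtype=float).reshape(-1)
    pred_a = np.asarray(pred_a, dtype=float).reshape(-1)
    pred_b = np.asarray(pred_b, dtype=float).reshape(-1)
    if not (len(y_true) == len(pred_a) == len(pred_b)):
        raise ValueError("inputs must have equal length")
    err_a = np.abs(y_true - pred_a)
    err_b = np.abs(y_true - pred_b)
    ties = int(np.sum(err_a == err_b))
    heads = int(np.sum(err_a < err_b))
    n_eff = len(y_true) - ties
    if n_eff == 0:
        return ComparisonResult(heads=0, n_effective=0, p_value=1.0, ties_discarded=ties)
    lower = stats.binom.cdf(heads, n_eff, 0.5)
    upper = stats.binom.sf(heads - 1, n_eff, 0.5)
    p = min(1.0, 2.0 * min(float(lower), float(upper)))
    return ComparisonResult(heads=heads, n_effective=n_eff, p_value=p, ties_discarded=ties)


def classification_metrics(labels, probabilities, threshold: float = 0.5) -> ClassificationReport:
    """Confusion counts, precision/recall/F1 and accuracy at one threshold.

    `labels` are binary (1 = stabilizing); a probability ≥ threshold predicts
    the positive class.
    """
    labels = np.asarray(labels).astype(int).reshape(-1)
    probs = np.asarray(probabilities, dtype=float).reshape(-1)
    if len(labels) == 0:
        raise ValueError("empty input")
    if labels.shape != probs.shape:
        raise ValueError("labels and probabilities must have equal length")
    if np.any(probs < 0) or np.any(probs > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    pred = probs >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    accuracy = (tp + tn) / len(labels)
    return ClassificationReport(
        threshold=threshold, tp=tp, fp=fp, tn=tn, fn=fn,
        precision=precision, recall=recall, f1=f1, accuracy=accuracy,
    )


def f1_threshold_sweep(labels, probabilities, thresholds=None) -> list[ClassificationReport]:
    """F1 (and companions) over a grid of probability thresholds."""
    if thresholds is None:
        thresholds = np.linspace(0.1, 0.9, 9)
    return [classification_metrics(labels, probabilities, float(t)) for t in thresholds]


def bias_scan(
    predict_fn,
    wt_structure: Structure,
    mt_structure: Structure,
    record: MutationRecord,
    mode: str = "wt_diff",
    spacing: float = 1.0,
    orient: bool = True,
) -> BiasScanReport:
    """Prediction spread of one model over the 120 bias-scan orientations.

    Both structures are rotated rigidly by the same matrix about the
    wild-type centroid, then featurized (with or without orientation
    standardization) and passed to `predict_fn`.  Per-orientation pipeline
    failures are counted, not raised.
    """
    rotset = bias_scan_rotations()
    center = wt_structure.coords().mean(axis=0)
    preds: list[float] = []
    n_failed = 0
    for mat in rotset.matrices:
        wt_rot = rotate_structure(wt_structure, mat, center=center)
        mt_rot = rotate_structure(mt_structure, mat, center=center)
        try:
            rep = featurize_mutation(
                wt_rot, mt_rot, record, mode=mode, spacing=spacing, orient=orient
            )
            preds.append(float(predict_fn(rep)))
        except FeaturizationError:
            n_failed += 1
    predictions = np.array(preds)
    if len(predictions) == 0:
        raise ValueError("every orientation failed to featurize")
    spread = float(predictions.max() - predictions.min())
    signs = np.where(predictions >= 0, 1, -1)
    return BiasScanReport(
        predictions=predictions,
        range=spread,
        sign_consistent=bool(np.all(signs == signs[0])),
        n_failed=n_failed,
    )
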