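"""Segmentation metrics and the uncertainty score.

Two families of quantities:

* classical per-slice segmentation comparison — accuracy, sensitivity,
  specificity, 2D Dice similarity coefficient (DSC), mean Hausdorff
  distance (mHD) and 95th-percentile Hausdorff distance (HD95), aggregated
  as mean +/- SD across slices;
* the uncertainty score: for tau = 1..100, pixels with normalized
  uncertainty U < tau are kept, and the filtered DSC, the fraction of
  filtered true positives FTP_tau = (TP_100 - TP_tau) / TP_100 and the
  fraction of filtered true negatives FTN_tau are traced over tau.  The
  areas under the three curves combine into

      U-score = (AUC_1 + (1 - AUC_2) + (1 - AUC_3)) / 3 ,

  rewarding high confidence in correct predictions and low confidence in
  incorrect ones.  tau = 100 keeps every pixel, so TP_100 / TN_100 are the
  unfiltered counts and FTP_100 = FTN_100 = 0 by construction.  Filtered-out
  pixels are removed from the evaluation entirely (not reassigned to
  background).

Hausdorff distances are symmetric by pooling the directed nearest-surface
distances in both directions; mHD is the pooled mean and HD95 the pooled
95th percentile (linear interpolation), converted to cm via the pixel
spacing.  Surfaces are foreground pixels 4-adjacent to background or to the
image border.  Distances come from exact Euclidean distance transforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import binary_erosion, distance_transform_edt

from .images import BinaryMask, UncertaintyMap

__all__ = [
    "UScoreCurves",
    "UScoreReport",
    "MetricsReport",
    "SliceRecord",
    "confusion_counts",
    "dice",
    "uscore_curves",
    "uscore",
    "surface_points",
    "hausdorff",
    "evaluate_case",
]

logger = logging.getLogger(__name__)

_TAUS = np.arange(1, 101)


# ---------------------------------------------------------------------------
# reports


@dataclass
class UScoreCurves:
    thresholds: np.ndarray
    dsc_curve: np.ndarray
    ftp_curve: np.ndarray
    ftn_curve: np.ndarray
    tp_counts: np.ndarray
    tn_counts: np.ndarray
    unfiltered: tuple[int, int]
    degenerate: bool = False


@dataclass
class UScoreReport:
    auc1: float
    auc2: float
    auc3: float
    u_score: float


@dataclass
class SliceRecord:
    accuracy: float
    sensitivity: Optional[float]
    specificity: float
    dsc: float
    mhd_cm: float
    hd95_cm: float
    distance_valid: bool


@dataclass
class MetricsReport:
    per_slice: list[SliceRecord]
    aggregate: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_distance_excluded: int = 0


# ---------------------------------------------------------------------------
# overlap metrics


def _check_shapes(pred: BinaryMask, gt: BinaryMask) -> None:
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")


def confusion_counts(
    pred: BinaryMask, gt: BinaryMask, include: Optional[np.ndarray] = None
) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) over the included pixels (all pixels by default)."""
    _check_shapes(pred, gt)
    p = pred.astype_bool()
    g = gt.astype_bool()
    if include is None:
        include = np.ones(p.shape, dtype=bool)
    else:
        include = np.asarray(include, dtype=bool)
        if include.shape != p.shape:
            raise ValueError("inclusion mask shape mismatch")
    tp = int(np.sum(p & g & include))
    tn = int(np.sum(~p & ~g & include))
    fp = int(np.sum(p & ~g & include))
    fn = int(np.sum(~p & g & include))
    return tp, tn, fp, fn


def dice(
    pred: BinaryMask, gt: BinaryMask, include: Optional[np.ndarray] = None
) -> float:
    """Dice similarity coefficient 2TP / (2TP + FP + FN) over included pixels.

    When both masks are empty on the included region the DSC is 1 by
    convention (perfect agreement on absence), logged at debug level.
    """
    tp, _, fp, fn = confusion_counts(pred, gt, include)
    denom = 2 * tp + fp + fn
    if denom == 0:
        logger.debug("both masks empty on evaluated region; DSC = 1 by convention")
        return 1.0
    return 2.0 * tp / denom


# ---------------------------------------------------------------------------
# uncertainty score


def uscore_curves(
    pred: BinaryMask, gt: BinaryMask, uncertainty: UncertaintyMap
) -> UScoreCurves:
    """DSC(tau), FTP(tau), FTN(tau) for tau = 1..100.

    For tau < 100 the inclusion mask is {normalized U < tau}; tau = 100
    includes every pixel so the unfiltered TP_100 / TN_100 anchor the FTP /
    FTN ratios.  A degenerate case (no unfiltered true positives or true
    negatives) reports the affected ratio curve as zero and sets the
    ``degenerate`` flag.
    """
    _check_shapes(pred, gt)
    u = uncertainty.normalized
    if u.shape != pred.shape:
        raise ValueError("uncertainty map shape mismatch")
    dscs = np.empty(100)
    tps = np.empty(100, dtype=np.int64)
    tns = np.empty(100, dtype=np.int64)
    for i, tau in enumerate(_TAUS):
        include = None if tau == 100 else (u < tau)
        tp, tn, fp, fn = confusion_counts(pred, gt, include)
        tps[i], tns[i] = tp, tn
        denom = 2 * tp + fp + fn
        dscs[i] = 1.0 if denom == 0 else 2.0 * tp / denom
    tp100, tn100 = int(tps[-1]), int(tns[-1])
    degenerate = False
    if tp100 > 0:
        ftp = (tp100 - tps) / tp100
    else:
        logger.warning("no unfiltered true positives; FTP curve reported as 0")
        ftp = np.zeros(100)
        degenerate = True
    if tn100 > 0:
        ftn = (tn100 - tns) / tn100
    else:
        logger.warning("no unfiltered true negatives; FTN curve reported as 0")
        ftn = np.zeros(100)
        degenerate = True
    return UScoreCurves(
        thresholds=_TAUS.copy(),
        dsc_curve=dscs,
        ftp_curve=ftp,
        ftn_curve=ftn,
        tp_counts=tps,
        tn_counts=tns,
        unfiltered=(tp100, tn100),
        degenerate=degenerate,
    )


def uscore(curves: UScoreCurves) -> UScoreReport:
    """Trapezoidal AUCs of the three curves over tau rescaled to [0, 1], and

        U-score = (AUC_1 + (1 - AUC_2) + (1 - AUC_3)) / 3 .
    """
    x = (curves.thresholds - 1) / 99.0
    auc1 = float(np.trapezoid(curves.dsc_curve, x))
    auc2 = float(np.trapezoid(curves.ftp_curve, x))
    auc3 = float(np.trapezoid(curves.ftn_curve, x))
    u = (auc1 + (1.0 - auc2) + (1.0 - auc3)) / 3.0
    return UScoreReport(auc1=auc1, auc2=auc2, auc3=auc3, u_score=u)


# ---------------------------------------------------------------------------
# surface distances

_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def surface_points(mask: BinaryMask) -> np.ndarray:
    """(n, 2) coordinates of foreground pixels 4-adjacent to background or to
    the image border; empty array for an empty mask."""
    m = mask.astype_bool()
    if not m.any():
        return np.empty((0, 2), dtype=np.int64)
    interior = binary_erosion(m, structure=_CROSS, border_value=0)
    surf = m & ~interior
    return np.argwhere(surf)


def hausdorff(pred: BinaryMask, gt: BinaryMask) -> tuple[float, float, bool]:
    """(mHD, HD95) in cm between the two mask surfaces, plus a validity flag.

    Pools the directed nearest-surface distances pred->gt and gt->pred;
    mHD is the pooled mean, HD95 the pooled 95th percentile (linear
    interpolation).  Pixel distances scale by the pixel spacing (mm) and are
    reported in cm.  If either mask is empty the distances are infinite and
    the flag is False; such slices are excluded from aggregates.
    """
    _check_shapes(pred, gt)
    sp = surface_points(pred)
    sg = surface_points(gt)
    if len(sp) == 0 or len(sg) == 0:
        return float("inf"), float("inf"), False
    shape = pred.shape

    def _dist_to(points: np.ndarray) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[points[:, 0], points[:, 1]] = True
        return distance_transform_edt(~m)

    d_to_gt = _dist_to(sg)
    d_to_pred = _dist_to(sp)
    pooled = np.concatenate([d_to_gt[sp[:, 0], sp[:, 1]], d_to_pred[sg[:, 0], sg[:, 1]]])
    spacing_cm = pred.pixel_spacing / 10.0
    mhd = float(pooled.mean() * spacing_cm)
    hd95 = float(np.percentile(pooled, 95) * spacing_cm)
    return mhd, hd95, True


# ---------------------------------------------------------------------------
# case evaluation


def _evaluate_slice(pred: BinaryMask, gt: BinaryMask) -> SliceRecord:
    tp, tn, fp, fn = confusion_counts(pred, gt)
    total = tp + tn + fp + fn
    accuracy = (tp + tn) / total
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else None
    specificity = tn / (tn + fp) if (tn + fp) > 0 else 1.0
    d = dice(pred, gt)
    mhd, hd95, valid = hausdorff(pred, gt)
    return SliceRecord(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        dsc=d,
        mhd_cm=mhd,
        hd95_cm=hd95,
        distance_valid=valid,
    )


def evaluate_case(
    preds: BinaryMask | Sequence[BinaryMask],
    gts: BinaryMask | Sequence[BinaryMask],
    uncertainties: UncertaintyMap | Sequence[UncertaintyMap] | None = None,
) -> tuple[MetricsReport, Optional[UScoreReport]]:
    """Per-slice metrics and mean +/- SD aggregates; optionally the U-score.

    Slices with an empty ground truth have undefined sensitivity (recorded
    as missing and excluded from the sensitivity aggregate); slices with an
    empty mask on either side are excluded from the distance aggregates with
    a logged count.  When uncertainty maps are given, the U-score is computed
    per slice and averaged (as are its AUC components).
    """
    if isinstance(preds, BinaryMask):
        preds = [preds]
    if isinstance(gts, BinaryMask):
        gts = [gts]
    if uncertainties is not None and isinstance(uncertainties, UncertaintyMap):
        uncertainties = [uncertainties]
    if len(preds) != len(gts):
        raise ValueError("number of predictions and ground truths differ")
    records = [_evaluate_slice(p, g) for p, g in zip(preds, gts)]
    n_excluded = sum(1 for r in records if not r.distance_valid)
    if n_excluded:
        logger.info("%d slice(s) excluded from distance aggregates (empty mask)", n_excluded)

    def agg(vals):
        arr = np.asarray(vals, dtype=np.float64)
        if arr.size == 0:
            return (float("nan"), float("nan"))
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return (float(arr.mean()), sd)

    aggregate = {
        "accuracy": agg([r.accuracy for r in records]),
        "sensitivity": agg([r.sensitivity for r in records if r.sensitivity is not None]),
        "specificity": agg([r.specificity for r in records]),
        "dsc": agg([r.dsc for r in records]),
        "mhd_cm": agg([r.mhd_cm for r in records if r.distance_valid]),
        "hd95_cm": agg([r.hd95_cm for r in records if r.distance_valid]),
    }
    report = MetricsReport(per_slice=records, aggregate=aggregate, n_distance_excluded=n_excluded)

    uscore_report = None
    if uncertainties is not None:
        if len(uncertainties) != len(preds):
            raise ValueError("number of uncertainty maps and predictions differ")
        per_slice_scores = [
            uscore(uscore_curves(p, g, u))
            for p, g, u in zip(preds, gts, uncertainties)
        ]
        u_vals = [s.u_score for s in per_slice_scores]
        uscore_report = UScoreReport(
            auc1=float(np.mean([s.auc1 for s in per_slice_scores])),
            auc2=float(np.mean([s.auc2 for s in per_slice_scores])),
            auc3=float(np.mean([s.auc3 for s in per_slice_scores])),
            u_score=float(np.mean(u_vals)),
        )
    return report, uscore_report
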