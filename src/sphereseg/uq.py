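"""Ensemble aggregation and pixel-wise uncertainty quantification.

The k backward-projected probability maps are aggregated two ways:

* a final binary mask — the pixel-wise ensemble mean, thresholded by a
  global Otsu threshold computed on that mean map;
* an uncertainty map — per pixel, the Shannon entropy (nats) of the
  discretized ensemble votes, normalized onto [0, 100] by its fixed
  theoretical maximum so filtering thresholds are comparable across slices.

Raw ensemble probabilities are continuous, so counting literally unique
values would be degenerate (every member distinct almost surely).  The
default discretization ``value_bins=2`` binarizes each member at 0.5 before
counting, giving the interpretable "fraction of members voting tumor"
entropy; finer histogram discretizations are available via ``value_bins``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .images import BinaryMask, PlanarImage, ProbabilityStack, UncertaintyMap

__all__ = [
    "OtsuThreshold",
    "DegenerateMapError",
    "otsu_threshold",
    "stack_mean",
    "binarize_ensemble",
    "entropy_map",
    "normalize_uncertainty",
]

logger = logging.getLogger(__name__)


class DegenerateMapError(ValueError):
    """Raised when a map is constant and no threshold separates two classes."""


@dataclass(frozen=True)
class OtsuThreshold:
    """A global probability threshold T maximizing between-class variance."""

    value: float
    histogram_bins: int
    source: str = "mean_map"


def stack_mean(stack: ProbabilityStack) -> PlanarImage:
    """Pixel-wise mean of the k ensemble probability maps."""
    return PlanarImage(pixels=stack.maps.mean(axis=0))


def otsu_threshold(map_: PlanarImage | np.ndarray, bins: int = 256) -> OtsuThreshold:
    """Otsu's global threshold over a ``bins``-bin histogram of the map.

    Maximizes between-class variance; ties break toward the lower threshold.
    A constant map carries no class structure and raises
    :class:`DegenerateMapError` — callers map that to an all-background mask.
    """
    arr = map_.pixels if isinstance(map_, PlanarImage) else np.asarray(map_)
    if np.unique(arr).size < 2:
        raise DegenerateMapError("map is constant; no threshold separates two classes")
    value = float(threshold_otsu(arr, nbins=bins))
    return OtsuThreshold(value=value, histogram_bins=bins)


def binarize_ensemble(
    stack: ProbabilityStack, bins: int = 256
) -> tuple[BinaryMask, OtsuThreshold]:
    """Final segmentation: mean map thresholded at its own Otsu threshold T.

    A pixel is foreground iff its ensemble-mean probability strictly exceeds
    T.  Returns the threshold alongside the mask for auditability.  A
    degenerate (constant) mean map yields an all-background mask — no tumor
    evidence — with a logged warning.
    """
    mean = stack_mean(stack)
    try:
        thr = otsu_threshold(mean, bins=bins)
    except DegenerateMapError:
        logger.warning("constant ensemble mean; emitting all-background mask")
        thr = OtsuThreshold(value=float(mean.pixels.flat[0]), histogram_bins=bins)
        return BinaryMask(np.zeros(mean.pixels.shape, dtype=np.uint8)), thr
    mask = (mean.pixels > thr.value).astype(np.uint8)
    return BinaryMask(mask), thr


def _discretize(maps: np.ndarray, value_bins: int) -> np.ndarray:
    """Assign each probability to one of ``value_bins`` equal bins on [0, 1].

    With the default 2 bins this is binarization at 0.5.
    """
    classes = np.floor(maps * value_bins).astype(np.int64)
    return np.clip(classes, 0, value_bins - 1)


def entropy_map(stack: ProbabilityStack, value_bins: int = 2) -> UncertaintyMap:
    """Pixel-wise Shannon entropy (nats) of the discretized ensemble votes.

    Per pixel the k member probabilities are discretized into ``value_bins``
    classes; with empirical class frequencies p_v over the k members,

        U(i, j) = -sum_v p_v ln p_v ,

    zero when the members agree unanimously and at most
    ``ln(min(k, value_bins))``.  The returned map also carries the 0-100
    normalized form (see :func:`normalize_uncertainty`).
    """
    if value_bins < 2:
        raise ValueError("value_bins must be >= 2")
    maps = stack.maps
    k = stack.k
    classes = _discretize(maps, value_bins)
    counts = np.stack([(classes == v).sum(axis=0) for v in range(value_bins)])
    p = counts / float(k)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    entropy = -terms.sum(axis=0)
    entropy = np.maximum(entropy, 0.0)  # clip -0.0 / rounding
    u = UncertaintyMap(
        entropy=entropy,
        normalized=np.zeros_like(entropy),
        value_bins=value_bins,
        support=k,
    )
    return normalize_uncertainty(u)


def normalize_uncertainty(map_: UncertaintyMap) -> UncertaintyMap:
    """Rescale entropy onto [0, 100] by the fixed theoretical maximum
    ``ln(min(k, value_bins))`` (not per-slice min-max), so a filtering
    threshold tau means the same across slices and cases."""
    max_h = map_.max_entropy
    if max_h <= 0:
        normalized = np.zeros_like(map_.entropy)
    else:
        normalized = 100.0 * map_.entropy / max_h
    normalized = np.clip(normalized, 0.0, 100.0)
    return UncertaintyMap(
        entropy=map_.entropy,
        normalized=normalized,
        value_bins=map_.value_bins,
        support=map_.support,
    )
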