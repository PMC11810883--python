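"""Lightweight array containers shared across the pipeline.

All containers wrap plain ``numpy`` arrays and validate the invariants the
pipeline relies on (finiteness, value ranges, shape agreement).  They are
deliberately thin: every algorithm in this package operates on the ``.pixels``
/ ``.maps`` arrays directly.

Conventions: 0-based pixel-center coordinates in ``(row, col)`` order; planar
images are ``(rows, cols)`` or ``(rows, cols, channels)`` with channels last.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Any, Optional

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .geometry import ProjectionCenter, ProjectionCenterSet, ProjectionGeometry

__all__ = [
    "PlanarImage",
    "SphericalImage",
    "BinaryMask",
    "ProbabilityStack",
    "UncertaintyMap",
]


def _check_finite(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")


@dataclass
class PlanarImage:
    """A 2D slice, single- or two-channel, on the planar (Cartesian) grid.

    Parameters
    ----------
    pixels
        ``(rows, cols)`` or ``(rows, cols, channels)`` float array with
        channels in {1, 2}.
    pixel_spacing
        In-plane resolution in mm per pixel (default 1.0, matching
        1x1 mm resampled MRI).
    """

    pixels: np.ndarray
    pixel_spacing: float = 1.0
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("PlanarImage expects a 2D or 3D (H, W, C) array")
        if self.pixels.ndim == 3 and self.pixels.shape[2] not in (1, 2):
            raise ValueError("PlanarImage supports 1 or 2 channels")
        _check_finite(self.pixels, "PlanarImage.pixels")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    def channel(self, idx: int) -> np.ndarray:
        if self.pixels.ndim == 2:
            if idx != 0:
                raise IndexError("single-channel image")
            return self.pixels
        return self.pixels[..., idx]


@dataclass
class SphericalImage:
    """A planar image resampled onto the spherical patch grid.

    Carries the :class:`~sphereseg.geometry.ProjectionGeometry` and
    :class:`~sphereseg.geometry.ProjectionCenter` it was produced with, which
    the backward projection requires.
    """

    pixels: np.ndarray
    center: "ProjectionCenter"
    geometry: "ProjectionGeometry"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("SphericalImage expects a 2D or 3D array")
        _check_finite(self.pixels, "SphericalImage.pixels")
        s = self.geometry.spherical_grid_size
        if self.pixels.shape[:2] != (s, s):
            raise ValueError(
                f"spherical image shape {self.pixels.shape[:2]} does not match "
                f"geometry.spherical_grid_size={s}"
            )

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]


@dataclass
class BinaryMask:
    """A strictly binary segmentation mask on the planar grid."""

    pixels: np.ndarray
    pixel_spacing: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError("BinaryMask expects a 2D array")
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("BinaryMask values must be in {0, 1}")
        self.pixels = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def astype_bool(self) -> np.ndarray:
        return self.pixels.astype(bool)


@dataclass
class ProbabilityStack:
    """The k per-pixel tumor-probability maps of an ensemble, co-registered
    on the planar grid.

    ``centers`` is the projection-center set that produced the stack for the
    spherical-projection ensemble; test-time-augmentation stacks carry
    ``centers=None``.
    """

    maps: np.ndarray
    centers: Optional["ProjectionCenterSet"] = None
    source_image_id: str = ""

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float64)
        if self.maps.ndim != 3:
            raise ValueError("ProbabilityStack expects a (k, rows, cols) array")
        if self.maps.shape[0] < 1:
            raise ValueError("ProbabilityStack must contain at least one map")
        _check_finite(self.maps, "ProbabilityStack.maps")
        if self.maps.min() < 0 or self.maps.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.centers is not None and self.centers.count != self.maps.shape[0]:
            raise ValueError("stack size does not match number of centers")

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.maps.shape[1:]  # type: ignore[return-value]


@dataclass
class UncertaintyMap:
    """Pixel-wise ensemble-disagreement entropy, plus its 0-100 normalization.

    ``entropy`` is Shannon entropy in nats of the discretized per-pixel
    ensemble votes; ``normalized`` rescales it by the fixed theoretical
    maximum ``ln(min(k, value_bins))`` onto [0, 100] so that filtering
    thresholds are comparable across slices.
    """

    entropy: np.ndarray
    normalized: np.ndarray
    value_bins: int
    support: int

    def __post_init__(self) -> None:
        self.entropy = np.asarray(self.entropy, dtype=np.float64)
        self.normalized = np.asarray(self.normalized, dtype=np.float64)
        if self.entropy.shape != self.normalized.shape:
            raise ValueError("entropy and normalized shapes differ")
        if self.entropy.min() < 0:
            raise ValueError("entropy must be non-negative")
        if self.normalized.min() < -1e-9 or self.normalized.max() > 100 + 1e-9:
            raise ValueError("normalized uncertainty must lie in [0, 100]")

    @property
    def max_entropy(self) -> float:
        return float(np.log(min(self.support, self.value_bins)))
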