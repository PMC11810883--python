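"""NIfTI slice I/O, intensity standardization, and overlay rendering.

Volumes are processed slice-wise: a 2D NIfTI is one slice, a 3D NIfTI is a
stack of slices along the last axis, and a 4D NIfTI carries channels on the
fourth axis (1 or 2 channels).  Intensities are standardized per slice and
per channel to zero mean / unit variance before segmentation; masks are
written as uint8 and uncertainty maps as float32, with the source affine
and spacing preserved.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

from .images import BinaryMask, PlanarImage, UncertaintyMap

__all__ = [
    "read_slices",
    "write_slices",
    "write_mask",
    "write_uncertainty",
    "standardize",
    "save_overlay",
]


def standardize(image: PlanarImage) -> PlanarImage:
    """Per-slice, per-channel z-score standardization."""
    arr = image.pixels.astype(np.float64).copy()
    if arr.ndim == 2:
        arr = (arr - arr.mean()) / (arr.std() + 1e-8)
    else:
        for c in range(arr.shape[2]):
            ch = arr[..., c]
            arr[..., c] = (ch - ch.mean()) / (ch.std() + 1e-8)
    return PlanarImage(pixels=arr, pixel_spacing=image.pixel_spacing, metadata=dict(image.metadata))


def _spacing_from(img: nib.Nifti1Image) -> float:
    zooms = img.header.get_zooms()
    return float(zooms[0]) if len(zooms) else 1.0


def read_slices(path: str | Path) -> tuple[list[PlanarImage], np.ndarray]:
    """Read a NIfTI file as a list of planar slices plus the affine.

    Accepts 2D (one slice), 3D (slices along the last axis) and 4D
    (rows x cols x slices x channels) images with 1 or 2 channels.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: non-finite voxels")
    spacing = _spacing_from(img)
    if data.ndim == 2:
        slices = [data]
    elif data.ndim == 3:
        slices = [data[..., i] for i in range(data.shape[2])]
    elif data.ndim == 4:
        if data.shape[3] not in (1, 2):
            raise ValueError(f"{path}: expected 1 or 2 channels, got {data.shape[3]}")
        slices = [data[:, :, i, :] for i in range(data.shape[2])]
    else:
        raise ValueError(f"{path}: unsupported dimensionality {data.ndim}")
    return [PlanarImage(pixels=s, pixel_spacing=spacing) for s in slices], img.affine


def _stack(slices: Sequence[np.ndarray]) -> np.ndarray:
    return slices[0] if len(slices) == 1 else np.stack(slices, axis=2)


def write_slices(
    path: str | Path, slices: Sequence[PlanarImage], affine: np.ndarray | None = None
) -> None:
    arrs = [s.pixels for s in slices]
    if arrs[0].ndim == 3:  # channels-last slices become 4D: H x W x slices x C
        data = np.stack(arrs, axis=2).astype(np.float32)
    else:
        data = _stack(arrs).astype(np.float32)
    nib.save(nib.Nifti1Image(data, affine if affine is not None else np.eye(4)), str(path))


def write_mask(
    path: str | Path, masks: BinaryMask | Sequence[BinaryMask], affine: np.ndarray | None = None
) -> None:
    if isinstance(masks, BinaryMask):
        masks = [masks]
    data = _stack([m.pixels for m in masks]).astype(np.uint8)
    nib.save(nib.Nifti1Image(data, affine if affine is not None else np.eye(4)), str(path))


def write_uncertainty(
    path: str | Path,
    maps: UncertaintyMap | Sequence[UncertaintyMap],
    affine: np.ndarray | None = None,
) -> None:
    if isinstance(maps, UncertaintyMap):
        maps = [maps]
    data = _stack([m.normalized for m in maps]).astype(np.float32)
    nib.save(nib.Nifti1Image(data, affine if affine is not None else np.eye(4)), str(path))


def save_overlay(
    path: str | Path,
    image: PlanarImage,
    mask: BinaryMask | None = None,
    uncertainty: UncertaintyMap | None = None,
    gt: BinaryMask | None = None,
) -> None:
    """PNG overlay: grayscale slice, mask contour, uncertainty heatmap."""
    from matplotlib.figure import Figure

    base = image.channel(image.n_channels - 1)
    fig = Figure(figsize=(5, 5))
    ax = fig.add_subplot(111)
    ax.imshow(base, cmap="gray", interpolation="nearest")
    if uncertainty is not None:
        ax.imshow(uncertainty.normalized, cmap="inferno", alpha=0.35, vmin=0, vmax=100)
    if mask is not None and mask.pixels.any():
        ax.contour(mask.pixels, levels=[0.5], colors="cyan", linewidths=1.0)
    if gt is not None and gt.pixels.any():
        ax.contour(gt.pixels, levels=[0.5], colors="lime", linewidths=1.0)
    ax.set_axis_off()
    fig.savefig(str(path), bbox_inches="tight", dpi=120)
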