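"""Spherical projection of planar image slices and its inverse.

The nonlinear transform at the core of the ensemble: a planar image is
projected radially onto a sphere and the spherical patch is laid out on a
Cartesian grid, which magnifies the neighborhood of a configurable
*projection center* while keeping the whole field of view.

Geometry
--------
The sphere has center ``O`` and radius ``r``; the image plane sits orthogonal
to the pole axis at distance ``d`` from ``O`` (``d < r``) and spans
``[-h, h]^2`` in dimensionless sphere units.  A planar point at in-plane
radial offset ``rho`` from the pole axis is projected along the ray from
``O`` through the point, reaching the sphere at polar angle

    theta(rho) = arctan(rho / d),        dtheta/drho = d / (d^2 + rho^2).

The spherical patch is re-parameterized onto a square grid by
azimuthal-equidistant coordinates about the pole axis: grid radius
proportional to ``theta``, grid angle equal to the azimuth ``phi``.  The
radial grid scale is anchored so that ``theta(h)`` (the plane's edge
midpoint) maps to the inscribed-circle radius of the spherical grid; plane
corners then still land inside the square grid.

Because ``dtheta/drho`` is maximal at ``rho = 0``, local scale is maximal at
the projection center and falls off monotonically with planar distance from
it — the documented magnification behavior.  Varying the projection center
is implemented by translating the planar sampling window so the chosen
center lies on the pole axis; samples falling outside the source image take
a constant fill value.

Both resampling directions use :func:`scipy.ndimage.map_coordinates`;
intensities default to bilinear interpolation and binary masks should use
``order=0`` (nearest neighbor) so they stay binary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .images import PlanarImage, SphericalImage

__all__ = [
    "ProjectionGeometry",
    "ProjectionCenter",
    "ProjectionCenterSet",
    "forward_project",
    "backward_project",
    "make_center_grid",
    "local_scale_map",
    "polar_angle",
]


@dataclass(frozen=True)
class ProjectionGeometry:
    """Sphere/plane configuration governing the projection.

    Parameters
    ----------
    plane_half_width
        Half-extent ``h`` of the planar image in sphere units.
    sphere_radius
        Sphere radius ``r`` (must exceed ``plane_distance``).
    plane_distance
        Distance ``d`` from the sphere center to the image plane.
    spherical_grid_size
        Pixels per side of the spherical (projected) image.
    planar_grid_size
        Pixels per side of the planar input.
    interpolation_order
        Spline order for intensity resampling (0 = nearest, 1 = bilinear).
    fill_value
        Value assumed outside the source image domain.

    The default ``(h, r, d) = (0.5, 1.0, 0.3)`` is the design with the least
    round-trip SSIM degradation.
    """

    plane_half_width: float = 0.5
    sphere_radius: float = 1.0
    plane_distance: float = 0.3
    spherical_grid_size: int = 256
    planar_grid_size: int = 192
    interpolation_order: int = 1
    fill_value: float = 0.0

    def __post_init__(self) -> None:
        if self.plane_half_width <= 0 or self.sphere_radius <= 0 or self.plane_distance <= 0:
            raise ValueError("h, r and d must all be positive")
        if self.plane_distance >= self.sphere_radius:
            raise ValueError(
                "plane_distance must be smaller than sphere_radius so radial "
                "rays from the center exit through the sphere surface"
            )
        if self.spherical_grid_size < 2 or self.planar_grid_size < 2:
            raise ValueError("grid sizes must be at least 2")
        if self.interpolation_order < 0:
            raise ValueError("interpolation_order must be >= 0")

    # -- derived quantities -------------------------------------------------

    @property
    def units_per_pixel(self) -> float:
        """Sphere units per planar pixel (plane spans [-h, h] over the grid)."""
        return 2.0 * self.plane_half_width / self.planar_grid_size

    @property
    def theta_max(self) -> float:
        """Polar angle of the plane's edge midpoint, the radial grid anchor."""
        return math.atan2(self.plane_half_width, self.plane_distance)

    @property
    def pixels_per_radian(self) -> float:
        """Radial scale of the azimuthal-equidistant spherical grid."""
        return ((self.spherical_grid_size - 1) / 2.0) / self.theta_max


@dataclass(frozen=True)
class ProjectionCenter:
    """Continuous planar pixel coordinate magnified by the projection."""

    row: float
    col: float

    def validate(self, planar_grid_size: int) -> None:
        if not (0 <= self.row < planar_grid_size and 0 <= self.col < planar_grid_size):
            raise ValueError(
                f"projection center ({self.row}, {self.col}) lies outside the "
                f"{planar_grid_size}x{planar_grid_size} image"
            )


@dataclass(frozen=True)
class ProjectionCenterSet:
    """An ordered set of projection centers defining the ensemble."""

    centers: tuple[ProjectionCenter, ...]

    def __init__(self, centers: Sequence[ProjectionCenter]):
        centers = tuple(centers)
        if len(centers) < 1:
            raise ValueError("at least one projection center is required")
        if len({(c.row, c.col) for c in centers}) != len(centers):
            raise ValueError("projection centers must be distinct")
        object.__setattr__(self, "centers", centers)

    @property
    def count(self) -> int:
        return len(self.centers)

    def __iter__(self):
        return iter(self.centers)

    def __getitem__(self, idx: int) -> ProjectionCenter:
        return self.centers[idx]


def polar_angle(rho: np.ndarray | float, geometry: ProjectionGeometry) -> np.ndarray | float:
    """Polar angle theta of a planar point at radial offset ``rho`` (sphere
    units) from the pole axis: ``theta = arctan(rho / d)``.

    This is the planar->angular radial map whose derivative
    ``d/(d^2 + rho^2)`` governs the locoregional magnification.
    """
    return np.arctan2(rho, geometry.plane_distance)


def _planar_sample_coords(
    geometry: ProjectionGeometry, center: ProjectionCenter
) -> tuple[np.ndarray, np.ndarray]:
    """Planar (row, col) sampling coordinates for every spherical grid pixel."""
    s = geometry.spherical_grid_size
    c = (s - 1) / 2.0
    ax = np.arange(s, dtype=np.float64)
    ya, xb = np.meshgrid(ax - c, ax - c, indexing="ij")
    grid_r = np.hypot(ya, xb)
    theta = grid_r / geometry.pixels_per_radian
    # Rays at theta >= pi/2 run parallel to / away from the plane.
    valid = theta < (math.pi / 2 - 1e-6)
    rho = geometry.plane_distance * np.tan(np.minimum(theta, math.pi / 2 - 1e-6))
    scale = np.where(grid_r > 0, rho / np.where(grid_r > 0, grid_r, 1.0), 0.0)
    du = geometry.units_per_pixel
    rows = center.row + ya * scale / du
    cols = center.col + xb * scale / du
    rows = np.where(valid, rows, -1e6)  # force fill value outside the domain
    cols = np.where(valid, cols, -1e6)
    return rows, cols


def _spherical_sample_coords(
    geometry: ProjectionGeometry, center: ProjectionCenter
) -> tuple[np.ndarray, np.ndarray]:
    """Spherical-grid (row, col) sampling coordinates for every planar pixel."""
    n = geometry.planar_grid_size
    ax = np.arange(n, dtype=np.float64)
    ri, cj = np.meshgrid(ax - center.row, ax - center.col, indexing="ij")
    du = geometry.units_per_pixel
    u = ri * du
    v = cj * du
    rho = np.hypot(u, v)
    theta = np.arctan2(rho, geometry.plane_distance)
    grid_r = theta * geometry.pixels_per_radian
    with np.errstate(invalid="ignore"):
        scale = np.where(rho > 0, grid_r / np.where(rho > 0, rho, 1.0), 0.0)
    c = (geometry.spherical_grid_size - 1) / 2.0
    rows = c + u * scale / 1.0
    cols = c + v * scale / 1.0
    return rows, cols


def _resample(
    pixels: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    order: int,
    fill_value: float,
) -> np.ndarray:
    """Channel-wise map_coordinates with constant fill outside the domain."""
    coords = np.stack([rows, cols])
    if pixels.ndim == 2:
        return map_coordinates(pixels, coords, order=order, mode="constant", cval=fill_value)
    out = [
        map_coordinates(pixels[..., c], coords, order=order, mode="constant", cval=fill_value)
        for c in range(pixels.shape[2])
    ]
    return np.stack(out, axis=-1)


def forward_project(
    image: PlanarImage,
    geometry: ProjectionGeometry,
    center: ProjectionCenter,
    order: int | None = None,
) -> SphericalImage:
    """Project a planar image onto the sphere and lay the patch out on a
    regular ``spherical_grid_size``-square Cartesian grid.

    Local scale is maximal at ``center`` and decreases monotonically with
    planar distance from it.  Samples outside the source image take
    ``geometry.fill_value``; intensities are interpolated, never
    extrapolated.

    Parameters
    ----------
    order
        Override of ``geometry.interpolation_order`` (use 0 for masks).
    """
    n = geometry.planar_grid_size
    if image.pixels.shape[0] != n or image.pixels.shape[1] != n:
        raise ValueError(
            f"image shape {image.pixels.shape[:2]} does not match "
            f"planar_grid_size={n}; standardize the input first"
        )
    center.validate(n)
    rows, cols = _planar_sample_coords(geometry, center)
    if order is None:
        order = geometry.interpolation_order
    out = _resample(image.pixels, rows, cols, order, geometry.fill_value)
    return SphericalImage(pixels=out, center=center, geometry=geometry)


def backward_project(spherical: SphericalImage, order: int | None = None) -> PlanarImage:
    """Resample a spherical image back onto the planar grid.

    Exact inverse of the :func:`forward_project` coordinate map, up to
    interpolation error; requires the geometry/center metadata the forward
    projection attached.
    """
    geometry = spherical.geometry
    center = spherical.center
    if geometry is None or center is None:
        raise ValueError("spherical image is missing geometry/center metadata")
    rows, cols = _spherical_sample_coords(geometry, center)
    if order is None:
        order = geometry.interpolation_order
    out = _resample(spherical.pixels, rows, cols, order, geometry.fill_value)
    return PlanarImage(pixels=out)


def make_center_grid(
    planar_grid_size: int,
    count: int,
    extent_fraction: float = 0.5,
) -> ProjectionCenterSet:
    """A uniform sqrt(count) x sqrt(count) lattice of projection centers,
    symmetric about the image center.

    ``extent_fraction`` is the fraction of the image side the lattice spans;
    ``count=1`` returns the image center itself.
    """
    if not (0 < extent_fraction <= 1):
        raise ValueError("extent_fraction must lie in (0, 1]")
    c = (planar_grid_size - 1) / 2.0
    if count == 1:
        return ProjectionCenterSet([ProjectionCenter(c, c)])
    m = math.isqrt(count)
    if m * m != count:
        lo, hi = m * m, (m + 1) * (m + 1)
        nearest = lo if count - lo <= hi - count else hi
        raise ValueError(
            f"count={count} is not a perfect square; the centers form a "
            f"square lattice (nearest square: {nearest})"
        )
    half_span = extent_fraction * (planar_grid_size - 1) / 2.0
    offsets = np.linspace(-half_span, half_span, m)
    centers = [ProjectionCenter(c + dr, c + dc) for dr in offsets for dc in offsets]
    return ProjectionCenterSet(centers)


def local_scale_map(
    geometry: ProjectionGeometry, center: ProjectionCenter
) -> PlanarImage:
    """Per-pixel magnification: |Jacobian determinant| of the planar->spherical
    coordinate map, in (spherical px / planar px)^2.

    In polar coordinates about the projection center the map sends
    ``(rho, phi) -> (S(theta(rho)), phi)`` with ``S = pixels_per_radian *
    theta``; its Jacobian determinant is the product of the radial stretch
    ``S'(rho)`` and the tangential stretch ``S(rho)/rho``.  Strictly positive
    and maximal at the center.
    """
    center.validate(geometry.planar_grid_size)
    n = geometry.planar_grid_size
    ax = np.arange(n, dtype=np.float64)
    ri, cj = np.meshgrid(ax - center.row, ax - center.col, indexing="ij")
    du = geometry.units_per_pixel
    rho = np.hypot(ri * du, cj * du)
    d = geometry.plane_distance
    k = geometry.pixels_per_radian
    radial = k * d / (d * d + rho * rho)  # dS/drho
    theta = np.arctan2(rho, d)
    # Tangential stretch S/rho -> k/d as rho -> 0 (l'Hopital).
    tangential = np.where(rho > 1e-12, k * theta / np.where(rho > 1e-12, rho, 1.0), k / d)
    jac = radial * tangential * du * du
    return PlanarImage(pixels=jac)
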