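"""Parametric active contour (snake) evolution and mask assembly.

A closed contour C(s) = (x(s), y(s)) evolves to balance internal
elasticity/rigidity forces against an external force field, i.e. toward
a solution of the Euler equation

    α C''(s) − β C''''(s) + V(C(s)) = 0,

where V is a precomputed external field (GVF or the improved field of
:mod:`spicseg.edge_forces`) standing in for −∇E_out.  The discretization
is the standard semi-implicit scheme: internal forces enter through a
cyclic pentadiagonal matrix solved implicitly each step, the external
force is evaluated explicitly by bilinear interpolation, and the contour
is resampled to uniform arc length after every step so that points do
not bunch up and stall in concavities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from scipy.linalg import lu_factor, lu_solve
from scipy.ndimage import map_coordinates
from shapely.geometry import Polygon

from .edge_forces import ForceField
from .imaging_io import ImageStack, Mask2D

__all__ = [
    "Contour",
    "SnakeParams",
    "ContourCollapseError",
    "init_circle",
    "evolve",
    "contour_to_mask",
    "segment_slice",
    "segment_volume",
    "polygon_area",
]

_MIN_POINTS = 8
_TARGET_SPACING = 1.0  # px; resampling keeps spacing within [0.5, 2.0]


class ContourCollapseError(RuntimeError):
    """Raised when the evolving contour's area drops below 1 px²."""


@dataclass(frozen=True)
class Contour:
    """Closed polygonal contour; points are (row, col) in cyclic order."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < _MIN_POINTS:
            raise ValueError(
                f"Contour requires an (n>={_MIN_POINTS}, 2) point array, got {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise ValueError("Contour points must be finite")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def closed(self) -> bool:
        return True

    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def area(self) -> float:
        return polygon_area(self.points)


@dataclass(frozen=True)
class SnakeParams:
    alpha: float = 0.1  # elasticity weight
    beta: float = 0.05  # rigidity weight
    dt: float = 1.0
    max_iter: int = 300
    move_tol: float = 0.01  # mean point displacement (px) stopping threshold
    ext_weight: float = 2.0  # gain on the external force field

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.dt <= 0 or self.move_tol <= 0 or self.max_iter < 1:
            raise ValueError("dt, move_tol must be > 0 and max_iter >= 1")
        if self.ext_weight < 0:
            raise ValueError("ext_weight must be >= 0")


def polygon_area(points: np.ndarray) -> float:
    """Unsigned shoelace area of a closed (row, col) polygon."""
    r, c = points[:, 0], points[:, 1]
    return float(abs(np.dot(c, np.roll(r, -1)) - np.dot(r, np.roll(c, -1))) / 2.0)


def init_circle(center: tuple[float, float], radius: float, n_points: int = 64) -> Contour:
    """Uniformly sampled circle; the first point sits at (row, col + radius)."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if n_points < _MIN_POINTS:
        raise ValueError(f"n_points must be >= {_MIN_POINTS}")
    t = 2.0 * np.pi * np.arange(n_points) / n_points
    rows = center[0] + radius * np.sin(t)
    cols = center[1] + radius * np.cos(t)
    return Contour(np.column_stack([rows, cols]))


def _resample(points: np.ndarray, n_points: int | None = None) -> np.ndarray:
    """Resample a closed polygon to uniform arc length.

    Keeps the point count unless the resulting spacing would leave
    [0.5, 2.0] px, in which case the count is retargeted to ~1 px
    spacing (never below the 8-point minimum).
    """
    closed = np.vstack([points, points[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    perim = seg.sum()
    if perim <= 0:
        return points
    n = n_points if n_points is not None else points.shape[0]
    if not (0.5 <= perim / n <= 2.0):
        n = max(_MIN_POINTS, int(round(perim / _TARGET_SPACING)))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = perim * np.arange(n) / n
    rows = np.interp(targets, cum, closed[:, 0])
    cols = np.interp(targets, cum, closed[:, 1])
    return np.column_stack([rows, cols])


def _internal_matrix(n: int, alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Cyclic pentadiagonal matrix gamma*I + A for the implicit solve."""
    a = np.zeros(n)
    a[0] = gamma + 2.0 * alpha + 6.0 * beta
    if n >= 2:
        a[1] = a[-1] = -(alpha + 4.0 * beta)
    if n >= 3:
        a[2] = a[-2] = beta
    mat = np.empty((n, n))
    for i in range(n):
        mat[i] = np.roll(a, i)
    return mat


def _external_force(field: ForceField, points: np.ndarray) -> np.ndarray:
    coords = [points[:, 0], points[:, 1]]  # (row, col)
    fu = map_coordinates(field.u, coords, order=1, mode="nearest")
    fv = map_coordinates(field.v, coords, order=1, mode="nearest")
    # u is the x (column) component, v the y (row) component
    return np.column_stack([fv, fu])


def evolve(
    contour: Contour,
    field: ForceField,
    params: SnakeParams,
    return_history: bool = False,
) -> Contour | tuple[Contour, list[Contour]]:
    """Evolve a contour under internal forces and the external field.

    Each iteration solves (γI + A) X⁺ = γX + V(X) with γ = 1/dt (the
    semi-implicit scheme), clamps points to the field domain, and
    resamples to uniform arc length.  Stops when the mean point
    displacement falls below ``move_tol`` or after ``max_iter``.
    """
    if not (np.all(np.isfinite(field.u)) and np.all(np.isfinite(field.v))):
        raise ValueError("external field contains non-finite values")
    h, w = field.shape
    gamma = 1.0 / params.dt
    pts = contour.points.copy()
    history: list[Contour] = []
    factor_cache: dict[int, tuple] = {}
    for _ in range(params.max_iter):
        n = pts.shape[0]
        if n not in factor_cache:
            factor_cache[n] = lu_factor(_internal_matrix(n, params.alpha, params.beta, gamma))
        rhs = gamma * pts + params.ext_weight * _external_force(field, pts)
        new_pts = lu_solve(factor_cache[n], rhs)
        new_pts[:, 0] = np.clip(new_pts[:, 0], 0.0, h - 1.0)
        new_pts[:, 1] = np.clip(new_pts[:, 1], 0.0, w - 1.0)
        moved = float(np.hypot(*(new_pts - pts).T).mean())
        pts = _resample(new_pts)
        if polygon_area(pts) < 1.0:
            raise ContourCollapseError("contour area fell below 1 px^2")
        if return_history:
            history.append(Contour(pts.copy()))
        if moved < params.move_tol:
            break
    result = Contour(pts)
    return (result, history) if return_history else result


def contour_to_mask(contour: Contour, height: int, width: int) -> Mask2D:
    """Rasterize a closed contour: pixels whose centers are inside or on
    the polygon (even-odd rule) are 1."""
    ring = contour.points
    poly = Polygon(zip(ring[:, 1], ring[:, 0]))  # shapely wants (x, y)
    if not poly.is_valid:
        warnings.warn("self-intersecting contour; rasterizing its repaired outline")
        poly = poly.buffer(0)
    if poly.is_empty or poly.area == 0.0:
        return Mask2D(np.zeros((height, width), dtype=np.uint8))
    rr, cc = np.mgrid[0:height, 0:width]
    centers = shapely.points(cc.ravel(), rr.ravel())
    inside = shapely.covers(poly, centers).reshape(height, width)
    return Mask2D(inside.astype(np.uint8))


def _field_for_image(image, field_params, mode: str, sigma: float) -> ForceField:
    from .edge_forces import compute_corner_field, compute_edge_map, compute_gvf, compute_improved_field

    edge = compute_edge_map(image, sigma=sigma)
    if mode == "gvf":
        return compute_gvf(edge, field_params)
    if mode == "improved":
        corner = compute_corner_field(image, sigma=sigma)
        return compute_improved_field(edge, corner, field_params)
    raise ValueError(f"unknown field mode {mode!r}")


def segment_slice(
    image,
    seed_center: tuple[float, float],
    seed_radius: float,
    field_params,
    snake_params: SnakeParams,
    mode: str = "improved",
    sigma: float = 1.0,
    init_contour: Contour | None = None,
) -> tuple[Mask2D, Contour]:
    """Segment one slice: field computation, snake evolution, rasterization."""
    field = _field_for_image(image, field_params, mode, sigma)
    if init_contour is None:
        n0 = max(_MIN_POINTS, int(round(2.0 * np.pi * seed_radius)))
        init_contour = init_circle(seed_center, seed_radius, n0)
    final = evolve(init_contour, field, snake_params)
    return contour_to_mask(final, image.height, image.width), final


def segment_volume(
    stack: ImageStack,
    seed_center: tuple[float, float],
    seed_radius: float,
    field_params,
    snake_params: SnakeParams,
    mode: str = "improved",
    sigma: float = 1.0,
    seed_slice: int | None = None,
) -> list[Mask2D]:
    """Segment a nodule layer by layer, propagating the converged contour.

    Starts at ``seed_slice`` (default the middle slice) with the seed
    circle and walks outward in both directions, each slice initialized
    from its neighbor's converged contour.  A collapsing contour yields
    an empty mask and ends propagation in that direction.
    """
    h, w = stack.height, stack.width
    r0, c0 = seed_center
    if not (0 <= r0 - seed_radius and r0 + seed_radius <= h - 1
            and 0 <= c0 - seed_radius and c0 + seed_radius <= w - 1):
        raise ValueError("seed circle does not fit inside the slices")
    if seed_slice is None:
        seed_slice = stack.n_slices // 2
    if not (0 <= seed_slice < stack.n_slices):
        raise ValueError("seed_slice out of range")

    masks: list[Mask2D | None] = [None] * stack.n_slices
    empty = Mask2D(np.zeros((h, w), dtype=np.uint8))

    def run_direction(indices, start_contour):
        contour = start_contour
        for k in indices:
            if contour is None:
                masks[k] = empty
                continue
            try:
                masks[k], contour = segment_slice(
                    stack.slices[k], seed_center, seed_radius, field_params,
                    snake_params, mode=mode, sigma=sigma, init_contour=contour,
                )
            except ContourCollapseError:
                masks[k] = empty
                contour = None

    mask0, contour0 = None, None
    try:
        mask0, contour0 = segment_slice(
            stack.slices[seed_slice], seed_center, seed_radius,
            field_params, snake_params, mode=mode, sigma=sigma,
        )
    except ContourCollapseError:
        mask0 = empty
    masks[seed_slice] = mask0
    run_direction(range(seed_slice + 1, stack.n_slices), contour0)
    run_direction(range(seed_slice - 1, -1, -1), contour0)
    return masks  # type: ignore[return-value]
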