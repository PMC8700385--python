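"""Landmark (control-point) planar registration and ROI transfer.

Fuses a high-resolution histology slice with a T2-weighted MRI slice from
manually paired control points, then carries the pathologist's lesion ROI
down to the coarse DWI grid.  Two transform families are supported:

* ``affine`` — 6 coefficients, needs >= 3 point pairs;
* ``polynomial-2`` — two full bivariate quadratics (12 coefficients),
  needs >= 6 point pairs.

Coordinates are (x, y) in pixel units with x = column, y = row, 0-based.
Physical pixel centers sit at (index + 0.5) * pixel_size.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "ControlPointSet",
    "PlanarTransform",
    "ROIMask",
    "FusionResult",
    "SingularConfigurationError",
    "EmptyMaskError",
    "estimate_transform",
    "warp_image",
    "transfer_roi",
    "downsample_mask",
    "mirror_roi",
    "target_registration_error",
]

FAMILY_MIN_POINTS = {"affine": 3, "polynomial-2": 6}


class SingularConfigurationError(ValueError):
    """Raised when the control points cannot determine the transform."""


class EmptyMaskError(ValueError):
    """Raised when an ROI mask is (or becomes) empty."""


@dataclass
class ControlPointSet:
    """Paired landmark coordinates in the moving (histology) and fixed
    (T2WI) frames."""

    moving: np.ndarray
    fixed: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.moving = np.atleast_2d(np.asarray(self.moving, dtype=float))
        self.fixed = np.atleast_2d(np.asarray(self.fixed, dtype=float))
        if self.moving.shape != self.fixed.shape or self.moving.shape[1] != 2:
            raise ValueError("moving and fixed must both be (n, 2) arrays")
        if len(self.moving) < 3:
            raise ValueError("at least 3 control point pairs are required")
        uniq = np.unique(self.moving, axis=0)
        if len(uniq) < len(self.moving):
            raise ValueError("duplicated moving control points")
        if not self.ids:
            self.ids = [f"p{i}" for i in range(len(self.moving))]

    def __len__(self) -> int:
        return len(self.moving)


def _design_matrix(xy: np.ndarray, family: str) -> np.ndarray:
    x, y = xy[:, 0], xy[:, 1]
    if family == "affine":
        return np.column_stack([np.ones_like(x), x, y])
    if family == "polynomial-2":
        return np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])
    raise ValueError(f"unknown transform family: {family!r}")


@dataclass
class PlanarTransform:
    """Planar mapping moving -> fixed, fitted from control points.

    ``coefficients`` has shape (2, k) with k = 3 (affine) or 6
    (polynomial-2); row 0 produces x', row 1 produces y', both as linear
    combinations of the monomials [1, x, y] or [1, x, y, x^2, xy, y^2].
    """

    family: str
    coefficients: np.ndarray
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        k = 3 if self.family == "affine" else 6
        if self.coefficients.shape != (2, k):
            raise ValueError(
                f"{self.family} transform needs (2, {k}) coefficients, "
                f"got {self.coefficients.shape}"
            )
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite transform coefficients")
        if self.family == "affine":
            det = np.linalg.det(self.coefficients[:, 1:3])
            if abs(det) < 1e-12:
                raise ValueError("affine transform has singular linear part")

    @property
    def n_coefficients(self) -> int:
        return self.coefficients.size

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return _design_matrix(points, self.family) @ self.coefficients.T

    def inverse(self, domain_shape: tuple[int, int] | None = None) -> "PlanarTransform":
        """Inverse mapping fixed -> moving.

        Exact for affine.  For polynomial-2 the inverse is approximated by
        fitting a polynomial-2 transform on a dense grid of forward-mapped
        samples covering ``domain_shape`` (rows, cols) of the moving image.
        """
        if self.family == "affine":
            a = self.coefficients
            m = a[:, 1:3]
            t = a[:, 0]
            minv = np.linalg.inv(m)
            tinv = -minv @ t
            return PlanarTransform("affine", np.column_stack([tinv, minv]))
        if domain_shape is None:
            raise ValueError("polynomial-2 inverse needs the moving image shape")
        ny, nx = domain_shape
        gx, gy = np.meshgrid(np.linspace(0, nx - 1, 40), np.linspace(0, ny - 1, 40))
        src = np.column_stack([gx.ravel(), gy.ravel()])
        dst = self(src)
        return estimate_transform(
            ControlPointSet(moving=dst, fixed=src), family="polynomial-2"
        )

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "coefficients": self.coefficients.tolist(),
            "residuals": np.asarray(self.residuals, dtype=float).tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "PlanarTransform":
        return cls(d["family"], np.asarray(d["coefficients"]), np.asarray(d["residuals"]))

    @classmethod
    def from_json(cls, path) -> "PlanarTransform":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class ROIMask:
    """Binary region-of-interest mask with its grid geometry."""

    data: np.ndarray
    pixel_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    label: str = ""
    zone: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.label in ("lesion", "contralateral_normal") and not self.data.any():
            raise EmptyMaskError(f"ROI labelled {self.label!r} is empty")

    @property
    def area_px(self) -> int:
        return int(self.data.sum())

    @property
    def area_mm2(self) -> float:
        return self.area_px * self.pixel_size**2


@dataclass
class FusionResult:
    """Warped histology on the T2 grid plus registration quality metrics."""

    warped: np.ndarray
    transform: PlanarTransform
    residuals: np.ndarray
    tre_mm: float | None = None


def estimate_transform(
    points: ControlPointSet, family: str | None = None
) -> PlanarTransform:
    """Least-squares planar transform from paired control points.

    With ``family=None`` the family is chosen from the point count:
    polynomial-2 when >= 6 pairs are available, affine otherwise (an affine
    fit is the only determinable model at the 5-point minimum).  When the
    pair count equals the family minimum and the points are in general
    position the fit interpolates exactly.
    """
    n = len(points)
    if family is None:
        family = "polynomial-2" if n >= 6 else "affine"
    if family not in FAMILY_MIN_POINTS:
        raise ValueError(f"unknown transform family: {family!r}")
    need = FAMILY_MIN_POINTS[family]
    if n < need:
        raise ValueError(
            f"{family} transform needs at least {need} control points, got {n}"
        )
    design = _design_matrix(points.moving, family)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        kind = (
            "collinear moving points"
            if family == "affine"
            else "moving points on a degenerate conic"
        )
        raise SingularConfigurationError(
            f"rank-deficient control-point configuration ({kind}): "
            f"rank {rank} < {design.shape[1]}"
        )
    coef, *_ = np.linalg.lstsq(design, points.fixed, rcond=None)
    tf = PlanarTransform(family, coef.T)
    tf.residuals = np.linalg.norm(tf(points.moving) - points.fixed, axis=1)
    return tf


def _inverse_coords(
    transform: PlanarTransform, target_shape: tuple[int, int], moving_shape: tuple[int, int]
) -> np.ndarray:
    """(2, ny, nx) row/col sampling coordinates into the moving image for
    every pixel of the target (fixed) grid."""
    inv = transform.inverse(moving_shape)
    ny, nx = target_shape
    gx, gy = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float))
    src = inv(np.column_stack([gx.ravel(), gy.ravel()]))
    rows = src[:, 1].reshape(ny, nx)
    cols = src[:, 0].reshape(ny, nx)
    return np.stack([rows, cols])


def _check_invertibility(transform: PlanarTransform, shape: tuple[int, int]) -> None:
    """Warn if the forward mapping folds (Jacobian changes sign) on the
    moving image domain."""
    ny, nx = shape
    xs = np.linspace(0, nx - 1, 15)
    ys = np.linspace(0, ny - 1, 15)
    gx, gy = np.meshgrid(xs, ys)
    c = transform.coefficients
    if transform.family == "affine":
        jac = np.full(gx.shape, np.linalg.det(c[:, 1:3]))
    else:
        # d(x')/dx = a1 + 2 a3 x + a4 y, etc.
        dxdx = c[0, 1] + 2 * c[0, 3] * gx + c[0, 4] * gy
        dxdy = c[0, 2] + c[0, 4] * gx + 2 * c[0, 5] * gy
        dydx = c[1, 1] + 2 * c[1, 3] * gx + c[1, 4] * gy
        dydy = c[1, 2] + c[1, 4] * gx + 2 * c[1, 5] * gy
        jac = dxdx * dydy - dxdy * dydx
    if np.any(jac > 0) and np.any(jac < 0):
        warnings.warn(
            "transform is not invertible everywhere on the image domain "
            "(Jacobian changes sign); warped output may fold",
            RuntimeWarning,
            stacklevel=3,
        )


def warp_image(
    image: np.ndarray,
    transform: PlanarTransform,
    target_shape: tuple[int, int],
    fill: float = 0.0,
) -> np.ndarray:
    """Resample ``image`` (moving frame) onto the fixed grid.

    Inverse-mapping with bilinear interpolation; pixels mapping outside the
    moving image are set to ``fill``.
    """
    image = np.asarray(image, dtype=float)
    _check_invertibility(transform, image.shape)
    coords = _inverse_coords(transform, target_shape, image.shape)
    return ndimage.map_coordinates(
        image, coords, order=1, mode="constant", cval=fill, prefilter=False
    )


def transfer_roi(
    mask: ROIMask, transform: PlanarTransform, target_shape: tuple[int, int],
    target_pixel_size: float | None = None,
) -> ROIMask:
    """Carry a binary ROI from the moving grid to the fixed grid.

    A target pixel is set when its inverse-mapped center falls inside the
    source mask (nearest-neighbor semantics, appropriate for labels).
    """
    if not mask.data.any():
        raise EmptyMaskError("source ROI mask is empty")
    coords = _inverse_coords(transform, target_shape, mask.data.shape)
    out = ndimage.map_coordinates(
        mask.data.astype(np.uint8), coords, order=0, mode="constant", cval=0
    ).astype(bool)
    if not out.any():
        raise EmptyMaskError("ROI mapped entirely outside the target field of view")
    return ROIMask(
        out,
        pixel_size=target_pixel_size or mask.pixel_size,
        origin=mask.origin,
        label=mask.label,
        zone=mask.zone,
    )


def _axis_overlap_weights(n_fine: int, p_fine: float, n_coarse: int, p_coarse: float) -> np.ndarray:
    """(n_coarse, n_fine) matrix of 1-D physical overlap lengths between
    coarse pixel intervals [i*P, (i+1)*P) and fine intervals [j*p, (j+1)*p)."""
    w = np.zeros((n_coarse, n_fine))
    for i in range(n_coarse):
        lo, hi = i * p_coarse, (i + 1) * p_coarse
        j0 = max(0, int(np.floor(lo / p_fine)))
        j1 = min(n_fine, int(np.ceil(hi / p_fine)))
        for j in range(j0, j1):
            w[i, j] = max(0.0, min(hi, (j + 1) * p_fine) - max(lo, j * p_fine))
    return w


def downsample_mask(
    mask: ROIMask,
    target_shape: tuple[int, int],
    target_pixel_size: float,
    threshold: float = 0.5,
) -> ROIMask:
    """Downsample a fine-grid ROI (T2 resolution) to a coarse grid (DWI).

    The two grids share a physical frame anchored at the same origin.  A
    coarse pixel is set when the fraction of its physical footprint covered
    by the fine mask is >= ``threshold`` (majority rule by default).
    """
    if target_pixel_size < mask.pixel_size:
        raise ValueError("target grid must be coarser than (or equal to) the source grid")
    ny_f, nx_f = mask.data.shape
    ny_c, nx_c = target_shape
    wy = _axis_overlap_weights(ny_f, mask.pixel_size, ny_c, target_pixel_size)
    wx = _axis_overlap_weights(nx_f, mask.pixel_size, nx_c, target_pixel_size)
    coverage = wy @ mask.data.astype(float) @ wx.T / target_pixel_size**2
    out = coverage >= threshold
    if not out.any():
        raise EmptyMaskError(
            "ROI vanished at DWI resolution; a larger ROI (or smaller DWI "
            "pixels) is needed for a small focus"
        )
    return ROIMask(
        out,
        pixel_size=target_pixel_size,
        origin=mask.origin,
        label=mask.label,
        zone=mask.zone,
    )


def mirror_roi(
    lesion: ROIMask,
    midline_x: float,
    zone_mask: np.ndarray | None = None,
) -> ROIMask:
    """Reflect a lesion ROI across the prostate midline to obtain the
    contralateral normal-tissue ROI.

    ``midline_x`` is the x coordinate (pixel units, column axis) of the
    vertical midline.  If ``zone_mask`` is given the mirrored ROI is clipped
    to the lesion's anatomical zone, preserving the zone label (a peripheral
    zone lesion is mirrored into the opposite peripheral zone, a
    transitional zone lesion into the opposite transitional zone).
    """
    if not lesion.data.any():
        raise EmptyMaskError("lesion mask is empty")
    ny, nx = lesion.data.shape
    rows, cols = np.nonzero(lesion.data)
    # pixel center x = col + 0.5 -> reflected center 2*m - x -> col' = 2m - col - 1
    ref_cols = np.rint(2.0 * midline_x - cols - 1.0).astype(int)
    keep = (ref_cols >= 0) & (ref_cols < nx)
    mirrored = np.zeros_like(lesion.data)
    mirrored[rows[keep], ref_cols[keep]] = True
    if zone_mask is not None:
        mirrored &= np.asarray(zone_mask).astype(bool)
    if np.any(mirrored & lesion.data):
        raise ValueError(
            "mirrored ROI overlaps the lesion (lesion straddles the midline); "
            "contralateral placement is not defined"
        )
    if not mirrored.any():
        raise EmptyMaskError("mirrored ROI is empty after clipping to the zone")
    return ROIMask(
        mirrored,
        pixel_size=lesion.pixel_size,
        origin=lesion.origin,
        label="contralateral_normal",
        zone=lesion.zone,
    )


def target_registration_error(
    transform: PlanarTransform,
    moving: np.ndarray,
    fixed: np.ndarray,
    pixel_size_mm: float = 1.0,
) -> float:
    """Root-mean-square distance between mapped and true held-out landmarks,
    in mm.  The held-out pairs must not have been used in the fit."""
    moving = np.atleast_2d(np.asarray(moving, dtype=float))
    fixed = np.atleast_2d(np.asarray(fixed, dtype=float))
    if len(moving) < 1 or moving.shape != fixed.shape:
        raise ValueError("need >= 1 matched held-out point pair")
    err = np.linalg.norm(transform(moving) - fixed, axis=1)
    return float(np.sqrt(np.mean(err**2)) * pixel_size_mm)


def fuse(
    histology: np.ndarray,
    points: ControlPointSet,
    target_shape: tuple[int, int],
    family: str | None = None,
    holdout: tuple[np.ndarray, np.ndarray] | None = None,
    pixel_size_mm: float = 1.0,
) -> FusionResult:
    """Estimate the transform and warp the histology slice onto the T2 grid."""
    tf = estimate_transform(points, family)
    warped = warp_image(histology, tf, target_shape)
    tre = None
    if holdout is not None:
        tre = target_registration_error(tf, holdout[0], holdout[1], pixel_size_mm)
    return FusionResult(warped=warped, transform=tf, residuals=tf.residuals, tre_mm=tre)
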