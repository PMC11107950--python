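"""Optic-disc and foveal morphometry from binary segmentation masks.

All measurements use raster coordinates: ``x`` = column, ``y`` = row with rows
increasing downward.  The optic disc is summarized by its moment-equivalent
ellipse — the ellipse with the same normalized second central moments as the
segmented region — from which orientation, ovality and area derive.  The
OD-fovea angle uses the absolute horizontal separation in its denominator, so
an optic disc sitting *higher* than the fovea on the photograph yields a
negative angle in either eye.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.measure import label

MIN_COMPONENT_PX = 25


@dataclass(frozen=True)
class Centroid:
    x: float  # column
    y: float  # row (increasing downward)


@dataclass(frozen=True)
class EllipseFit:
    """Moment-equivalent ellipse of a segmented region.

    ``major_len``/``minor_len`` are full axis lengths; ``theta`` is the angle
    in degrees between the image horizontal and the major axis, measured
    toward increasing row index, wrapped to [-90, 90].
    """

    centroid: Centroid
    major_len: float
    minor_len: float
    theta: float

    def __post_init__(self) -> None:
        if not (self.major_len >= self.minor_len > 0):
            raise ValueError("require major_len >= minor_len > 0")
        if not (-90.0 <= self.theta <= 90.0):
            raise ValueError("theta outside [-90, 90]")


class MaskShapeError(ValueError):
    """Mask violates the single-component contract."""


def _largest_component(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise MaskShapeError("mask is empty")
    lab, n = label(mask, return_num=True)
    if n == 1:
        return mask
    sizes = np.bincount(lab.ravel())[1:]
    large = np.flatnonzero(sizes >= MIN_COMPONENT_PX) + 1
    if len(large) > 1:
        raise MaskShapeError(
            f"mask has {len(large)} connected components of >= {MIN_COMPONENT_PX} px; expected one"
        )
    if len(large) == 0:
        raise MaskShapeError(f"largest component smaller than {MIN_COMPONENT_PX} px")
    warnings.warn(f"ignoring {n - 1} small speck component(s) in mask", stacklevel=3)
    return lab == large[0]


def mask_centroid(mask: np.ndarray) -> Centroid:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise MaskShapeError("mask is empty")
    rows, cols = np.nonzero(mask)
    return Centroid(x=float(cols.mean()), y=float(rows.mean()))


def fit_ellipse(mask: np.ndarray) -> EllipseFit:
    """Fit the moment-equivalent ellipse to the mask's single large component.

    Second central moments of the pixel coordinates give the covariance
    matrix; eigenvalues lam yield full axis lengths 4*sqrt(lam) and the
    leading eigenvector the orientation.
    """
    comp = _largest_component(np.asarray(mask, dtype=bool))
    rows, cols = np.nonzero(comp)
    x = cols.astype(float)
    y = rows.astype(float)
    cx, cy = x.mean(), y.mean()
    dx, dy = x - cx, y - cy
    cxx = np.mean(dx * dx)
    cyy = np.mean(dy * dy)
    cxy = np.mean(dx * dy)
    # eigen-decomposition of [[cxx, cxy], [cxy, cyy]] in closed form
    tr, det = cxx + cyy, cxx * cyy - cxy * cxy
    disc = np.sqrt(max((tr / 2.0) ** 2 - det, 0.0))
    lam1 = tr / 2.0 + disc
    lam2 = max(tr / 2.0 - disc, 0.0)
    theta = 0.5 * np.degrees(np.arctan2(2.0 * cxy, cxx - cyy))
    if theta > 90.0:
        theta -= 180.0
    elif theta < -90.0:
        theta += 180.0
    return EllipseFit(
        centroid=Centroid(x=cx, y=cy),
        major_len=4.0 * np.sqrt(lam1),
        minor_len=4.0 * np.sqrt(lam2),
        theta=float(theta),
    )


def od_ovality(fit: EllipseFit) -> float:
    """Major-to-minor axis ratio; 1 = circular, larger = more oval."""
    return fit.major_len / fit.minor_len


def od_area(fit: EllipseFit) -> float:
    """Ellipse area: major * minor * pi / 4 (axis lengths are full lengths)."""
    return fit.major_len * fit.minor_len * np.pi / 4.0


def od_fovea_distance(od: Centroid, fovea: Centroid) -> float:
    """Euclidean distance between optic-disc and foveal centroids, px."""
    return float(np.hypot(od.x - fovea.x, od.y - fovea.y))


def od_fovea_angle(od: Centroid, fovea: Centroid) -> float:
    """Signed OD-fovea angle in degrees.

    arctan((od_y - fovea_y) / |od_x - fovea_x|): the absolute horizontal
    separation in the denominator makes the sign laterality-independent, and
    with rows increasing downward a disc *above* the fovea gives a negative
    angle.
    """
    dx = abs(od.x - fovea.x)
    if dx == 0.0:
        raise ValueError("OD and fovea share the same column; angle undefined")
    return float(np.degrees(np.arctan((od.y - fovea.y) / dx)))


def postprocess_fovea(mask: np.ndarray, image_size: tuple[int, int] | None = None,
                      area_fraction: float = 0.01) -> np.ndarray:
    """Replace a foveal mask by a circle of fixed relative size at its centroid.

    The output is a filled disk centred at the input centroid covering
    ``area_fraction`` (default 1%) of the image area, standardizing foveal
    size and shape across eyes.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise MaskShapeError("fovea mask is empty")
    if image_size is None:
        image_size = mask.shape
    h, w = image_size
    c = mask_centroid(mask)
    radius = np.sqrt(area_fraction * h * w / np.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    return (xx - c.x) ** 2 + (yy - c.y) ** 2 <= radius**2


def foveal_pixel_intensity(image: np.ndarray, fovea_mask: np.ndarray,
                           fundus_mask: np.ndarray | None = None,
                           brighter_is_negative: bool = True) -> float:
    """Median foveal intensity adjusted for the whole-fundus median.

    With the default sign convention the value is
    ``median(fundus) - median(fovea)``, so a fovea brighter than the fundus
    background yields a *negative* value.  ``brighter_is_negative=False``
    returns ``median(fovea) - median(fundus)`` instead.  Invariant to global
    additive intensity shifts either way.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:  # RGB -> luminance (ITU-R BT.601)
        image = image[..., 0] * 0.299 + image[..., 1] * 0.587 + image[..., 2] * 0.114
    fovea_mask = np.asarray(fovea_mask, dtype=bool)
    if not fovea_mask.any():
        raise MaskShapeError("fovea mask is empty")
    if fundus_mask is None:
        fundus_mask = np.ones_like(fovea_mask)
    fundus_mask = np.asarray(fundus_mask, dtype=bool)
    med_fovea = float(np.median(image[fovea_mask]))
    med_fundus = float(np.median(image[fundus_mask]))
    diff = med_fovea - med_fundus
    return -diff if brighter_is_negative else diff
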