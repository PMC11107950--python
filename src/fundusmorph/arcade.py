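"""Papillomacular arcade extraction and robust concavity estimation.

The main temporal vascular arcade emanates from the optic disc and bows
around the macula.  Its concavity is estimated by (1) isolating the arcade
from the binary vessel mask with a staged morphological pipeline and (2)
fitting a parabola to the arcade skeleton with RANSAC; the absolute quadratic
coefficient ``|a|`` is the concavity — larger values mean the arcade curves
inward more strongly and straightens out toward the fovea.

Extraction stages, in order: horizontal crop to the papillomacular half
(left-eye masks are mirrored first so one code path serves both eyes),
padding, distance transform to drop vessels thinner than a working calibre,
area opening, circle Hough transform to locate the arcade, retention of mask
pixels near the best circle, a second area opening, morphological closing,
and skeletonization.  The parabola is fitted with the skeleton *row* as the
abscissa (the arcade opens sideways, toward the fovea), so every stage error
names the stage for diagnosis.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.measure import label
from skimage.morphology import closing, dilation, disk, reconstruction, skeletonize
from skimage.transform import hough_circle

from .config import ArcadeConfig, RansacConfig


def _prune_spurs(skel: np.ndarray, min_len: int) -> np.ndarray:
    """Remove short skeleton side-branches (spurs).

    A spur is a segment between a branch point and a free end shorter than
    ``min_len`` px — the signature of a small vessel branching off the main
    arcade.  Segments free at both ends (the arcade itself, possibly cut into
    pieces by the circle-band selection) are never pruned.
    """
    from scipy.ndimage import convolve

    skel = skel.copy()
    kernel = np.ones((3, 3), dtype=np.uint8)
    for _ in range(2):  # second pass catches spurs revealed by the first
        s8 = skel.astype(np.uint8)
        deg = convolve(s8, kernel, mode="constant") - s8
        branch = skel & (deg >= 3)
        ends = skel & (deg <= 1)
        lab, n = label(skel & ~branch, return_num=True, connectivity=2)
        if n == 0:
            break
        removed = False
        near_branch = convolve(branch.astype(np.uint8), kernel, mode="constant") > 0
        for i in range(1, n + 1):
            seg = lab == i
            if seg.sum() >= min_len:
                continue
            if (seg & ends).any() and (seg & near_branch).any():
                skel &= ~seg
                removed = True
        if not removed:
            break
    return skel


def _area_open(mask: np.ndarray, min_size: int) -> np.ndarray:
    """Drop connected components smaller than ``min_size`` px (binary area opening)."""
    lab, n = label(mask, return_num=True, connectivity=2)
    if n == 0:
        return mask.copy()
    sizes = np.bincount(lab.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return keep[lab]


class ArcadeExtractionError(RuntimeError):
    """Extraction failed; ``stage`` names the pipeline stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass(frozen=True)
class ArcadeFit:
    """Robust parabola fit col = a*row^2 + b*row + c to the arcade skeleton."""

    a: float
    b: float
    c: float
    inlier_fraction: float
    r_squared: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.inlier_fraction <= 1.0):
            raise ValueError("inlier_fraction outside [0, 1]")

    @property
    def concavity(self) -> float:
        return abs(self.a)


def extract_arcade(vessel_mask: np.ndarray, laterality: str,
                   config: ArcadeConfig = ArcadeConfig(),
                   debug_dir: str | Path | None = None) -> np.ndarray:
    """Isolate the main arcade; returns (n, 2) skeleton points (row, col).

    Points are in the cropped (and, for left eyes, mirrored) frame; cropping
    and mirroring shift/flip the parabola's linear terms but leave ``|a|``
    unchanged.  ``debug_dir`` dumps each intermediate stage as .npy for
    visual audit.
    """
    mask = np.asarray(vessel_mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("vessel mask must be 2-D")
    if laterality == "LE":
        mask = mask[:, ::-1]
    elif laterality != "RE":
        raise ValueError(f"unknown laterality {laterality!r}")

    stages: dict[str, np.ndarray] = {}
    w = mask.shape[1]
    crop = mask[:, max(w - config.crop_cols, 0):]
    stages["crop"] = crop
    if not crop.any():
        raise ArcadeExtractionError("crop", "no vessel pixels in the papillomacular half")

    p = config.pad
    padded = np.pad(crop, p)
    edt = distance_transform_edt(padded)
    stages["distance_transform"] = edt
    cores = edt >= config.min_halfwidth
    if not cores.any():
        raise ArcadeExtractionError(
            "distance_transform", f"no vessels wider than {2 * config.min_halfwidth:g} px")
    # restore the full width of surviving vessels, then drop small specks
    thick = reconstruction(cores.astype(np.uint8), padded.astype(np.uint8)).astype(bool)
    opened = _area_open(thick, config.area_open_small)
    stages["area_opening_1"] = opened
    if not opened.any():
        raise ArcadeExtractionError("area_opening_1", "nothing survived the first area opening")

    circles = _hough_arcade(opened, config)
    if not circles:
        raise ArcadeExtractionError(
            "hough", f"no circle reached the accumulator threshold {config.hough_min_votes}")
    yy, xx = np.mgrid[0:opened.shape[0], 0:opened.shape[1]]
    near = np.zeros(opened.shape, dtype=bool)
    for r, cy, cx, _ in circles:
        near |= np.abs(np.hypot(yy - cy, xx - cx) - r) <= config.band
    selected = opened & near
    stages["hough_selection"] = selected
    if not selected.any():
        raise ArcadeExtractionError("hough", "no mask pixels near the detected circle")

    selected = _area_open(selected, config.area_open_isolated)
    stages["area_opening_2"] = selected
    closed = closing(selected, disk(config.close_radius))
    stages["closing"] = closed
    # Skeleton points are taken from the medial axis of the *original* cropped
    # mask restricted to the selected arcade region: skeletonizing the clipped
    # selection directly would let its skeleton drift off the vessel centerline
    # wherever the circle band cuts a vessel obliquely, biasing the fit.
    skel = skeletonize(padded) & dilation(closed, disk(2))
    skel = _prune_spurs(skel, config.spur_min_len)
    skel = skel[p:-p, p:-p]
    stages["skeleton"] = skel
    if not skel.any():
        raise ArcadeExtractionError("skeleton", "empty skeleton after closing")

    if debug_dir is not None:
        debug_dir = Path(debug_dir)
        debug_dir.mkdir(parents=True, exist_ok=True)
        for i, (name, arr) in enumerate(stages.items()):
            np.save(debug_dir / f"{i}_{name}.npy", arr)

    rows, cols = np.nonzero(skel)
    return np.column_stack([rows, cols]).astype(float)


def _hough_arcade(opened: np.ndarray, config: ArcadeConfig
                  ) -> list[tuple[float, float, float, int]]:
    """Top circles (radius, center_row, center_col, votes) through the arcade.

    Runs on a decimated skeleton for speed.  The accumulator is padded on the
    fovea side so circle centers may lie beyond the cropped half (flat arcades
    have large radii whose centers fall far toward or past the fovea).  A
    strongly curved arcade is not well covered by any single circle, so up to
    ``hough_n_circles`` peaks above the vote threshold are returned; their
    bands are united downstream.
    """
    ds = config.hough_downscale
    small = skeletonize(opened[::ds, ::ds])
    r_lo, r_hi = config.hough_radii
    radii = np.unique(np.rint(np.geomspace(r_lo / ds, r_hi / ds, config.hough_n_radii)).astype(int))
    pad_left = int(np.ceil(r_hi / ds))
    himg = np.pad(small, ((0, 0), (pad_left, 0)))
    accum = hough_circle(himg, radii, normalize=False)
    out: list[tuple[float, float, float, int]] = []
    suppress = max(int(config.band / ds), 1)
    for _ in range(config.hough_n_circles):
        ri, py, px = np.unravel_index(int(np.argmax(accum)), accum.shape)
        votes = int(accum[ri, py, px])
        if votes < config.hough_min_votes:
            break
        out.append((float(radii[ri] * ds), float(py * ds), float((px - pad_left) * ds), votes))
        y0, y1 = max(py - suppress, 0), py + suppress + 1
        x0, x1 = max(px - suppress, 0), px + suppress + 1
        accum[:, y0:y1, x0:x1] = 0  # non-maximum suppression around the peak
    return out


def fit_parabola_ransac(points: np.ndarray,
                        config: RansacConfig = RansacConfig()) -> ArcadeFit:
    """RANSAC quadratic fit y = a*x^2 + b*x + c to (x, y) points.

    Repeats minimal 3-point samples, counts points within
    ``config.residual_threshold`` of the candidate parabola, then refits by
    least squares on the best consensus set.  Deterministic for a fixed
    ``config.seed``.  Raises if the consensus stays below
    ``config.min_inlier_frac``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    n = len(pts)
    if n < 10:
        raise ValueError(f"need >= 10 points for a robust fit, got {n}")
    x, y = pts[:, 0], pts[:, 1]
    rng = np.random.default_rng(config.seed)
    best_mask = None
    best_count = -1
    for _ in range(config.max_iters):
        idx = rng.choice(n, size=3, replace=False)
        xs, ys = x[idx], y[idx]
        if min(abs(xs[0] - xs[1]), abs(xs[0] - xs[2]), abs(xs[1] - xs[2])) < 1e-9:
            continue
        try:
            coef = np.linalg.solve(np.vander(xs, 3), ys)
        except np.linalg.LinAlgError:
            continue
        resid = np.abs(np.polyval(coef, x) - y)
        inliers = resid <= config.residual_threshold
        count = int(inliers.sum())
        if count > best_count:
            best_count = count
            best_mask = inliers
            if count == n:
                break
    if best_mask is None or best_count / n < config.min_inlier_frac:
        raise ArcadeExtractionError(
            "ransac",
            f"consensus {max(best_count, 0)}/{n} below minimum inlier fraction "
            f"{config.min_inlier_frac:g}")
    a, b, c = np.polyfit(x[best_mask], y[best_mask], 2)
    fit_y = np.polyval([a, b, c], x[best_mask])
    ss_res = float(np.sum((y[best_mask] - fit_y) ** 2))
    ss_tot = float(np.sum((y[best_mask] - y[best_mask].mean()) ** 2))
    if ss_tot == 0.0:
        r2 = 1.0 if ss_res < 1e-12 else -np.inf
    else:
        r2 = 1.0 - ss_res / ss_tot
    return ArcadeFit(a=float(a), b=float(b), c=float(c),
                     inlier_fraction=best_count / n, r_squared=r2)


def arcade_fit(vessel_mask: np.ndarray, laterality: str,
               arcade_config: ArcadeConfig = ArcadeConfig(),
               ransac_config: RansacConfig = RansacConfig()) -> ArcadeFit:
    """Extraction + robust parabola fit for one vessel class."""
    points = extract_arcade(vessel_mask, laterality, arcade_config)
    return fit_parabola_ransac(points, ransac_config)


def concavity(arterial_mask: np.ndarray, venous_mask: np.ndarray, laterality: str,
              arcade_config: ArcadeConfig = ArcadeConfig(),
              ransac_config: RansacConfig = RansacConfig()) -> tuple[float, float]:
    """(arterial, venous) arcade concavity |a| in px^-1."""
    out = []
    for name, mask in (("artery", arterial_mask), ("vein", venous_mask)):
        try:
            out.append(arcade_fit(mask, laterality, arcade_config, ransac_config).concavity)
        except (ArcadeExtractionError, ValueError) as exc:
            raise ArcadeExtractionError(name, str(exc)) from exc
    return out[0], out[1]
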