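"""Synthetic fundus scenes with known ground-truth geometry.

A scene is the set of binary segmentation masks (optic disc, fovea, artery,
vein) plus a grayscale fundus image, generated from a :class:`SceneTruth` whose
fields are the exact geometric parameters every measurement operation is meant
to recover.  Coordinates follow raster convention: ``x`` is the column index
(increasing rightward), ``y`` the row index (increasing *downward*).

The temporal vascular arcades emanate from the optic disc and bow around the
macula, so the main arcade is modelled as a parabola whose *abscissa is the
image row*::

    col(row) = a * row**2 + b * row + c

with the vertex near the optic disc and the parabola opening toward the fovea
side.  ``|a|`` is the arcade concavity.  Vessels are drawn as constant-width
tubes around the centerline (distance-transform thresholding), so centerline
widths are known exactly for calibre tests.  Optional short distractor
branches exercise robust fitting downstream.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.draw import line as draw_line


class SceneGeometryError(ValueError):
    """Requested geometry does not fit on the canvas."""


@dataclass
class SegmentationMaskSet:
    """Aligned binary masks plus the grayscale fundus image."""

    od: np.ndarray
    fovea: np.ndarray
    artery: np.ndarray
    vein: np.ndarray
    fundus: np.ndarray

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.od, self.fovea, self.artery, self.vein, self.fundus)}
        if len(shapes) != 1:
            raise ValueError(f"masks have mismatched shapes: {shapes}")
        for name in ("od", "fovea", "artery", "vein"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))

    @property
    def vessels(self) -> np.ndarray:
        """Union of artery and vein masks (the 'vessel' map)."""
        return self.artery | self.vein


@dataclass
class SceneTruth:
    """Generating parameters of a synthetic scene.

    Axis lengths are *full* lengths (matching the ellipse-fit convention);
    ``od_theta`` is the angle in degrees between the image horizontal and the
    OD major axis, measured toward increasing row index, in [-90, 90].
    """

    od_center: tuple[float, float] = (780.0, 430.0)   # (x, y) px
    od_major: float = 150.0
    od_minor: float = 135.0
    od_theta: float = -7.0
    fovea_center: tuple[float, float] = (456.0, 456.0)
    arcade_coeffs: tuple[float, float, float] = (-0.002, 1.824, 384.128)
    arcade_rows: tuple[int, int] = (106, 806)
    vessel_width_profile: tuple[tuple[str, float], ...] = (("artery", 11.0), ("vein", 14.0))
    vein_offset: float = 14.0           # nasal offset of the vein arcade, px
    tortuosity_amp: float = 0.0         # sinusoidal centerline perturbation, px
    tortuosity_period: float = 250.0
    n_distractors: int = 0
    distractor_width: float = 8.0
    distractor_len: tuple[int, int] = (40, 90)
    laterality: str = "RE"
    image_size: tuple[int, int] = (912, 912)  # (rows, cols)
    seed: int = 0

    @classmethod
    def default(cls, laterality: str = "RE", **overrides) -> "SceneTruth":
        """A realistic default scene; ``laterality='LE'`` mirrors the geometry."""
        truth = cls(laterality=laterality, **overrides)
        if laterality == "LE" and "od_center" not in overrides:
            w = truth.image_size[1]
            a, b, c = truth.arcade_coeffs
            truth.od_center = (w - 1 - truth.od_center[0], truth.od_center[1])
            truth.fovea_center = (w - 1 - truth.fovea_center[0], truth.fovea_center[1])
            truth.arcade_coeffs = (-a, -b, w - 1 - c)
            truth.od_theta = -truth.od_theta
        return truth

    @classmethod
    def from_arcade_geometry(cls, concavity: float, vertex: tuple[float, float] | None = None,
                             sign: float = -1.0, **overrides) -> "SceneTruth":
        """Build a truth whose arcade has quadratic coefficient ``sign*concavity``.

        The parabola ``col(row)`` has its vertex at ``vertex`` (defaults to a
        point just nasal of the optic disc) and opens toward the fovea when
        ``sign`` matches the fovea side (-1 for a right eye with the disc on
        the right).
        """
        base = cls(**overrides)
        if vertex is None:
            vertex = (base.od_center[0] + 20.0, base.od_center[1])
        vx, vy = vertex
        a = sign * concavity
        b = -2.0 * a * vy
        c = vx + a * vy**2
        base.arcade_coeffs = (a, b, c)
        return base

    def validate(self) -> None:
        if not (self.od_major >= self.od_minor > 0):
            raise ValueError("require od_major >= od_minor > 0")
        if not (-90.0 <= self.od_theta <= 90.0):
            raise ValueError("od_theta must be in [-90, 90] degrees")
        if self.laterality not in ("RE", "LE"):
            raise ValueError(f"unknown laterality {self.laterality!r}")
        a, b, c = self.arcade_coeffs
        if a != 0.0:
            vy = -b / (2.0 * a)
            vx = c + a * vy**2 + b * vy
            opens_positive = a > 0
            fovea_positive = self.fovea_center[0] > vx
            if opens_positive != fovea_positive:
                raise ValueError("arcade must open toward the fovea side")


@dataclass
class SyntheticScene:
    masks: SegmentationMaskSet
    truth: SceneTruth


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  major: float, minor: float, theta_deg: float) -> np.ndarray:
    h, w = shape
    cx, cy = center
    sa, sb = major / 2.0, minor / 2.0
    t = np.deg2rad(theta_deg)
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - cx, yy - cy
    u = dx * np.cos(t) + dy * np.sin(t)
    v = -dx * np.sin(t) + dy * np.cos(t)
    return (u / sa) ** 2 + (v / sb) ** 2 <= 1.0


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    h, w = shape
    cx, cy = center
    yy, xx = np.mgrid[0:h, 0:w]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2


def fovea_radius(image_size: tuple[int, int], area_fraction: float = 0.01) -> float:
    """Radius of a disk covering ``area_fraction`` of the canvas."""
    h, w = image_size
    return float(np.sqrt(area_fraction * h * w / np.pi))


def render_vessel(shape: tuple[int, int], points: np.ndarray, width: float) -> np.ndarray:
    """Constant-width tube around a polyline centerline.

    ``points`` is an (n, 2) array of (row, col) vertices.  The tube is the set
    of pixels within ``width/2`` of the rasterized centerline, which gives a
    vessel whose medial-axis width is ``width`` up to rasterization.
    """
    pts = np.asarray(points, dtype=float)
    center = np.zeros(shape, dtype=bool)
    rounded = np.rint(pts).astype(int)
    rounded[:, 0] = np.clip(rounded[:, 0], 0, shape[0] - 1)
    rounded[:, 1] = np.clip(rounded[:, 1], 0, shape[1] - 1)
    for (r0, c0), (r1, c1) in zip(rounded[:-1], rounded[1:]):
        rr, cc = draw_line(r0, c0, r1, c1)
        center[rr, cc] = True
    if not center.any():
        return center
    dist = distance_transform_edt(~center)
    return dist <= width / 2.0


def _arcade_points(truth: SceneTruth) -> np.ndarray:
    a, b, c = truth.arcade_coeffs
    rows = np.arange(truth.arcade_rows[0], truth.arcade_rows[1] + 1, dtype=float)
    cols = a * rows**2 + b * rows + c
    if truth.tortuosity_amp > 0.0:
        cols = cols + truth.tortuosity_amp * np.sin(2.0 * np.pi * rows / truth.tortuosity_period)
    return np.column_stack([rows, cols])


def render_scene(truth: SceneTruth, *, background: int = 120, fovea_intensity: int = 80,
                 vessel_intensity: int = 60, fovea_area_fraction: float = 0.01) -> SyntheticScene:
    """Render the masks and grayscale fundus described by ``truth``.

    Deterministic: the same truth (including ``seed``) yields byte-identical
    rasters.  Raises :class:`SceneGeometryError` if any structure would leave
    the canvas.
    """
    truth.validate()
    shape = truth.image_size
    h, w = shape
    rng = np.random.default_rng(truth.seed)

    # --- optic disc ---
    cx, cy = truth.od_center
    half = truth.od_major / 2.0
    if not (half <= cx <= w - 1 - half and half <= cy <= h - 1 - half):
        raise SceneGeometryError("optic disc does not fit on the canvas")
    od = _ellipse_mask(shape, truth.od_center, truth.od_major, truth.od_minor, truth.od_theta)

    # --- fovea: circle covering fovea_area_fraction of the canvas ---
    fr = fovea_radius(shape, fovea_area_fraction)
    fx, fy = truth.fovea_center
    if not (fr <= fx <= w - 1 - fr and fr <= fy <= h - 1 - fr):
        raise SceneGeometryError("fovea does not fit on the canvas")
    fovea = _disk_mask(shape, truth.fovea_center, fr)

    # --- vascular arcades ---
    widths = dict(truth.vessel_width_profile)
    arcade = _arcade_points(truth)
    if arcade[:, 1].min() < 0 or arcade[:, 1].max() > w - 1:
        raise SceneGeometryError("arcade leaves the canvas")
    artery = render_vessel(shape, arcade, widths.get("artery", 11.0))
    vein_pts = arcade.copy()
    vein_pts[:, 1] += truth.vein_offset
    if vein_pts[:, 1].min() < 0 or vein_pts[:, 1].max() > w - 1:
        raise SceneGeometryError("vein arcade leaves the canvas")
    vein = render_vessel(shape, vein_pts, widths.get("vein", 14.0))

    # Distractor branches: short straight stubs rooted on the arcade, to
    # exercise outlier rejection in the robust parabola fit.
    for k in range(truth.n_distractors):
        root = arcade[rng.integers(0, len(arcade))]
        ang = rng.uniform(0.0, 2.0 * np.pi)
        length = rng.uniform(*truth.distractor_len)
        end = root + length * np.array([np.sin(ang), np.cos(ang)])
        end[0] = np.clip(end[0], 0, h - 1)
        end[1] = np.clip(end[1], 0, w - 1)
        stub = render_vessel(shape, np.array([root, end]), truth.distractor_width)
        # alternate classes so both masks carry an equal distractor load
        if k % 2 == 0:
            artery |= stub
        else:
            vein |= stub

    fundus = np.full(shape, background, dtype=np.uint8)
    fundus[artery | vein] = vessel_intensity
    fundus[fovea] = fovea_intensity

    masks = SegmentationMaskSet(od=od, fovea=fovea, artery=artery, vein=vein, fundus=fundus)
    return SyntheticScene(masks=masks, truth=truth)


# ---------------------------------------------------------------------------
# Disk I/O: 8-bit PNG masks (0/255) plus a JSON manifest holding the truth.
# ---------------------------------------------------------------------------

_MASK_FILES = ("od", "fovea", "artery", "vein", "fundus")


def save_scene(scene: SyntheticScene, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    m = scene.masks
    for name in _MASK_FILES:
        arr = getattr(m, name)
        img = arr if arr.dtype == np.uint8 else (arr.astype(np.uint8) * 255)
        iio.imwrite(directory / f"{name}.png", img)
    manifest = {"truth": dataclasses.asdict(scene.truth),
                "files": {name: f"{name}.png" for name in _MASK_FILES}}
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=lambda o: list(o))
    return directory


def load_scene(directory: str | Path) -> SyntheticScene:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    raw = manifest["truth"]
    fields = {f.name for f in dataclasses.fields(SceneTruth)}

    def _tupled(v):
        if isinstance(v, list):
            return tuple(_tupled(x) for x in v)
        return v

    truth = SceneTruth(**{k: _tupled(v) for k, v in raw.items() if k in fields})
    imgs = {name: iio.imread(directory / manifest["files"][name]) for name in _MASK_FILES}
    masks = SegmentationMaskSet(
        od=imgs["od"] > 127, fovea=imgs["fovea"] > 127,
        artery=imgs["artery"] > 127, vein=imgs["vein"] > 127,
        fundus=imgs["fundus"],
    )
    return SyntheticScene(masks=masks, truth=truth)
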