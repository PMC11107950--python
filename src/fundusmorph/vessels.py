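"""Vessel calibre summaries, tortuosity and fractal dimension.

Calibres follow the revised iterative pairwise combination formulas for the
six widest arterioles/venules measured in the standard annulus 0.5-1.0 disc
diameters from the optic-disc margin.  Tortuosity is the length-weighted
arc-to-chord ratio over skeleton segments; vascular complexity is the classic
box-counting fractal dimension of the binary vessel map.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import convolve, distance_transform_edt
from skimage.measure import label
from skimage.morphology import skeletonize

from .config import CalibreConfig, FractalConfig, TortuosityConfig
from .morphometry import EllipseFit


@dataclass
class VesselWidthSample:
    """Per-vessel centerline points (x, y) and the local width at each."""

    vessel_id: int
    points: np.ndarray   # (n, 2) of (x=col, y=row)
    widths: np.ndarray   # px, one per point

    @property
    def median_width(self) -> float:
        return float(np.median(self.widths))


@dataclass(frozen=True)
class VesselSummary:
    crae: float
    crve: float
    avr: float
    tortuosity: float
    fd: float


def measure_widths(vessel_mask: np.ndarray, od_fit: EllipseFit,
                   config: CalibreConfig = CalibreConfig()) -> list[VesselWidthSample]:
    """Median centerline width per vessel inside the measurement annulus.

    Local width at a skeleton pixel is twice the Euclidean distance transform
    (distance to the vessel edge).  The annulus spans ``config.annulus`` disc
    diameters from the disc margin, with the disc diameter taken as the mean
    of the fitted major and minor axis lengths.
    """
    mask = np.asarray(vessel_mask, dtype=bool)
    if not mask.any():
        raise ValueError("vessel mask is empty")
    edt = distance_transform_edt(mask)
    skel = skeletonize(mask)
    d_od = 0.5 * (od_fit.major_len + od_fit.minor_len)
    r_od = d_od / 2.0
    lo, hi = config.annulus
    yy, xx = np.mgrid[0:mask.shape[0], 0:mask.shape[1]]
    dist = np.hypot(xx - od_fit.centroid.x, yy - od_fit.centroid.y) - r_od
    annulus = (dist >= lo * d_od) & (dist <= hi * d_od)
    lab, n = label(mask, return_num=True, connectivity=2)
    samples: list[VesselWidthSample] = []
    for i in range(1, n + 1):
        sel = skel & annulus & (lab == i)
        if not sel.any():
            continue
        rows, cols = np.nonzero(sel)
        # EDT measures to the first background pixel *center*, overshooting the
        # vessel boundary by half a pixel; 2*d - 1 removes that bias.
        samples.append(VesselWidthSample(
            vessel_id=i,
            points=np.column_stack([cols, rows]).astype(float),
            widths=2.0 * edt[rows, cols] - 1.0,
        ))
    if not samples:
        warnings.warn("no vessel centerline pixels inside the measurement annulus", stacklevel=2)
    return samples


def knudtson_summary(widths: Sequence[float], kind: str,
                     config: CalibreConfig = CalibreConfig()) -> float:
    """Summary calibre (CRAE/CRVE) by iterative pairwise combination.

    The six largest widths are kept.  Each round sorts the remaining values,
    pairs the widest with the narrowest (and so on inward) into
    ``k * sqrt(w1^2 + w2^2)`` with the branching coefficient ``k`` for the
    vessel kind; an odd count carries the median value forward unchanged.
    The single remaining value is returned.
    """
    if kind == "artery":
        k = config.artery_coefficient
    elif kind == "vein":
        k = config.vein_coefficient
    else:
        raise ValueError(f"kind must be 'artery' or 'vein', got {kind!r}")
    ws = sorted(float(w) for w in widths)
    if not ws:
        raise ValueError("knudtson_summary requires at least one width")
    ws = sorted(ws, reverse=True)[: config.n_widest]
    while len(ws) > 1:
        ws.sort()
        carry = []
        if len(ws) % 2 == 1:
            mid = len(ws) // 2
            carry = [ws[mid]]
            ws = ws[:mid] + ws[mid + 1:]
        combined = [k * float(np.hypot(ws[i], ws[-1 - i])) for i in range(len(ws) // 2)]
        ws = combined + carry
    return ws[0]


# ---------------------------------------------------------------------------
# Skeleton segment machinery (shared by tortuosity)
# ---------------------------------------------------------------------------

_NEIGH = np.ones((3, 3), dtype=np.uint8)


def _skeleton_segments(skel: np.ndarray) -> list[np.ndarray]:
    """Ordered pixel paths between branch/end points of a skeleton.

    Branch points (>= 3 neighbours) are removed; each remaining connected run
    is ordered by walking from an endpoint.  Returns (n, 2) arrays of
    (row, col) in path order.
    """
    skel = np.asarray(skel, dtype=bool)
    deg = convolve(skel.astype(np.uint8), _NEIGH, mode="constant") - skel.astype(np.uint8)
    branch = skel & (deg >= 3)
    lab, n = label(skel & ~branch, return_num=True, connectivity=2)
    segments = []
    for i in range(1, n + 1):
        coords = np.argwhere(lab == i)
        segments.append(_order_path(coords))
    return segments


def _order_path(coords: np.ndarray) -> np.ndarray:
    if len(coords) <= 2:
        return coords
    coord_set = {tuple(c) for c in map(tuple, coords)}
    # endpoint: pixel with at most one 8-neighbour in the segment
    start = None
    for c in coord_set:
        nn = sum((c[0] + dr, c[1] + dc) in coord_set
                 for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0))
        if nn <= 1:
            start = c
            break
    if start is None:  # cycle; arbitrary start
        start = next(iter(coord_set))
    path = [start]
    visited = {start}
    cur = start
    while True:
        nxt = None
        best = np.inf
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                cand = (cur[0] + dr, cur[1] + dc)
                if cand != cur and cand in coord_set and cand not in visited:
                    d = dr * dr + dc * dc
                    if d < best:
                        best, nxt = d, cand
        if nxt is None:
            break
        path.append(nxt)
        visited.add(nxt)
        cur = nxt
    return np.asarray(path, dtype=float)


def _polyline_length(path: np.ndarray, step: int) -> float:
    idx = list(range(0, len(path), step))
    if idx[-1] != len(path) - 1:
        idx.append(len(path) - 1)
    pts = path[idx]
    return float(np.sum(np.hypot(*(np.diff(pts, axis=0).T))))


def tortuosity(vessel_mask: np.ndarray,
               config: TortuosityConfig = TortuosityConfig()) -> float:
    """Length-weighted mean arc-to-chord ratio over skeleton segments (>= 1).

    Arc length is measured on a resampled polyline (every
    ``config.resample_step`` skeleton pixels) to suppress rasterization
    stair-stepping; the chord is the straight endpoint distance.
    """
    mask = np.asarray(vessel_mask, dtype=bool)
    if not mask.any():
        raise ValueError("vessel mask is empty")
    skel = skeletonize(mask)
    ratios, weights = [], []
    for path in _skeleton_segments(skel):
        if len(path) < config.min_segment_len:
            continue
        chord = float(np.hypot(*(path[-1] - path[0])))
        if chord < 1.0:  # closed loop or point; arc/chord undefined
            continue
        arc = _polyline_length(path, config.resample_step)
        ratios.append(max(arc / chord, 1.0))
        weights.append(arc)
    if not ratios:
        raise ValueError("no skeleton segment long enough for tortuosity")
    return float(np.average(ratios, weights=weights))


def fractal_dimension(vessel_mask: np.ndarray,
                      config: FractalConfig = FractalConfig()) -> float:
    """Box-counting fractal dimension of the binary vessel map.

    Occupied boxes N(eps) are counted over a dyadic ladder of box sizes from
    ``config.min_box`` up to ``config.max_box_frac`` of the smaller image
    dimension; the dimension is the least-squares slope of log N against
    log(1/eps), clipped to the planar upper bound of 2.
    """
    mask = np.asarray(vessel_mask, dtype=bool)
    if not mask.any():
        raise ValueError("vessel mask is empty")
    h, w = mask.shape
    max_box = int(min(h, w) * config.max_box_frac)
    sizes = []
    e = config.min_box
    while e <= max_box:
        sizes.append(e)
        e *= 2
    if len(sizes) < 2:
        raise ValueError("mask too small for two box-counting scales")
    counts = []
    for e in sizes:
        hh = -(-h // e) * e
        ww = -(-w // e) * e
        padded = np.zeros((hh, ww), dtype=bool)
        padded[:h, :w] = mask
        boxes = padded.reshape(hh // e, e, ww // e, e).any(axis=(1, 3))
        counts.append(max(int(boxes.sum()), 1))
    slope = np.polyfit(np.log(1.0 / np.asarray(sizes, dtype=float)),
                       np.log(np.asarray(counts, dtype=float)), 1)[0]
    return float(min(slope, 2.0))


def vessel_summary(artery_mask: np.ndarray, vein_mask: np.ndarray, od_fit: EllipseFit,
                   calibre: CalibreConfig = CalibreConfig(),
                   tort: TortuosityConfig = TortuosityConfig(),
                   fractal: FractalConfig = FractalConfig()) -> VesselSummary:
    """CRAE, CRVE, AVR plus tortuosity and fractal dimension of the vessel map."""
    a_widths = [s.median_width for s in measure_widths(artery_mask, od_fit, calibre)]
    v_widths = [s.median_width for s in measure_widths(vein_mask, od_fit, calibre)]
    crae = knudtson_summary(a_widths, "artery", calibre)
    crve = knudtson_summary(v_widths, "vein", calibre)
    both = np.asarray(artery_mask, bool) | np.asarray(vein_mask, bool)
    return VesselSummary(
        crae=crae, crve=crve, avr=crae / crve,
        tortuosity=tortuosity(both, tort),
        fd=fractal_dimension(both, fractal),
    )
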