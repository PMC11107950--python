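"""Pipeline constants.

Every tunable of the measurement pipeline lives here as a frozen dataclass so a
run is fully described by its configuration.  Defaults target the 912x912 px
working resolution used throughout the package.
"""
from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ArcadeConfig:
    """Constants of the papillomacular-arcade extraction pipeline.

    The pipeline crops the temporal half of the vessel mask (the side holding
    the optic disc and the papillomacular bundle), removes thin vessels via the
    distance transform, detects the main arcade with a circle Hough transform,
    keeps mask pixels near the best circle, cleans up and skeletonizes.
    """

    canvas: tuple[int, int] = (912, 912)  # (rows, cols) working resolution
    crop_cols: int = 450                  # width of the papillomacular half-crop
    pad: int = 16                         # zero padding before morphology
    min_halfwidth: float = 2.5            # vessels thinner than 2x this are removed
    area_open_small: int = 400            # px; first area opening (specks)
    hough_downscale: int = 4              # Hough runs on a decimated image
    hough_radii: tuple[float, float] = (60.0, 1000.0)  # px, full resolution
    hough_n_radii: int = 16
    hough_min_votes: int = 15             # accumulator threshold (decimated px)
    hough_n_circles: int = 3              # union the bands of up to this many peaks
    band: float = 45.0                    # px; keep pixels this close to the circle
    area_open_isolated: int = 150         # px; second area opening
    close_radius: int = 7                 # px; morphological closing disk
    spur_min_len: int = 100               # px; skeleton side-branches shorter than this are pruned


@dataclass(frozen=True)
class RansacConfig:
    """Robust quadratic fit: y = a*x^2 + b*x + c by minimal-sample consensus."""

    residual_threshold: float = 3.0  # px; inlier band around the candidate parabola
    max_iters: int = 500
    min_inlier_frac: float = 0.3
    seed: int = 0


@dataclass(frozen=True)
class CalibreConfig:
    """Knudtson revised-formula constants and the measurement zone.

    Branching coefficients are the published artery/vein constants of the
    revised formulas; the annulus is the standard zone 0.5-1.0 disc diameters
    from the optic-disc margin.
    """

    artery_coefficient: float = 0.88
    vein_coefficient: float = 0.95
    n_widest: int = 6
    annulus: tuple[float, float] = (0.5, 1.0)  # disc diameters from OD margin


@dataclass(frozen=True)
class TortuosityConfig:
    min_segment_len: int = 10  # skeleton px; shorter segments are ignored
    resample_step: int = 5     # px; polyline resampling for arc length


@dataclass(frozen=True)
class FractalConfig:
    min_box: int = 2
    max_box_frac: float = 0.25  # largest box = max_box_frac * min(image dims)


@dataclass(frozen=True)
class MagnificationConfig:
    """Constants of the ocular magnification factor q(SER, CR).

    Littmann's relation t = 1.37 * q * s converts a measured fundus-image size
    s into a true retinal size t.  q is approximated from a schematic eye:
    axial length AL = al_per_cr * CR - SER / diopters_per_mm (an emmetropic
    length proportional to corneal radius, shortened/lengthened by ametropia at
    ~2.7 D per mm), then Bennett's q = q_slope * (AL - q_offset).
    """

    littmann_constant: float = 1.37
    al_per_cr: float = 2.96       # emmetropic axial length / corneal radius
    diopters_per_mm: float = 2.7  # refractive change per mm of axial length
    q_slope: float = 0.01306
    q_offset: float = 1.82        # mm; distance from cornea to the eye's 2nd principal point


@dataclass(frozen=True)
class PipelineConfig:
    arcade: ArcadeConfig = field(default_factory=ArcadeConfig)
    ransac: RansacConfig = field(default_factory=RansacConfig)
    calibre: CalibreConfig = field(default_factory=CalibreConfig)
    tortuosity: TortuosityConfig = field(default_factory=TortuosityConfig)
    fractal: FractalConfig = field(default_factory=FractalConfig)
    magnification: MagnificationConfig = field(default_factory=MagnificationConfig)


DEFAULT_CONFIG = PipelineConfig()
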