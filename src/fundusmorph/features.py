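"""Per-eye assembly of the 12 retinal parameters.

Given the four segmentation masks and the grayscale fundus image of one eye,
:func:`measure_eye` computes OD orientation, OD ovality, OD area, OD-fovea
distance, OD-fovea angle, foveal pixel intensity, CRAE, CRVE, arterial and
venous papillomacular concavity, vessel tortuosity, and vessel fractal
dimension.  When biometry (SER, CR) is supplied, the dimensional metrics
(OD-fovea distance, CRAE, CRVE, OD axis lengths before the area formula) are
magnification-corrected via Littmann's relation.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass

import pandas as pd

from . import morphometry as mm
from .arcade import concavity
from .biometry import MagnificationModel, correct_dimension
from .config import DEFAULT_CONFIG, PipelineConfig
from .scene import SegmentationMaskSet
from .vessels import knudtson_summary, measure_widths, fractal_dimension, tortuosity

FEATURE_COLUMNS = (
    "od_orientation", "od_ovality", "od_area", "od_fovea_distance", "od_fovea_angle",
    "fpi", "crae", "crve", "arterial_concavity", "venous_concavity",
    "vessel_tortuosity", "vessel_fd",
)


@dataclass(frozen=True)
class RetinalFeatureRecord:
    """The 12 per-eye parameters (+ AVR as a derived extra).

    Dimensional entries are in pixels unless magnification correction was
    applied, in which case they are in retinal units (mm-scale set by the
    q-strategy constants).
    """

    eye_id: str
    laterality: str
    od_orientation: float   # degrees
    od_ovality: float       # ratio >= 1
    od_area: float          # px^2 (or corrected^2)
    od_fovea_distance: float
    od_fovea_angle: float   # degrees, negative = OD above fovea
    fpi: float              # grayscale units, brighter fovea => negative
    crae: float
    crve: float
    avr: float
    arterial_concavity: float  # px^-1, |a| of the arcade parabola
    venous_concavity: float
    vessel_tortuosity: float
    vessel_fd: float
    magnification_corrected: bool = False

    def to_series(self) -> pd.Series:
        return pd.Series(asdict(self))


def measure_eye(masks: SegmentationMaskSet, laterality: str = "RE", eye_id: str = "eye",
                ser: float | None = None, cr: float | None = None,
                config: PipelineConfig = DEFAULT_CONFIG,
                magnification: MagnificationModel | None = None) -> RetinalFeatureRecord:
    """Compute all 12 retinal parameters for one eye."""
    od_fit = mm.fit_ellipse(masks.od)
    fovea = mm.postprocess_fovea(masks.fovea)
    fovea_c = mm.mask_centroid(fovea)

    major, minor = od_fit.major_len, od_fit.minor_len
    distance = mm.od_fovea_distance(od_fit.centroid, fovea_c)
    angle = mm.od_fovea_angle(od_fit.centroid, fovea_c)
    fpi = mm.foveal_pixel_intensity(masks.fundus, fovea)

    a_widths = [s.median_width for s in measure_widths(masks.artery, od_fit, config.calibre)]
    v_widths = [s.median_width for s in measure_widths(masks.vein, od_fit, config.calibre)]
    crae = knudtson_summary(a_widths, "artery", config.calibre)
    crve = knudtson_summary(v_widths, "vein", config.calibre)

    corrected = False
    if ser is not None and cr is not None:
        model = magnification or MagnificationModel(config.magnification)
        distance = correct_dimension(distance, model, ser, cr)
        crae = correct_dimension(crae, model, ser, cr)
        crve = correct_dimension(crve, model, ser, cr)
        major = correct_dimension(major, model, ser, cr)
        minor = correct_dimension(minor, model, ser, cr)
        corrected = True
    area = major * minor * 3.141592653589793 / 4.0

    art_conc, ven_conc = concavity(masks.artery, masks.vein, laterality,
                                   config.arcade, config.ransac)
    vessel_map = masks.vessels
    return RetinalFeatureRecord(
        eye_id=eye_id, laterality=laterality,
        od_orientation=od_fit.theta,
        od_ovality=mm.od_ovality(od_fit),
        od_area=area,
        od_fovea_distance=distance,
        od_fovea_angle=angle,
        fpi=fpi,
        crae=crae, crve=crve, avr=crae / crve,
        arterial_concavity=art_conc, venous_concavity=ven_conc,
        vessel_tortuosity=tortuosity(vessel_map, config.tortuosity),
        vessel_fd=fractal_dimension(vessel_map, config.fractal),
        magnification_corrected=corrected,
    )


def records_to_frame(records: list[RetinalFeatureRecord]) -> pd.DataFrame:
    """Stack per-eye records into the feature CSV layout."""
    return pd.DataFrame([r.to_series() for r in records])
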