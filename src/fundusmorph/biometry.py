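"""Ocular biometry, magnification correction and cohort selection.

Spherical equivalent refraction (SER) is sphere + 0.5 * cylinder (diopters);
corneal radius (CR) is the mean of the steepest and flattest corneal meridian
radii (mm).  Dimensional fundus measurements are converted from image pixels
to retinal size with Littmann's relation t = 1.37 * q * s, where the ocular
magnification factor q is approximated from SER and CR by a pluggable
strategy (see :class:`MagnificationModel`).

Cohort selection mirrors a standard quality/biometry funnel: drop rejected
image quality, optional health exclusions, missing refraction/keratometry/VA,
extreme corneal radii (within-sample percentile tails), and poor visual
acuity (worse than 0.00 logMAR), producing a per-step audit trail.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .config import MagnificationConfig


def compute_ser(sphere, cylinder):
    """Spherical equivalent refraction: sphere + 0.5 * cylinder, diopters."""
    return np.asarray(sphere, dtype=float) + 0.5 * np.asarray(cylinder, dtype=float)


def compute_cr(steep, flat):
    """Mean corneal radius of the steepest and flattest meridians, mm."""
    steep = np.asarray(steep, dtype=float)
    flat = np.asarray(flat, dtype=float)
    if np.any(steep <= 0) or np.any(flat <= 0):
        raise ValueError("corneal meridian radii must be positive")
    return 0.5 * (steep + flat)


def _schematic_eye_q(ser, cr, cfg: MagnificationConfig):
    """Default q(SER, CR): schematic-eye axial length into Bennett's factor."""
    al = cfg.al_per_cr * np.asarray(cr, dtype=float) - np.asarray(ser, dtype=float) / cfg.diopters_per_mm
    return cfg.q_slope * (al - cfg.q_offset)


@dataclass(frozen=True)
class MagnificationModel:
    """Littmann correction t = littmann_constant * q(SER, CR) * s.

    ``q_strategy`` may be swapped for any callable (ser, cr, config) -> q to
    match a particular published approximation; the default uses the
    schematic-eye constants in :class:`MagnificationConfig`.
    """

    config: MagnificationConfig = field(default_factory=MagnificationConfig)
    q_strategy: Callable = _schematic_eye_q

    @property
    def littmann_constant(self) -> float:
        return self.config.littmann_constant

    def q(self, ser, cr):
        q = np.asarray(self.q_strategy(ser, cr, self.config), dtype=float)
        if np.any(~np.isfinite(q)) or np.any(q <= 0):
            raise ValueError("magnification factor q must be positive and finite")
        return q if q.ndim else float(q)


def correct_dimension(s, model: MagnificationModel, ser, cr, power: int = 1):
    """Convert a pixel measurement to retinal units.

    ``power=1`` for linear metrics (t = 1.37 * q * s); ``power=2`` for areal
    metrics, where the linear scale factor applies squared.
    """
    if power not in (1, 2):
        raise ValueError("power must be 1 (linear) or 2 (areal)")
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("measured size must be non-negative")
    scale = model.littmann_constant * model.q(ser, cr)
    out = (np.asarray(scale) ** power) * s
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Cohort selection
# ---------------------------------------------------------------------------

MISSINGNESS_COLUMNS = ("sphere", "cylinder", "cr_steep", "cr_flat", "va")


@dataclass
class FilterAudit:
    """Per-step drop counts of the selection funnel."""

    n_input: int
    steps: list[tuple[str, int]]
    n_output: int

    @property
    def dropped(self) -> int:
        return sum(n for _, n in self.steps)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"n_input": self.n_input, "n_output": self.n_output,
             "steps": [{"step": s, "dropped": n} for s, n in self.steps]},
            indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload


def apply_selection_filters(table: pd.DataFrame,
                            cr_percentiles: tuple[float, float] = (0.5, 99.5),
                            cr_bounds: tuple[float, float] | None = None,
                            va_cutoff: float = 0.0,
                            ) -> tuple[pd.DataFrame, FilterAudit]:
    """Sequential cohort selection with an audit trail.

    Steps (each logged with its drop count):

    1. ``quality_reject`` flag true (column optional);
    2. ``health_exclusion`` flag true (column optional; supplied by the user
       from linked records — this package does not derive it);
    3. missing refraction, keratometry or VA;
    4. CR outside the within-sample percentile interval ``cr_percentiles``
       computed on the surviving rows (or fixed ``cr_bounds`` for
       reproducible fixtures);
    5. VA worse than ``va_cutoff`` logMAR.

    Returns the surviving rows and a :class:`FilterAudit`.
    """
    missing = [c for c in MISSINGNESS_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks required columns: {missing}")
    df = table.copy()
    steps: list[tuple[str, int]] = []
    n0 = len(df)

    def _drop(name: str, keep: pd.Series) -> None:
        nonlocal df
        steps.append((name, int((~keep).sum())))
        df = df.loc[keep]

    if "quality_reject" in df.columns:
        _drop("image_quality_reject", ~df["quality_reject"].fillna(False).astype(bool))
    if "health_exclusion" in df.columns:
        _drop("health_exclusion", ~df["health_exclusion"].fillna(False).astype(bool))
    _drop("missing_refraction_keratometry_va",
          df[list(MISSINGNESS_COLUMNS)].notna().all(axis=1))
    if len(df):
        cr = compute_cr(df["cr_steep"], df["cr_flat"])
        if cr_bounds is None:
            lo, hi = np.percentile(cr, cr_percentiles)
        else:
            lo, hi = cr_bounds
        _drop("extreme_corneal_radius", pd.Series((cr >= lo) & (cr <= hi), index=df.index))
    else:
        steps.append(("extreme_corneal_radius", 0))
    _drop("poor_visual_acuity", df["va"] <= va_cutoff)

    audit = FilterAudit(n_input=n0, steps=steps, n_output=len(df))
    return df, audit


def assemble_biometry(table: pd.DataFrame) -> pd.DataFrame:
    """Add derived ``ser`` and ``cr`` columns to a biometry table."""
    df = table.copy()
    df["ser"] = compute_ser(df["sphere"], df["cylinder"])
    df["cr"] = compute_cr(df["cr_steep"], df["cr_flat"])
    return df
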