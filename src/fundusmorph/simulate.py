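"""Synthetic cohorts with known conditional-quantile effect structure.

Refraction is generated from a location-scale model

    SER = b0 + X @ beta + (1 + X @ delta) * eps,     eps ~ N(0, sigma^2)

so the true conditional-quantile slope of feature j at level tau has the
closed form  beta_j + delta_j * Q_eps(tau)  where Q_eps is the noise quantile
function.  delta = 0 gives homoscedastic data with flat (constant-in-tau)
slopes; delta != 0 gives slopes that grow toward one tail — the pattern in
which retinal features associate more strongly with refraction as myopia
deepens.  Ground truth is returned alongside the table so quantile-regression
estimates can be scored exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import ndtri


@dataclass(frozen=True)
class CohortEffectSpec:
    """Effect structure of a simulated cohort.

    ``feature_effects`` / ``covariate_effects`` map column name to
    (location slope beta, scale slope delta); ``sigma`` is the noise SD in
    diopters.  Defaults emulate a mildly myopic adult cohort with one
    strongly quantile-varying vascular feature, one weak feature, and
    age/sex/CR covariates with constant effects.
    """

    n: int = 5000
    seed: int = 0
    intercept: float = -0.3
    feature_effects: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"vessel_fd": (0.55, 0.12), "od_fovea_angle": (0.05, 0.0)})
    covariate_effects: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"age": (-0.10, 0.0), "sex": (0.10, 0.0), "cr": (0.20, 0.0)})
    sigma: float = 2.0


@dataclass(frozen=True)
class CohortTruth:
    """Closed-form ground truth for a location-scale cohort."""

    betas: Mapping[str, float]
    deltas: Mapping[str, float]
    sigma: float
    intercept: float

    def slope(self, name: str, tau) -> np.ndarray | float:
        """True conditional-quantile slope beta + delta * sigma * Phi^-1(tau)."""
        q = self.sigma * ndtri(np.asarray(tau, dtype=float))
        out = self.betas[name] + self.deltas[name] * q
        return out if out.ndim else float(out)


def simulate_cohort(spec: CohortEffectSpec = CohortEffectSpec()
                    ) -> tuple[pd.DataFrame, CohortTruth]:
    """Simulate a cohort table and its ground-truth quantile slopes.

    Features and continuous covariates are standard normal (i.e. already
    standardized); ``sex`` is Bernoulli(0.5) coded 0/1.  Raises if the noise
    scale 1 + X @ delta is non-positive for any row.
    """
    if spec.n < 50:
        raise ValueError("need n >= 50 eyes")
    rng = np.random.default_rng(spec.seed)
    cols: dict[str, np.ndarray] = {}
    betas: dict[str, float] = {}
    deltas: dict[str, float] = {}
    for name, (b, d) in spec.feature_effects.items():
        cols[name] = rng.standard_normal(spec.n)
        betas[name], deltas[name] = float(b), float(d)
    for name, (b, d) in spec.covariate_effects.items():
        if name == "sex":
            cols[name] = rng.integers(0, 2, size=spec.n).astype(float)
        else:
            cols[name] = rng.standard_normal(spec.n)
        betas[name], deltas[name] = float(b), float(d)
    X = np.column_stack(list(cols.values())) if cols else np.empty((spec.n, 0))
    bvec = np.array([betas[k] for k in cols])
    dvec = np.array([deltas[k] for k in cols])
    scale = 1.0 + X @ dvec
    if np.any(scale <= 0):
        raise ValueError("noise scale 1 + X @ delta is non-positive for some rows; "
                         "reduce the delta magnitudes")
    eps = rng.normal(0.0, spec.sigma, size=spec.n)
    ser = spec.intercept + X @ bvec + scale * eps
    df = pd.DataFrame(cols)
    df["ser"] = ser
    truth = CohortTruth(betas=betas, deltas=deltas, sigma=spec.sigma, intercept=spec.intercept)
    return df, truth
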