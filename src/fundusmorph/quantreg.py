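"""Regression of spherical equivalent refraction on retinal features.

Two statsmodels-style model classes operate on an assembled per-eye table
(12 retinal features + age, sex, corneal radius + SER):

* :class:`SEROLSModel` — ordinary least squares within a refractive group
  (myopes: SER <= -0.50 D; non-myopes otherwise), with standardized
  coefficients, 95% CIs, variance-inflation factors, and Q-Q /
  residual-vs-fitted diagnostics.

* :class:`SERQuantileModel` — quantile regression of SER across a grid of 34
  conditional quantiles from 0.005 (most myopic) to 0.995 (most hyperopic),
  giving a standardized coefficient curve beta(tau) per feature with CIs
  (asymptotic robust or xy-pair bootstrap) and per-tau significance.

Both expose ``from_dataframe`` constructors and ``fit()`` returning a
Results object with a ``summary()`` table; plots and ranking tables hang off
the quantile Results.  No multiple-testing correction is applied across
quantiles: each eye contributes to one refractive quantile, so the per-tau
tests are not family-wise repeated tests of one hypothesis.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

MYOPIA_CUTOFF_D = -0.50
DEFAULT_COVARIATES = ("age", "sex", "cr")


def quantile_grid(n: int = 34, lo: float = 0.005, hi: float = 0.995) -> np.ndarray:
    """Evenly spaced quantile levels; defaults give 34 levels 0.005..0.995."""
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("quantile endpoints must satisfy 0 < lo < hi < 1")
    return np.linspace(lo, hi, n)


@dataclass(frozen=True)
class Standardization:
    """Column means/SDs used for z-scoring; supports inverse mapping."""

    means: pd.Series
    sds: pd.Series

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for c in self.means.index:
            out[c] = (out[c] - self.means[c]) / self.sds[c]
        return out

    def inverse(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for c in self.means.index:
            out[c] = out[c] * self.sds[c] + self.means[c]
        return out


def standardize(table: pd.DataFrame, columns: Sequence[str]
                ) -> tuple[pd.DataFrame, Standardization]:
    """Z-score the named columns (continuous features and age; never sex)."""
    means = table[list(columns)].mean()
    sds = table[list(columns)].std(ddof=0)
    zero = sds[sds == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance column(s): {zero}")
    scaler = Standardization(means=means, sds=sds)
    return scaler.transform(table), scaler


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1/(1 - R^2_j) per predictor.

    Perfect collinearity yields ``inf`` rather than an exception so the
    offending terms can be flagged (the conventional cutoff is 10).
    """
    X = design.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least two predictors")
    out = {}
    for j, name in enumerate(design.columns):
        others = np.column_stack([np.delete(X, j, axis=1), np.ones(len(X))])
        yj = X[:, j]
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 1.0
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


@dataclass(frozen=True)
class CoefficientEstimate:
    term: str
    beta_std: float
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.beta_std <= self.ci_high):
            raise ValueError("point estimate outside its own CI")


def _design(table: pd.DataFrame, features: Sequence[str], covariates: Sequence[str],
            outcome: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    terms = list(features) + list(covariates)
    cols = terms + [outcome]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks columns: {missing}")
    if table[cols].isna().any().any():
        raise ValueError("table contains missing values; assemble/filter first")
    X = np.column_stack([np.ones(len(table)), table[terms].to_numpy(dtype=float)])
    y = table[outcome].to_numpy(dtype=float)
    return y, X, ["intercept"] + terms


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        df = pd.DataFrame(X[:, 1:], columns=names[1:])
        bad = vif(df)
        aliased = bad.index[~np.isfinite(bad) | (bad > 1e10)].tolist()
        raise ValueError(f"singular design; aliased columns: {aliased or 'unknown'}")


# ---------------------------------------------------------------------------
# OLS per refractive group
# ---------------------------------------------------------------------------


class SEROLSModel:
    """OLS of SER on the 12 features + covariates within a refractive group."""

    def __init__(self, endog: np.ndarray, exog: np.ndarray, term_names: list[str]):
        if len(endog) <= exog.shape[1]:
            raise ValueError("need n > number of parameters")
        _check_full_rank(exog, term_names)
        self.endog = endog
        self.exog = exog
        self.term_names = term_names

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, features: Sequence[str],
                       covariates: Sequence[str] = DEFAULT_COVARIATES,
                       outcome: str = "ser", group: str | None = None,
                       cutoff: float = MYOPIA_CUTOFF_D) -> "SEROLSModel":
        """``group`` in {'myope', 'nonmyope', None}; myopes have SER <= cutoff."""
        if group == "myope":
            table = table[table[outcome] <= cutoff]
        elif group == "nonmyope":
            table = table[table[outcome] > cutoff]
        elif group is not None:
            raise ValueError("group must be 'myope', 'nonmyope' or None")
        if not len(table):
            raise ValueError(f"group {group!r} is empty")
        y, X, names = _design(table, features, covariates, outcome)
        return cls(y, X, names)

    def fit(self, alpha: float = 0.05) -> "SEROLSResults":
        res = sm.OLS(self.endog, self.exog).fit()
        ci = res.conf_int(alpha=alpha)
        coefs = [CoefficientEstimate(t, float(res.params[i]), float(ci[i, 0]),
                                     float(ci[i, 1]), float(res.pvalues[i]))
                 for i, t in enumerate(self.term_names)]
        return SEROLSResults(model=self, sm_results=res, coefficients=coefs)


@dataclass
class SEROLSResults:
    model: SEROLSModel
    sm_results: object
    coefficients: list[CoefficientEstimate]

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.sm_results.params, index=self.model.term_names)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.__dict__ for c in self.coefficients])

    def vif(self) -> pd.Series:
        """VIFs of the non-intercept terms; values above 10 flag collinearity."""
        df = pd.DataFrame(self.model.exog[:, 1:], columns=self.model.term_names[1:])
        return vif(df)

    def qq_points(self) -> tuple[np.ndarray, np.ndarray]:
        """(theoretical, sample) normal Q-Q ordinates of the residuals."""
        resid = np.sort(self.sm_results.resid)
        n = len(resid)
        theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        return theo, resid

    def resid_fitted(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.sm_results.fittedvalues), np.asarray(self.sm_results.resid)

    def summary(self):
        return self.sm_results.summary(xname=self.model.term_names)


# ---------------------------------------------------------------------------
# Quantile regression across the refractive distribution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuantileFitResult:
    """Fit at one quantile level: intercept + per-term estimates."""

    tau: float
    intercept: float
    coefficients: tuple[CoefficientEstimate, ...]

    def __post_init__(self) -> None:
        if not (0.0 < self.tau < 1.0):
            raise ValueError("tau must lie strictly within (0, 1)")


class SERQuantileModel:
    """Quantile regression of SER on retinal features + covariates.

    Fit on the *full* refractive range (no group split): the whole point is
    to let effects vary across the outcome distribution.
    """

    def __init__(self, endog: np.ndarray, exog: np.ndarray, term_names: list[str]):
        _check_full_rank(exog, term_names)
        self.endog = endog
        self.exog = exog
        self.term_names = term_names

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, features: Sequence[str],
                       covariates: Sequence[str] = DEFAULT_COVARIATES,
                       outcome: str = "ser") -> "SERQuantileModel":
        y, X, names = _design(table, features, covariates, outcome)
        return cls(y, X, names)

    def fit(self, taus: np.ndarray | None = None, ci: str = "asymptotic",
            n_boot: int = 200, seed: int | None = None, alpha: float = 0.05,
            min_tail_obs: int = 30) -> "QuantileCurveResults":
        """Fit every tau in ``taus`` (default: the 34-level grid).

        ``ci='asymptotic'`` uses the robust (Powell kernel sandwich)
        covariance of statsmodels; ``ci='bootstrap'`` resamples (x, y) pairs
        ``n_boot`` times.  Quantiles with fewer than ``min_tail_obs``
        effective observations in the shorter tail are refused and recorded
        in ``results.errors`` while the remaining taus are still returned.
        """
        taus = quantile_grid() if taus is None else np.atleast_1d(np.asarray(taus, dtype=float))
        if np.any((taus <= 0.0) | (taus >= 1.0)):
            raise ValueError("all tau must lie strictly within (0, 1)")
        if ci not in ("asymptotic", "bootstrap"):
            raise ValueError("ci must be 'asymptotic' or 'bootstrap'")
        n = len(self.endog)
        rng = np.random.default_rng(seed)
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        qr = sm.QuantReg(self.endog, self.exog)
        fits: list[QuantileFitResult] = []
        errors: dict[float, str] = {}
        for tau in taus:
            n_tail = n * min(tau, 1.0 - tau)
            if n_tail < min_tail_obs:
                errors[float(tau)] = (f"only ~{n_tail:.0f} effective tail observations "
                                      f"(< {min_tail_obs}); refusing tau={tau:g}")
                continue
            try:
                res = qr.fit(q=tau)
                params = np.asarray(res.params, dtype=float)
                if ci == "asymptotic":
                    se = np.asarray(res.bse, dtype=float)
                    lo_ci = params - z * se
                    hi_ci = params + z * se
                    pvals = np.asarray(res.pvalues, dtype=float)
                else:
                    boots = np.empty((n_boot, len(params)))
                    for b in range(n_boot):
                        idx = rng.integers(0, n, size=n)
                        boots[b] = sm.QuantReg(self.endog[idx], self.exog[idx]).fit(q=tau).params
                    lo_ci = np.percentile(boots, 100 * alpha / 2.0, axis=0)
                    hi_ci = np.percentile(boots, 100 * (1.0 - alpha / 2.0), axis=0)
                    lo_ci = np.minimum(lo_ci, params)
                    hi_ci = np.maximum(hi_ci, params)
                    se = boots.std(axis=0, ddof=1)
                    with np.errstate(divide="ignore", invalid="ignore"):
                        pvals = 2.0 * stats.norm.sf(np.abs(params) / se)
            except Exception as exc:  # non-convergence at this tau only
                errors[float(tau)] = str(exc)
                continue
            coefs = tuple(
                CoefficientEstimate(t, float(params[i]), float(lo_ci[i]),
                                    float(hi_ci[i]), float(pvals[i]))
                for i, t in enumerate(self.term_names) if t != "intercept")
            fits.append(QuantileFitResult(tau=float(tau), intercept=float(params[0]),
                                          coefficients=coefs))
        return QuantileCurveResults(model=self, fits=fits, errors=errors, alpha=alpha)


@dataclass
class QuantileCurveResults:
    """Coefficient curves beta(tau) with CIs across the refractive quantiles."""

    model: SERQuantileModel
    fits: list[QuantileFitResult]
    errors: dict[float, str] = field(default_factory=dict)
    alpha: float = 0.05

    @property
    def taus(self) -> np.ndarray:
        return np.array([f.tau for f in self.fits])

    def frame(self) -> pd.DataFrame:
        """Tidy table: one row per term x tau."""
        rows = []
        for f in self.fits:
            for c in f.coefficients:
                rows.append({"tau": f.tau, "term": c.term, "beta_std": c.beta_std,
                             "ci_low": c.ci_low, "ci_high": c.ci_high,
                             "p_value": c.p_value})
        return pd.DataFrame(rows)

    def intercept_curve(self) -> pd.DataFrame:
        """Predicted SER per tau at the quantile-specific covariate means.

        Each eye is assigned to its nearest tau by empirical SER rank; the
        prediction is x-bar(tau) @ beta(tau) — the refraction of a 'typical'
        eye in that quantile.
        """
        y = self.model.endog
        ranks = (stats.rankdata(y) - 0.5) / len(y)
        taus = self.taus
        rows = []
        for f in self.fits:
            in_bin = np.abs(ranks[:, None] - taus[None, :]).argmin(axis=1) == list(taus).index(f.tau)
            xbar = self.model.exog[in_bin].mean(axis=0) if in_bin.any() else self.model.exog.mean(axis=0)
            beta = np.array([f.intercept] + [c.beta_std for c in f.coefficients])
            rows.append({"tau": f.tau, "predicted_ser": float(xbar @ beta)})
        return pd.DataFrame(rows)

    def ranking_table(self, features: Sequence[str] | None = None) -> pd.DataFrame:
        """Per-tau ranking of terms by absolute standardized effect size."""
        df = self.frame()
        if features is not None:
            df = df[df["term"].isin(features)]
        df = df.assign(abs_beta=df["beta_std"].abs())
        df["rank"] = df.groupby("tau")["abs_beta"].rank(ascending=False, method="first").astype(int)
        return df.sort_values(["tau", "rank"]).reset_index(drop=True)

    def summary(self) -> str:
        lines = [f"Quantile regression of SER: {len(self.fits)} quantiles fitted, "
                 f"{len(self.errors)} refused/failed",
                 f"terms: {', '.join(self.model.term_names[1:])}", ""]
        df = self.frame()
        for term, sub in df.groupby("term"):
            sig = int((sub["p_value"] < self.alpha).sum())
            lines.append(f"{term:>22s}: beta(tau) in [{sub['beta_std'].min():+.3f}, "
                         f"{sub['beta_std'].max():+.3f}] D/SD, significant at "
                         f"{sig}/{len(sub)} quantiles")
        return "\n".join(lines)

    def plot_coefficient_curves(self, features: Sequence[str] | None = None, ncols: int = 4):
        """Per-term beta(tau) curves with CI ribbons; markers where p < alpha."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        df = self.frame()
        terms = list(features) if features is not None else sorted(df["term"].unique())
        nrows = -(-len(terms) // ncols)
        fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows),
                                 squeeze=False, sharex=True)
        for ax, term in zip(axes.ravel(), terms):
            sub = df[df["term"] == term].sort_values("tau")
            ax.fill_between(sub["tau"], sub["ci_low"], sub["ci_high"], alpha=0.25)
            ax.plot(sub["tau"], sub["beta_std"], lw=1.2)
            sig = sub[sub["p_value"] < self.alpha]
            if len(sig):
                ax.plot(sig["tau"], sig["beta_std"], ".", ms=5)
            ax.axhline(0.0, ls=":", lw=0.8, color="gray")
            ax.set_title(term, fontsize=9)
        for ax in axes.ravel()[len(terms):]:
            ax.set_visible(False)
        fig.supxlabel("refractive quantile (myopic -> hyperopic)")
        fig.supylabel("standardized beta (D per SD)")
        fig.tight_layout()
        return fig


def fit_quantile_curve(table: pd.DataFrame, taus: np.ndarray | None = None,
                       features: Sequence[str] | None = None,
                       covariates: Sequence[str] = DEFAULT_COVARIATES,
                       **fit_kwargs) -> QuantileCurveResults:
    """Convenience wrapper: build an :class:`SERQuantileModel` and fit."""
    if features is None:
        reserved = set(covariates) | {"ser", "laterality", "eye_id", "group"}
        features = [c for c in table.columns if c not in reserved]
    model = SERQuantileModel.from_dataframe(table, features, covariates)
    return model.fit(taus=taus, **fit_kwargs)


def coefficient_curve_report(results: QuantileCurveResults,
                             features: Sequence[str] | None = None,
                             outdir: str | None = None):
    """Curves table + ranking table + figure; optionally written to disk."""
    if len(results.fits) < 2:
        raise ValueError("need fits at >= 2 quantiles to report curves")
    curves = results.frame()
    ranking = results.ranking_table(features)
    fig = results.plot_coefficient_curves(features)
    if outdir is not None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        curves.to_csv(out / "coefficient_curves.csv", index=False)
        ranking.to_csv(out / "ranking.csv", index=False)
        fig.savefig(out / "coefficient_curves.png", dpi=150)
    return curves, ranking, fig
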