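"""Compressibility from the pressure dependence of the IDF, and comparisons.

The IDF center and width are linear in pressure,

    center(p) = nu00 + (2 kappa nu0s) p,
    sigma(p)  = sigma0 + (2 kappa sigma0) p,

so straight-line fits of the per-pressure IDF estimates give kappa.  The
width trend alone determines kappa (slope / (2 x intercept)) without any
knowledge of the vacuum frequency; the center trend then yields the matrix
shift estimate nu0s = slope_c / (2 kappa), or a second kappa estimator when
nu0s is supplied independently.  Standard deviations come from the
weighted-least-squares slope/intercept covariance by the delta method, with
the covariance scale never shrunk below the chi-square estimate
(max(1, chi2/dof)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .extraction import IDFEstimate

__all__ = [
    "PressureSeries",
    "LinearFit",
    "CompressibilityResult",
    "fit_compressibility",
    "compare_conditions",
]


@dataclass(frozen=True)
class PressureSeries:
    """IDF estimates across >= 3 distinct pressures within the cell range."""

    estimates: tuple[IDFEstimate, ...]
    pressure_range: tuple[float, float] = (0.0, 1.5)

    def __post_init__(self) -> None:
        est = tuple(sorted(self.estimates, key=lambda e: e.pressure))
        object.__setattr__(self, "estimates", est)
        pressures = [e.pressure for e in est]
        if len(set(pressures)) < 3:
            raise ValueError(f"need >= 3 distinct pressures, got {sorted(set(pressures))}")
        lo, hi = self.pressure_range
        if min(pressures) < lo or max(pressures) > hi:
            raise ValueError(
                f"pressures {pressures} outside the cell range {self.pressure_range} GPa"
            )

    @property
    def pressures(self) -> np.ndarray:
        return np.array([e.pressure for e in self.estimates])


@dataclass(frozen=True)
class LinearFit:
    """Straight-line fit y = intercept + slope * p with its 2x2 covariance."""

    slope: float
    intercept: float
    cov: np.ndarray  # [[var_i, cov_is], [cov_is, var_s]]
    r_squared: float
    chi2: float
    n: int
    weighted: bool

    @property
    def slope_sd(self) -> float:
        return math.sqrt(max(self.cov[1, 1], 0.0))

    @property
    def intercept_sd(self) -> float:
        return math.sqrt(max(self.cov[0, 0], 0.0))


def _linear_fit(x: np.ndarray, y: np.ndarray, se: np.ndarray | None) -> LinearFit:
    """WLS (weights 1/SE^2) when usable SEs are given, else OLS.

    Covariance = scale * (X'WX)^-1 with scale = max(1, chi2/dof) for WLS and
    scale = RSS/dof for OLS.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    weighted = se is not None and np.all(np.isfinite(se)) and np.all(np.asarray(se) > 0)
    w = 1.0 / np.asarray(se, dtype=float) ** 2 if weighted else np.ones(n)
    X = np.column_stack([np.ones(n), x])
    xtwx = X.T @ (w[:, None] * X)
    if abs(np.linalg.det(xtwx)) <= 0 or not np.all(np.isfinite(xtwx)):
        raise ValueError("singular design: pressures do not span a line")
    xtwx_inv = np.linalg.inv(xtwx)
    beta = xtwx_inv @ (X.T @ (w * y))
    resid = y - X @ beta
    chi2 = float(np.sum(w * resid**2))
    dof = max(n - 2, 1)
    scale = max(1.0, chi2 / dof) if weighted else chi2 / dof
    cov = xtwx_inv * scale
    wmean = float(np.sum(w * y) / np.sum(w))
    ss_tot = float(np.sum(w * (y - wmean) ** 2))
    r2 = 1.0 - chi2 / ss_tot if ss_tot > 0 else float("nan")
    return LinearFit(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        cov=cov,
        r_squared=r2,
        chi2=chi2,
        n=n,
        weighted=bool(weighted),
    )


def _jackknife_kappa_sd(
    p: np.ndarray, sig: np.ndarray, sig_se: np.ndarray | None
) -> float:
    """Leave-one-pressure-out jackknife SD of kappa_width."""
    n = p.size
    if n < 4:
        return 0.0
    values = []
    for i in range(n):
        mask = np.arange(n) != i
        if len(set(p[mask])) < 3:
            continue
        try:
            fit = _linear_fit(p[mask], sig[mask], None if sig_se is None else sig_se[mask])
        except ValueError:
            continue
        if fit.intercept > 0:
            values.append(fit.slope / (2.0 * fit.intercept))
    if len(values) < 3:
        return 0.0
    values = np.asarray(values)
    m = len(values)
    return float(np.sqrt((m - 1) / m * np.sum((values - values.mean()) ** 2)))


@dataclass(frozen=True)
class CompressibilityResult:
    """kappa with uncertainty for one condition, plus regression diagnostics."""

    kappa_width: float
    kappa_width_sd: float
    kappa_combined: float
    kappa_combined_sd: float
    solvent_shift_est: float
    solvent_shift_sd: float
    width_fit: LinearFit
    center_fit: LinearFit
    kappa_center: float | None = None
    kappa_center_sd: float | None = None
    n_pressures: int = 0

    def as_row(self, sample: str = "", effectors: str = "") -> dict:
        return {
            "sample": sample,
            "effectors": effectors,
            "kappa": self.kappa_combined,
            "kappa_sd": self.kappa_combined_sd,
            "kappa_width": self.kappa_width,
            "kappa_width_sd": self.kappa_width_sd,
            "solvent_shift_est": self.solvent_shift_est,
            "solvent_shift_sd": self.solvent_shift_sd,
            "n_pressures": self.n_pressures,
            "width_r2": self.width_fit.r_squared,
            "center_r2": self.center_fit.r_squared,
        }


def fit_compressibility(
    series: PressureSeries,
    nu0s: float | None = None,
    use_se_weights: bool = True,
) -> CompressibilityResult:
    """Estimate kappa from the pressure trends of IDF width and center.

    Width trend: kappa_width = slope / (2 * intercept); needs no vacuum
    frequency.  Center trend: solvent-shift estimate
    nu0s_est = slope_c / (2 * kappa_width); when an independent ``nu0s`` is
    supplied the center trend yields a second estimator
    kappa_center = slope_c / (2 * nu0s) and kappa_combined is the
    inverse-variance mean of the two, otherwise kappa_combined equals
    kappa_width.  SDs are first-order (delta-method) propagations; the small
    covariance between the two estimators (they share the underlying
    spectra) is neglected.
    """
    p = series.pressures
    sig = np.array([e.sigma for e in series.estimates])
    sig_se = np.array([e.sigma_se for e in series.estimates])
    cen = np.array([e.center for e in series.estimates])
    cen_se = np.array([e.center_se for e in series.estimates])
    if not use_se_weights:
        sig_se = cen_se = None

    width_fit = _linear_fit(p, sig, sig_se)
    if width_fit.intercept <= 0:
        raise ValueError(
            f"width intercept sigma0 = {width_fit.intercept:.3g} must be positive"
        )
    b0, b1 = width_fit.intercept, width_fit.slope
    kappa_w = b1 / (2.0 * b0)
    grad = np.array([-b1 / (2.0 * b0**2), 1.0 / (2.0 * b0)])
    kappa_w_sd = float(np.sqrt(max(grad @ width_fit.cov @ grad, 0.0)))
    # reported SD is the one-sigma-equivalent (68.3%) interval half-width:
    # with few pressures the estimated SE needs the small-sample t quantile
    kappa_w_sd *= float(stats.t.ppf(0.841345, max(width_fit.n - 2, 1)))
    # the within-fit covariance also misses between-pressure systematics of
    # the spectral evaluation; never report less than the jackknife estimate
    kappa_w_sd = max(kappa_w_sd, _jackknife_kappa_sd(p, sig, sig_se))

    center_fit = _linear_fit(p, cen, cen_se)
    slope_c = center_fit.slope
    var_sc = center_fit.cov[1, 1]
    if kappa_w != 0:
        nu0s_est = slope_c / (2.0 * kappa_w)
        var_nu0s = var_sc / (2.0 * kappa_w) ** 2 + (
            slope_c / (2.0 * kappa_w**2)
        ) ** 2 * kappa_w_sd**2
        nu0s_sd = math.sqrt(max(var_nu0s, 0.0))
    else:
        nu0s_est, nu0s_sd = float("nan"), float("nan")

    kappa_c = kappa_c_sd = None
    if nu0s is not None:
        if nu0s == 0:
            raise ValueError("nu0s must be nonzero for the center estimator")
        kappa_c = slope_c / (2.0 * nu0s)
        kappa_c_sd = math.sqrt(max(var_sc, 0.0)) / (2.0 * abs(nu0s))

    if kappa_c is not None:
        w_w = 1.0 / max(kappa_w_sd, 1e-12) ** 2
        w_c = 1.0 / max(kappa_c_sd, 1e-12) ** 2
        kappa_comb = (w_w * kappa_w + w_c * kappa_c) / (w_w + w_c)
        kappa_comb_sd = math.sqrt(1.0 / (w_w + w_c))
    else:
        kappa_comb, kappa_comb_sd = kappa_w, kappa_w_sd

    return CompressibilityResult(
        kappa_width=kappa_w,
        kappa_width_sd=kappa_w_sd,
        kappa_combined=kappa_comb,
        kappa_combined_sd=kappa_comb_sd,
        solvent_shift_est=nu0s_est,
        solvent_shift_sd=nu0s_sd,
        width_fit=width_fit,
        center_fit=center_fit,
        kappa_center=kappa_c,
        kappa_center_sd=kappa_c_sd,
        n_pressures=int(p.size),
    )


def _condition_key(row: pd.Series) -> str:
    return f"{row['sample']}|{row['effectors']}"


def compare_conditions(
    results: pd.DataFrame,
    effector_strengths: dict[str, float] | None = None,
    kappa_grid: np.ndarray | None = None,
) -> dict[str, pd.DataFrame]:
    """Pairwise condition comparison and optional effector-strength correlation.

    ``results`` must carry one row per condition with columns sample,
    effectors, kappa, kappa_sd.  Returns pairwise two-sided normal
    z-statistics (|k1 - k2| / sqrt(sd1^2 + sd2^2)), unit-height Gaussian
    summary curves (center kappa, width kappa_sd) for plotting, and -- when
    ``effector_strengths`` maps effector labels to user-supplied strength
    scores -- the per-sample Pearson correlation between the
    effector-induced kappa decrease and those scores.  The pairwise p-values
    are raw (no multiplicity correction); the output header of the CLI notes
    this.
    """
    required = {"sample", "effectors", "kappa", "kappa_sd"}
    if not required.issubset(results.columns):
        raise ValueError(f"results table needs columns {sorted(required)}")
    if len(results) < 2:
        raise ValueError("need >= 2 conditions to compare")
    if results.duplicated(subset=["sample", "effectors"]).any():
        raise ValueError("duplicate (sample, effectors) rows")

    rows = []
    recs = results.to_dict("records")
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            a, b = recs[i], recs[j]
            denom = math.hypot(a["kappa_sd"], b["kappa_sd"])
            z = abs(a["kappa"] - b["kappa"]) / denom if denom > 0 else math.inf
            rows.append(
                {
                    "sample_1": a["sample"],
                    "effectors_1": a["effectors"],
                    "sample_2": b["sample"],
                    "effectors_2": b["effectors"],
                    "delta_kappa": a["kappa"] - b["kappa"],
                    "z": z,
                    "p_value": 2.0 * stats.norm.sf(z) if math.isfinite(z) else 0.0,
                }
            )
    pairwise = pd.DataFrame(rows)

    if kappa_grid is None:
        kappa_grid = np.linspace(-0.1, 0.7, 401)
    curve_rows = []
    for rec in recs:
        dens = np.exp(-0.5 * ((kappa_grid - rec["kappa"]) / rec["kappa_sd"]) ** 2)
        for k, d in zip(kappa_grid, dens):
            curve_rows.append(
                {
                    "sample": rec["sample"],
                    "effectors": rec["effectors"],
                    "kappa": k,
                    "density": d,
                }
            )
    curves = pd.DataFrame(curve_rows)

    correlations = pd.DataFrame(
        columns=["sample", "r", "n_effectors"]
    )
    if effector_strengths:
        corr_rows = []
        for sample, grp in results.groupby("sample"):
            base = grp.loc[grp["effectors"] == "none", "kappa"]
            if base.empty:
                continue
            k0 = float(base.iloc[0])
            deltas, strengths = [], []
            for _, row in grp.iterrows():
                eff = row["effectors"]
                if eff == "none" or eff not in effector_strengths:
                    continue
                deltas.append(k0 - float(row["kappa"]))
                strengths.append(float(effector_strengths[eff]))
            if len(deltas) >= 2:
                r = float(stats.pearsonr(deltas, strengths).statistic)
                corr_rows.append({"sample": sample, "r": r, "n_effectors": len(deltas)})
        if corr_rows:
            correlations = pd.DataFrame(corr_rows)

    return {"pairwise": pairwise, "curves": curves, "correlations": correlations}
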