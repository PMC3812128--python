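"""Fixed-form trend regressions: polynomial (L, Q, C) and linear-plus-plateau.

The polynomial models are ordinary least squares on the internal time index
T.  The linear-plus-plateau (LP) model rises at a constant rate R up to a
break date T* and is flat at Ymax thereafter; continuity at the break is
enforced by construction.  LP is fitted by profiling the residual sum of
squares over candidate integer break dates (solving the conditionally
linear parameters exactly at each) and refining the best candidate with a
bounded nonlinear least-squares step.  Non-convergence — typically because
the series has no plateau, so the break date is unidentifiable — is a
reportable status, not an exception, so panel runs can count failures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import f as f_distribution

from .data_io import YieldSeries

__all__ = [
    "FitError",
    "PlateauFit",
    "PolynomialFit",
    "fit_linear_plateau",
    "fit_polynomial",
    "plateau_curve",
    "residual_autocorrelation",
]


class FitError(ValueError):
    """A model cannot be fitted to the series (too few points, singular design)."""


@dataclass
class PolynomialFit:
    """OLS polynomial trend of degree 1 (L), 2 (Q) or 3 (C).

    ``coefficients`` are (a, b[, c[, d]]) in increasing powers of T, i.e.
    the fitted trend is a + b·T + c·T² + d·T³.
    """

    degree: int
    coefficients: np.ndarray
    t: np.ndarray          # time indices of the non-missing observations
    fitted: np.ndarray
    residuals: np.ndarray
    sigma: float
    converged: bool = True

    def predict(self, t_index) -> np.ndarray | float:
        t = np.asarray(t_index, dtype=float)
        out = np.polynomial.polynomial.polyval(t, self.coefficients)
        return float(out) if np.isscalar(t_index) else out

    @property
    def rss(self) -> float:
        return float(self.residuals @ self.residuals)


@dataclass
class PlateauFit:
    """Linear-plus-plateau trend: rises at rate R until T*, flat at Ymax after.

    When ``converged`` is False the numeric fields are None: the series gave
    the optimizer no identifiable plateau.
    """

    converged: bool
    ymax: float | None = None
    t_break: float | None = None
    rate: float | None = None
    t: np.ndarray | None = None
    fitted: np.ndarray | None = None
    residuals: np.ndarray | None = None
    sigma: float | None = None
    message: str = ""

    def predict(self, t_index) -> np.ndarray | float:
        if not self.converged:
            raise FitError("cannot predict from an unconverged linear-plus-plateau fit")
        out = plateau_curve(np.asarray(t_index, dtype=float), self.ymax, self.t_break, self.rate)
        return float(out) if np.isscalar(t_index) else out

    @property
    def rss(self) -> float:
        if not self.converged:
            raise FitError("unconverged fit has no residuals")
        return float(self.residuals @ self.residuals)


def plateau_curve(t, ymax: float, t_break: float, rate: float):
    """Evaluate the continuous broken line Ymax + R·min(T − T*, 0)."""
    t = np.asarray(t, dtype=float)
    return ymax + rate * np.minimum(t - t_break, 0.0)


def fit_polynomial(series: YieldSeries, degree: int) -> PolynomialFit:
    """Least-squares polynomial trend of the given degree on (T, Y)."""
    if degree not in (1, 2, 3):
        raise ValueError(f"degree must be 1, 2 or 3, got {degree}")
    t, y = series.observed()
    n, p = t.size, degree + 1
    if n < p + 1:
        raise FitError(
            f"{series.unit_id}: degree-{degree} fit needs ≥ {p + 1} observations, have {n}"
        )
    # Vandermonde solve via lstsq; T is strictly increasing so the design
    # has full column rank for degree ≤ 3 and n ≥ 4.
    X = np.vander(t.astype(float), p, increasing=True)
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise FitError(f"{series.unit_id}: singular design matrix")
    # one step of iterative refinement: the cubic Vandermonde is poorly
    # conditioned enough to cost a few digits in a single lstsq pass
    r = (y.astype(np.longdouble) - X.astype(np.longdouble) @ coef).astype(float)
    coef = coef + np.linalg.lstsq(X, r, rcond=None)[0]
    fitted = X @ coef
    resid = y - fitted
    sigma = float(np.sqrt(resid @ resid / max(n - p, 1)))
    return PolynomialFit(degree, coef, t, fitted, resid, sigma)


def _profile_plateau_rss(t: np.ndarray, y: np.ndarray, t_break: float):
    """Exact OLS of (Ymax, R) for a fixed break date; returns (rss, ymax, rate)."""
    x = np.minimum(t - t_break, 0.0)
    X = np.column_stack([np.ones_like(x), x])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 2:  # break before all data: pure constant, rate unidentified
        return np.inf, np.nan, np.nan
    resid = y - X @ coef
    return float(resid @ resid), float(coef[0]), float(coef[1])


def fit_linear_plateau(
    series: YieldSeries,
    init_grid: np.ndarray | None = None,
    *,
    min_plateau_span: float = 5.0,
    f_crit_quantile: float = 0.99,
) -> PlateauFit:
    """Fit the linear-plus-plateau model by grid profiling plus refinement.

    The fit is declared unconverged (not an error) when the break date is
    unidentifiable, which covers three situations: the optimizer fails or
    its curvature at the optimum is degenerate; the refined break leaves
    ``[T_min, T_max - min_plateau_span]`` (a plateau supported by fewer
    than ~5 years of data is indistinguishable from noise at the end of a
    rising series); or the broken line does not beat the nested pure-line
    fit at the ``f_crit_quantile`` level of the F(1, n−3) reference (a
    series without a plateau is explained equally well by the line, so the
    break date carries no information).
    """
    t, y = series.observed()
    if t.size < 6:
        raise FitError(f"{series.unit_id}: linear-plus-plateau fit needs ≥ 6 observations")
    t = t.astype(float)

    if init_grid is None:
        # every observed T from the 3rd to the (M-2)-th point
        init_grid = t[2:-2]
    profiles = [(_profile_plateau_rss(t, y, tb), tb) for tb in np.asarray(init_grid, dtype=float)]
    (rss0, ymax0, rate0), tb0 = min(profiles, key=lambda pr: pr[0][0])
    if not np.isfinite(rss0):
        return PlateauFit(False, message="profile search found no valid break date")

    lo, hi = float(t[0]), float(t[-1])

    def resid_fn(params):
        ymax, tb, rate = params
        return plateau_curve(t, ymax, tb, rate) - y

    sol = least_squares(
        resid_fn,
        x0=[ymax0, tb0, rate0],
        bounds=([-np.inf, lo - 5.0, -np.inf], [np.inf, hi + 5.0, np.inf]),
        xtol=1e-12,
        ftol=1e-12,
    )
    if not sol.success:
        return PlateauFit(False, message=f"optimizer failure: {sol.message}")
    ymax, t_break, rate = map(float, sol.x)

    if not (lo <= t_break <= hi - min_plateau_span):
        return PlateauFit(
            False,
            message=f"break date {t_break:.2f} outside [{lo:.0f}, {hi - min_plateau_span:.0f}]: no plateau",
        )
    # Degenerate curvature in the break direction means the plateau carries
    # no information about T*; JᵀJ then loses rank.
    jtj = sol.jac.T @ sol.jac
    if np.linalg.cond(jtj) > 1e10:
        return PlateauFit(False, message="degenerate curvature at optimum (break unidentifiable)")

    fitted = plateau_curve(t, ymax, t_break, rate)
    resid = y - fitted
    # identifiability: the broken line must improve decisively on the pure line
    X = np.column_stack([np.ones_like(t), t])
    line_resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    rss_lp = float(resid @ resid)
    rss_line = float(line_resid @ line_resid)
    dof = t.size - 3
    if rss_lp > 0:
        f_stat = (rss_line - rss_lp) / (rss_lp / dof)
        if f_stat < f_distribution.ppf(f_crit_quantile, 1, dof):
            return PlateauFit(
                False,
                message=f"no plateau signal: F={f_stat:.2f} vs pure line (break unidentifiable)",
            )
    sigma = float(np.sqrt(resid @ resid / max(t.size - 3, 1)))
    return PlateauFit(True, ymax, t_break, rate, t, fitted, resid, sigma)


def residual_autocorrelation(fit, max_lag: int) -> dict:
    """Sample autocorrelations of the fit residuals with a white-noise band.

    Returns ``{"lags", "acf", "band"}`` where ``band`` is the ±1.96/√M
    bound under the independence null.  Used to check the regression
    models' assumption of independent errors.
    """
    resid = np.asarray(fit.residuals if hasattr(fit, "residuals") else fit, dtype=float)
    m = resid.size
    if m < max_lag + 5:
        raise ValueError(f"need ≥ {max_lag + 5} residuals for {max_lag} lags, have {m}")
    centered = resid - resid.mean()
    denom = float(centered @ centered)
    if denom == 0.0:
        raise ValueError("residuals are constant: autocorrelation undefined")
    lags = np.arange(1, max_lag + 1)
    acf = np.array([float(centered[l:] @ centered[:-l]) / denom for l in lags])
    return {"lags": lags, "acf": acf, "band": 1.96 / np.sqrt(m)}
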