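"""Goodness-of-fit and rolling-origin forecast evaluation.

Two statistics drive the model comparison:

* RMSE — in-sample root mean square error of a trend fitted to the whole
  series (state-space models contribute their smoothed level; the
  Holt-Winters forecasters have no in-sample trend and are excluded).
* RMSEP — root mean square error of k-year-ahead out-of-sample forecasts
  under a rolling-origin protocol: for each target year t in an evaluation
  window, the model is refitted from scratch on all data up to t − k and
  its k-step forecast compared to the observation at t.

Per-unit statistics are averaged arithmetically over the units of a panel
(a pooled-error alternative is available), and percent differences are
taken against the best model per (statistic, horizon) group:
difference = 100·(value − min)/min.

The linear-plus-plateau model is excluded from RMSEP: its refits fail to
converge on plateau-free training windows, so no honest forecast path
exists.  Refitting at every origin is mandatory, but because the fit of a
model to a given training window is deterministic, fits are memoized by
(unit, model, training-end year) — a pure-function cache, not state
leakage across origins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_io import DataError, YieldPanel, YieldSeries
from .regression import FitError, fit_linear_plateau, fit_polynomial
from .smoothing import fit_holt_winters, hw_forecast
from .state_space import fit_dlm, forecast_from_series

__all__ = [
    "EvaluationError",
    "ForecastPoint",
    "MODEL_NAMES",
    "default_window",
    "dlms_vs_dlm0_winrate",
    "insample_rmse",
    "panel_evaluate",
    "rmse",
    "rolling_rmsep",
]

MODEL_NAMES = ("L", "Q", "C", "LP", "HW0", "HWs", "DLM0", "DLMs")

#: minimum non-missing training observations per model
_MIN_OBS = {"L": 3, "Q": 4, "C": 5, "LP": 6, "HW0": 4, "HWs": 4, "DLM0": 5, "DLMs": 8}

_POLY_DEGREE = {"L": 1, "Q": 2, "C": 3}


class EvaluationError(ValueError):
    """The evaluation protocol cannot be honored (window/model mismatch)."""


@dataclass(frozen=True)
class ForecastPoint:
    """One rolling-origin forecast with its training-window endpoint."""

    unit_id: str
    target_year: int
    horizon: int
    predicted: float
    observed: float
    train_end_year: int


def rmse(observed, fitted) -> float:
    """Root mean square difference over paired non-missing values."""
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape:
        raise ValueError("observed and fitted must have equal length")
    mask = np.isfinite(obs) & np.isfinite(fit)
    if not mask.any():
        raise ValueError("no paired non-missing values")
    d = obs[mask] - fit[mask]
    return float(np.sqrt(d @ d / d.size))


def default_window(series: YieldSeries, n: int = 20) -> list[int]:
    """The final ``n`` calendar years of the series (the evaluation window)."""
    return [int(y) for y in series.years[-n:]]


def _check_min_obs(series: YieldSeries, model: str) -> None:
    need = _MIN_OBS[model]
    if series.n_obs < need:
        raise EvaluationError(
            f"{series.unit_id}: model {model} needs ≥ {need} observations, "
            f"training set up to {series.years[-1]} has {series.n_obs}"
        )


def _fit_for_forecast(series: YieldSeries, model: str, n_starts: int):
    """Fit one model on a training series; the return value forecasts later."""
    if model in _POLY_DEGREE:
        return fit_polynomial(series, _POLY_DEGREE[model])
    if model in ("HW0", "HWs"):
        return fit_holt_winters(series, model)
    if model in ("DLM0", "DLMs"):
        order = 0 if model == "DLM0" else 1
        spec, _ = fit_dlm(series, order, n_starts=n_starts, return_smoother=False)
        return spec
    raise EvaluationError(
        "RMSEP is undefined for LP (refits diverge on plateau-free windows)"
        if model == "LP" else f"unknown model {model!r}"
    )


def _forecast(fitted, train: YieldSeries, model: str, target_t: int, horizon: int) -> float:
    if model in _POLY_DEGREE:
        return float(fitted.predict(target_t))
    if model in ("HW0", "HWs"):
        return float(hw_forecast(fitted, horizon))
    mean, _ = forecast_from_series(train, fitted, horizon)
    return mean


def rolling_rmsep(
    series: YieldSeries,
    model: str,
    k: int,
    target_years: Sequence[int] | None = None,
    *,
    n_starts: int = 3,
    fit_cache: dict | None = None,
) -> tuple[float, list[ForecastPoint]]:
    """Rolling-origin k-year-ahead RMSEP of one model on one series.

    For every target year t in the window the model is refitted on all data
    up to t − k and forecasts k steps ahead.  Target years whose training
    set is too small raise :class:`EvaluationError` naming the year; target
    years whose own observation is missing are dropped from the average.
    """
    if k < 1:
        raise ValueError(f"horizon must be ≥ 1, got {k}")
    if model == "LP":
        raise EvaluationError("RMSEP is undefined for LP (refits diverge on plateau-free windows)")
    if target_years is None:
        target_years = default_window(series)
    cache = fit_cache if fit_cache is not None else {}

    points: list[ForecastPoint] = []
    year_to_value = dict(zip(series.years.tolist(), series.yields.tolist()))
    for t_year in target_years:
        train = series.truncate(t_year - k)
        if train.n_obs < _MIN_OBS[model]:
            raise EvaluationError(
                f"{series.unit_id}: target year {t_year} at horizon {k}: training set "
                f"up to {t_year - k} has {train.n_obs} observations but model {model} "
                f"needs ≥ {_MIN_OBS[model]}"
            )
        if train.years[-1] != t_year - k:
            raise EvaluationError(
                f"{series.unit_id}: no training data ending at {t_year - k} for target {t_year}"
            )
        key = (series.unit_id, model, int(train.years[-1]))
        if key not in cache:
            cache[key] = _fit_for_forecast(train, model, n_starts)
        target_t = series.t_of_year(t_year)
        horizon = int(t_year - train.years[-1])
        pred = _forecast(cache[key], train, model, target_t, horizon)
        obs = year_to_value.get(t_year, float("nan"))
        if np.isfinite(obs):
            points.append(ForecastPoint(series.unit_id, int(t_year), k, pred, float(obs),
                                        int(train.years[-1])))
    if not points:
        raise EvaluationError(f"{series.unit_id}: no observed target years in the window")
    value = rmse([p.observed for p in points], [p.predicted for p in points])
    return value, points


def insample_rmse(series: YieldSeries, model: str, *, n_starts: int = 5) -> float:
    """In-sample RMSE of one model fitted to the whole series."""
    _check_min_obs(series, model)
    t, y = series.observed()
    if model in _POLY_DEGREE:
        return rmse(y, fit_polynomial(series, _POLY_DEGREE[model]).fitted)
    if model == "LP":
        fit = fit_linear_plateau(series)
        if not fit.converged:
            raise FitError(f"{series.unit_id}: LP did not converge ({fit.message})")
        return rmse(y, fit.fitted)
    if model in ("DLM0", "DLMs"):
        order = 0 if model == "DLM0" else 1
        spec, smooth = fit_dlm(series, order, n_starts=n_starts)
        mask = np.isfinite(series.yields)
        return rmse(series.yields[mask], smooth.level_mean[mask])
    raise EvaluationError(f"model {model} has no in-sample trend (forecast-only)")


def panel_evaluate(
    panel: YieldPanel,
    models: Iterable[str] = ("L", "Q", "C", "DLM0", "DLMs", "HW0", "HWs"),
    horizons: Iterable[int] = range(1, 11),
    target_years: Sequence[int] | None = None,
    *,
    include_rmse: bool = True,
    n_starts: int = 3,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Panel-level RMSE/RMSEP comparison table.

    Statistics are computed per unit and averaged over units (``aggregate
    = "mean"``, the default) or pooled over all forecast errors
    (``"pooled"``).  Horizon 0 rows hold in-sample RMSE.  Units where a
    model cannot be fitted are excluded from that model's average and the
    surviving count reported as ``n_units``.
    """
    if aggregate not in ("mean", "pooled"):
        raise ValueError("aggregate must be 'mean' or 'pooled'")
    models = list(models)
    unknown = [m for m in models if m not in MODEL_NAMES]
    if unknown:
        raise ValueError(f"unknown models {unknown}; valid: {MODEL_NAMES}")
    rows = []
    cache: dict = {}

    if include_rmse:
        for model in models:
            if model in ("HW0", "HWs"):
                continue  # forecast-only models have no in-sample trend
            vals = []
            for s in panel:
                try:
                    vals.append(insample_rmse(s, model))
                except (FitError, DataError, EvaluationError, ValueError):
                    continue
            if vals:
                rows.append((panel.label, model, "RMSE", 0, float(np.mean(vals)), len(vals)))

    for k in horizons:
        for model in models:
            if model == "LP":
                continue
            vals, pooled = [], []
            for s in panel:
                window = target_years if target_years is not None else default_window(s)
                try:
                    v, pts = rolling_rmsep(s, model, k, window, n_starts=n_starts,
                                           fit_cache=cache)
                except (FitError, DataError, EvaluationError, ValueError):
                    continue
                vals.append(v)
                pooled.extend((p.observed - p.predicted) ** 2 for p in pts)
            if vals:
                value = (float(np.mean(vals)) if aggregate == "mean"
                         else float(np.sqrt(np.mean(pooled))))
                rows.append((panel.label, model, "RMSEP", int(k), value, len(vals)))

    table = pd.DataFrame(
        rows, columns=["dataset", "model", "statistic", "horizon", "value", "n_units"]
    )
    if len(table):
        group_min = table.groupby(["dataset", "statistic", "horizon"])["value"].transform("min")
        table["pct_difference_vs_min"] = 100.0 * (table["value"] - group_min) / group_min
    else:
        table["pct_difference_vs_min"] = pd.Series(dtype=float)
    return table[["dataset", "model", "statistic", "horizon", "value",
                  "pct_difference_vs_min", "n_units"]]


def _lower_median(values: np.ndarray) -> float:
    """Median taking the lower central value for even counts (ties go low)."""
    s = np.sort(values)
    return float(s[(s.size - 1) // 2])


def dlms_vs_dlm0_winrate(
    panel: YieldPanel,
    horizons: Iterable[int] = (1, 10),
    target_years: Sequence[int] | None = None,
    *,
    n_starts: int = 3,
) -> pd.DataFrame:
    """Share of units where the trend DLM out-predicts the random-walk DLM.

    For each horizon k the per-unit RMSEPs of the two state-space models
    are compared; the overall win rate is the percentage of units where the
    local-linear-trend model is strictly more accurate.  Units are also
    stratified by their final-year smoothed yield-increase rate relative to
    the cross-unit median (ties to the low stratum): fast-improving regions
    are where the trend model should earn its keep.
    """
    if len(panel) < 2:
        raise ValueError("win-rate stratification needs at least 2 units")
    cache: dict = {}
    slopes: dict[str, float] = {}
    for s in panel:
        _, smooth = fit_dlm(s, order=1, n_starts=n_starts)
        slopes[s.unit_id] = float(smooth.slope_mean[-1])
    median = _lower_median(np.array(list(slopes.values())))

    rows = []
    for k in horizons:
        wins = {}
        for s in panel:
            window = target_years if target_years is not None else default_window(s)
            try:
                v_s, _ = rolling_rmsep(s, "DLMs", k, window, n_starts=n_starts, fit_cache=cache)
                v_0, _ = rolling_rmsep(s, "DLM0", k, window, n_starts=n_starts, fit_cache=cache)
            except (DataError, EvaluationError, ValueError):
                continue
            wins[s.unit_id] = v_s < v_0
        if not wins:
            raise EvaluationError("no unit supported both state-space models")
        high = [u for u in wins if slopes[u] > median]
        low = [u for u in wins if slopes[u] <= median]
        pct = lambda ids: 100.0 * np.mean([wins[u] for u in ids]) if ids else float("nan")
        rows.append((int(k), pct(list(wins)), pct(low), pct(high),
                     len(wins), len(low), len(high)))
    return pd.DataFrame(
        rows,
        columns=["horizon", "overall_pct", "low_rate_pct", "high_rate_pct",
                 "n_units", "n_low", "n_high"],
    )
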