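"""Non-seasonal Holt-Winters forecasters.

Two variants: simple exponential smoothing (HW0, level only, flat
forecasts) and Holt's linear-trend method (HWs, level + slope, forecasts
affine in the horizon).  The smoothing constants are chosen to minimize
the sum of squared one-step-ahead in-sample forecast errors, accumulated
from the third observation onward so the initialization (level at y₁,
slope at y₂ − y₁) is not rewarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .data_io import YieldSeries

__all__ = ["HoltWintersState", "fit_holt_winters", "hw_forecast", "hw_init", "hw_update", "one_step_sse"]


@dataclass
class HoltWintersState:
    """Running state of a Holt-Winters recursion.

    ``beta is None`` marks the HW0 (no-trend) variant, whose slope stays 0.
    ``history`` records (level, slope) after each processed observation.
    """

    alpha: float
    beta: float | None
    level: float
    slope: float
    n_obs: int = 0
    history: list = field(default_factory=list)
    sse: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        if self.beta is not None and not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must lie in [0, 1], got {self.beta}")
        if self.beta is None and self.slope != 0.0:
            raise ValueError("the no-trend variant must have zero slope")

    @property
    def variant(self) -> str:
        return "HW0" if self.beta is None else "HWs"


def hw_init(y1: float, y2: float | None, alpha: float, beta: float | None) -> HoltWintersState:
    """Initial state: level at the first observation, slope at y₂ − y₁ (HWs)."""
    if beta is None:
        state = HoltWintersState(alpha, None, float(y1), 0.0, n_obs=1)
    else:
        if y2 is None or not np.isfinite(y2):
            raise ValueError("the trend variant needs two observations to initialize")
        state = HoltWintersState(alpha, beta, float(y2), float(y2 - y1), n_obs=2)
    state.history.append((state.level, state.slope))
    return state


def hw_update(state: HoltWintersState, y: float) -> HoltWintersState:
    """Process one new observation (in place; the state is also returned).

    A missing (NaN) observation carries the state forward along its own
    one-step forecast, so the calendar axis stays aligned.
    """
    if y is not None and np.isinf(y):
        raise ValueError("observation must be finite or NaN")
    prev_level, prev_slope = state.level, state.slope
    forecast = prev_level + prev_slope
    if y is None or np.isnan(y):
        state.level = forecast
    elif state.beta is None:
        state.level = state.alpha * y + (1.0 - state.alpha) * prev_level
    else:
        state.level = state.alpha * y + (1.0 - state.alpha) * forecast
        state.slope = state.beta * (state.level - prev_level) + (1.0 - state.beta) * prev_slope
    state.n_obs += 1
    state.history.append((state.level, state.slope))
    return state


def hw_forecast(state: HoltWintersState, k: int) -> float:
    """k-step-ahead forecast: level + k·slope (flat in k for HW0)."""
    if k < 1:
        raise ValueError(f"forecast horizon must be ≥ 1, got {k}")
    min_obs = 1 if state.beta is None else 2
    if state.n_obs < min_obs:
        raise ValueError("state has not processed enough observations to forecast")
    return state.level + k * state.slope


def _run_recursion(y: np.ndarray, alpha: float, beta: float | None) -> tuple[HoltWintersState, float]:
    """Run the full recursion over a series; returns (state, one-step SSE).

    The SSE accumulates (y_t − forecast)² from the third observation on.
    """
    if beta is None:
        state = hw_init(y[0], None, alpha, beta)
        start = 1
    else:
        state = hw_init(y[0], y[1], alpha, beta)
        start = 2
    sse = 0.0
    for i in range(start, y.size):
        if i >= 2 and np.isfinite(y[i]):
            err = y[i] - (state.level + state.slope)
            sse += err * err
        hw_update(state, y[i])
    return state, sse


def one_step_sse(series: YieldSeries, alpha: float, beta: float | None) -> float:
    """Sum of squared one-step in-sample forecast errors at fixed constants."""
    _, sse = _run_recursion(series.yields, alpha, beta)
    return sse


def fit_holt_winters(series: YieldSeries, variant: str = "HWs") -> HoltWintersState:
    """Optimize the smoothing constants and return the final fitted state.

    The objective is bounded on [0,1] (HW0) or [0,1]² (HWs) and multimodal
    near zero, so the bounded optimizer is restarted from a coarse grid and
    the best solution kept.  ``state.sse`` holds the achieved objective.
    """
    if variant not in ("HW0", "HWs"):
        raise ValueError(f"variant must be 'HW0' or 'HWs', got {variant!r}")
    y = series.yields
    if np.isfinite(y).sum() < 4:
        raise ValueError(f"{series.unit_id}: Holt-Winters fit needs ≥ 4 observations")
    if not np.isfinite(y[0]) or (variant == "HWs" and not np.isfinite(y[1])):
        raise ValueError(f"{series.unit_id}: the first two observations must be present")

    if variant == "HW0":
        def obj(a):
            return _run_recursion(y, float(a), None)[1]

        sol = minimize_scalar(obj, bounds=(0.0, 1.0), method="bounded",
                              options={"xatol": 1e-10})
        best_a, best_val = float(sol.x), float(sol.fun)
        for a0 in (0.05, 0.3, 0.7, 0.95):  # guard against the flat region near 0
            v = obj(a0)
            if v < best_val:
                best_a, best_val = a0, v
        state, sse = _run_recursion(y, best_a, None)
    else:
        def obj(x):
            return _run_recursion(y, float(x[0]), float(x[1]))[1]

        best = None
        for a0 in (0.2, 0.5, 0.8):
            for b0 in (0.1, 0.4, 0.8):
                sol = minimize(obj, x0=[a0, b0], method="L-BFGS-B",
                               bounds=[(0.0, 1.0), (0.0, 1.0)])
                if best is None or sol.fun < best.fun:
                    best = sol
        state, sse = _run_recursion(y, float(best.x[0]), float(best.x[1]))
    state.sse = sse
    return state
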