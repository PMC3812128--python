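"""Seeded synthetic yield panels with known ground truth.

Four scenarios cover the trend shapes the analysis must handle:

* ``dlm_draw`` — exact draws from the local-linear-trend state-space model
  with known variances, for parameter-recovery and calibration tests.
* ``plateau`` — a "France-like" broken line: strong linear rise from
  about 2.5 t/ha in 1961 at 0.13 t/ha/yr, flattening near 6.5 t/ha in the
  early 1990s, plus observation noise.
* ``accelerating`` — a "Brazil-like" convex trend: low starting yield
  (0.5 t/ha) with a yearly increase rate that itself grows over time,
  reaching almost 3 t/ha after five decades.
* ``linear`` — a plain noisy straight line (no plateau anywhere), the
  regime in which the linear-plus-plateau fit must refuse to converge.

Every generator returns the latent truth alongside the observations, and
the panel writer keeps truth in a sibling ``*_truth.csv`` so no analysis
stage can consume it by accident.  Draws come from numpy's seeded PCG64
generator, so identical config + seed means bit-identical panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_io import YieldPanel, YieldSeries, write_table

__all__ = ["SimulationConfig", "simulate_dlm_series", "simulate_scenario_panel", "write_panel"]

#: yields are floored here; configs that would truncate often are rejected
YIELD_FLOOR = 0.05

SCENARIOS = ("dlm_draw", "plateau", "accelerating", "linear")


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world of one synthetic panel.

    Defaults mirror a FAOSTAT-like national panel: 50 years (1961–2010),
    observation noise σ = 0.3 t/ha around the trend, and the France/Brazil
    archetype shapes for the plateau and accelerating scenarios.
    """

    scenario: str = "dlm_draw"
    n_units: int = 1
    first_year: int = 1961
    last_year: int = 2010
    seed: int = 0
    # state-space draw variances (t² ha⁻²)
    var_obs: float = 0.09
    var_level: float = 0.01
    var_slope: float = 1e-4
    start_level: float = 2.5
    start_slope: float = 0.13
    # plateau scenario ("France-like")
    plateau_break_year: int = 1992
    plateau_level: float | None = None   # derived from rise if None
    # accelerating scenario ("Brazil-like")
    accel_start_level: float = 0.5
    accel_start_slope: float = 0.02
    accel_end_slope: float = 0.08
    # observation noise of the deterministic scenarios
    noise_sd: float = 0.3
    #: relative jitter of unit-level shape parameters (heterogeneity)
    unit_jitter: float = 0.05

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; valid: {SCENARIOS}")
        if self.n_units < 1:
            raise ValueError("n_units must be ≥ 1")
        if self.last_year - self.first_year + 1 < 10:
            raise ValueError("the year range must span at least 10 years")
        for name in ("var_obs", "var_level", "var_slope"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be ≥ 0")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)


def _floor_yields(y: np.ndarray, config: SimulationConfig) -> np.ndarray:
    hit = y < YIELD_FLOOR
    if hit.mean() > 0.01:
        raise ValueError(
            f"{hit.mean():.1%} of draws fall below the {YIELD_FLOOR} t/ha floor; "
            "truncation at this rate would distort recovery tests — lower the noise"
        )
    return np.maximum(y, YIELD_FLOOR)


def simulate_dlm_series(
    config: SimulationConfig,
    unit_id: str = "U001",
    rng: np.random.Generator | None = None,
) -> tuple[YieldSeries, pd.DataFrame]:
    """One draw from the local-linear-trend model; returns (series, truth).

    The truth frame carries the latent level and slope paths so recovery
    tests can score the smoother against what actually generated the data.
    """
    if config.scenario != "dlm_draw":
        raise ValueError("simulate_dlm_series requires the 'dlm_draw' scenario")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    years = config.years
    m = years.size
    level = np.empty(m)
    slope = np.empty(m)
    lv, sl = config.start_level, config.start_slope
    s_lev, s_slo = np.sqrt(config.var_level), np.sqrt(config.var_slope)
    for t in range(m):
        lv = lv + sl + rng.normal(0.0, s_lev)
        sl = sl + rng.normal(0.0, s_slo)
        level[t] = lv
        slope[t] = sl
    y = _floor_yields(level + rng.normal(0.0, np.sqrt(config.var_obs), size=m), config)
    truth = pd.DataFrame({"unit_id": unit_id, "year": years,
                          "true_level": level, "true_slope": slope})
    return YieldSeries(unit_id, years, y), truth


def _scenario_trend(config: SimulationConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic (level, slope) paths for one unit, with jittered shape."""
    years = config.years
    t = np.arange(years.size, dtype=float)  # 0-based offsets from the first year

    def jit(x: float) -> float:
        return x * (1.0 + config.unit_jitter * rng.standard_normal()) if x else x

    if config.scenario == "plateau":
        rise = jit(config.start_slope)
        base = jit(config.start_level)
        t_break = float(config.plateau_break_year - config.first_year)
        t_break *= 1.0 + config.unit_jitter * rng.standard_normal()
        if config.plateau_level is None:
            top = base + rise * t_break
        else:
            top = jit(config.plateau_level)
            base = top - rise * t_break
        level = np.where(t < t_break, base + rise * t, top)
        slope = np.where(t < t_break, rise, 0.0)
    elif config.scenario == "accelerating":
        base = jit(config.accel_start_level)
        s0 = jit(config.accel_start_slope)
        s1 = jit(config.accel_end_slope)
        growth = (s1 - s0) / max(years.size - 1, 1)
        slope = s0 + growth * t
        # level integrates the slope path
        level = base + np.concatenate([[0.0], np.cumsum(slope[:-1])])
    elif config.scenario == "linear":
        base = jit(config.start_level)
        rise = jit(config.start_slope)
        level = base + rise * t
        slope = np.full_like(t, rise)
    else:
        raise ValueError(f"scenario {config.scenario!r} is not deterministic")
    return level, slope


def simulate_scenario_panel(config: SimulationConfig) -> tuple[YieldPanel, pd.DataFrame]:
    """A panel of ``n_units`` series plus the per-unit latent truth frame."""
    rng = np.random.default_rng(config.seed)
    width = max(3, len(str(config.n_units)))
    series: dict[str, YieldSeries] = {}
    truths = []
    for i in range(config.n_units):
        unit = f"U{i + 1:0{width}d}"
        if config.scenario == "dlm_draw":
            s, truth = simulate_dlm_series(config, unit, rng)
        else:
            level, slope = _scenario_trend(config, rng)
            y = _floor_yields(
                level + rng.normal(0.0, config.noise_sd, size=level.size), config
            )
            s = YieldSeries(unit, config.years, y)
            truth = pd.DataFrame({"unit_id": unit, "year": config.years,
                                  "true_level": level, "true_slope": slope})
        series[unit] = s
        truths.append(truth)
    label = f"{config.scenario}[n={config.n_units},seed={config.seed}]"
    return YieldPanel(series, label=label), pd.concat(truths, ignore_index=True)


def write_panel(panel: YieldPanel, truth: pd.DataFrame, path, *, decimals: int = 6) -> None:
    """Write a panel as CSV plus its truth as a sibling ``*_truth.csv``."""
    path = str(path)
    write_table(panel.to_frame(), path, decimals=decimals)
    stem = path[:-4] if path.endswith(".csv") else path
    write_table(truth, stem + "_truth.csv", decimals=decimals)
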