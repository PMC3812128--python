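# yieldtrends

Trend models and rolling-origin forecast evaluation for crop yield time
series.

National and regional statistical agencies publish yearly crop-yield series
(t ha⁻¹) that underpin food-security foresight work: is yield still rising,
has it stagnated, how fast is it changing, and which statistical model
should be trusted to extrapolate it? This package implements, as a tested
library plus CLI, a model-comparison pipeline for exactly that question on
panels of yield series (one series per country or region), together with a
seeded synthetic-data generator so the entire pipeline is testable without
external data.

## Models

Eight trend models for a series Y_t with internal time index T = 1..M:

| name | model |
|------|-------|
| L    | linear regression Y_t = a + bT + ε_t |
| Q    | quadratic regression Y_t = a + bT + cT² + ε_t |
| C    | cubic regression Y_t = a + bT + cT² + dT³ + ε_t |
| LP   | linear-plus-plateau: rises at rate R until break date T\*, constant at Ymax after (continuous at T\*) |
| HW0  | simple exponential smoothing: â_t = αY_t + (1−α)â_{t−1}; flat forecasts |
| HWs  | Holt's linear trend: recursively updated level â_t and slope b̂_t; forecast Ŷ_{t+k} = â_t + k·b̂_t |
| DLM0 | local-level (random-walk) state-space model: L_t = L_{t−1} + w_t, Y_t = L_t + ν_t |
| DLMs | local-linear-trend state-space model: L_t = L_{t−1} + b_{t−1} + w_t, b_t = b_{t−1} + u_t, Y_t = L_t + ν_t |

Polynomials are fitted by OLS; LP by profiling the residual sum of squares
over candidate break dates with a nonlinear refinement (non-convergence on
plateau-free series is a reported status, not an error); Holt-Winters
constants by minimizing one-step in-sample forecast error; the dynamic
linear models by maximum likelihood over (σ²_y, σ²_L, σ²_b) via a
from-scratch Kalman filter with prediction-error-decomposition likelihood.
A two-filter Kalman smoother yields the retrospective trend and, for DLMs,
the yearly yield-increase rate b̂_t = E[b_t | Y_{1:M}] with quartile and
95% bands — the quantity that distinguishes stagnating regions from
improving ones.

Models are compared by in-sample RMSE and by rolling-origin k-year-ahead
RMSEP: for each target year t in an evaluation window (default: the final
20 years) the model is refitted on all data up to t − k and its k-step
forecast scored against Y_t, for k = 1..10, averaged over the units of a
panel.

## Worked example

```python
from yieldtrends import panel_evaluate, increase_rate_trajectory
from yieldtrends.simulate import SimulationConfig, simulate_scenario_panel

cfg = SimulationConfig(scenario="plateau", n_units=5, seed=42, noise_sd=0.25)
panel, truth = simulate_scenario_panel(cfg)   # France-like rise-then-plateau units

table = panel_evaluate(panel, ["L", "Q", "DLM0", "DLMs", "HW0"], horizons=[1, 10])
print(table)
```

prints (abridged):

```
model statistic  horizon  value  pct_difference_vs_min  n_units
    L      RMSE        0 0.4792               395.8305        5
    Q      RMSE        0 0.2746               184.1107        5
 DLM0      RMSE        0 0.0966                 0.0000        5
 DLMs      RMSE        0 0.1796                85.8242        5
    L     RMSEP        1 0.7383               158.9819        5
 DLM0     RMSEP        1 0.2851                 0.0000        5
 HW0      RMSEP        1 0.2852                 0.0275        5
    L     RMSEP       10 1.2005                65.1337        5
 DLM0     RMSEP       10 0.7275                 0.0762        5
 HW0      RMSEP       10 0.7270                 0.0000        5
```

Read: on plateauing series the random-walk model (DLM0) tracks the data
best in-sample (RMSE 0.097 t/ha, all other models ≥ 86% worse) and DLM0
and simple exponential smoothing give practically identical out-of-sample
errors at every horizon (0.03–0.08% apart) — the steady-state Kalman gain
of the local-level model *is* an exponential-smoothing constant. The
linear model, which cannot bend, is 159% worse at k = 1.

```python
traj = increase_rate_trajectory(panel.series["U001"])
print(traj.table.tail(3))
print(traj.cv_final, traj.cv_category)
```

```
unit_id  year   slope     sd      q1      q3    lo95   hi95
   U001  2008 -0.0311 0.0321 -0.0528 -0.0095 -0.0941 0.0318
   U001  2010 -0.0341 0.0416 -0.0622 -0.0061 -0.1157 0.0475
122.0 high
```

The smoothed yield-increase rate of this plateaued unit is ≈ −0.03 t/ha/yr
in 2010 with a 95% interval straddling zero: yield has stagnated, and the
coefficient of variation (122%) flags the final-year rate estimate as
highly uncertain.

## Command line

```bash
yieldtrends simulate --scenario plateau --n-units 20 --seed 1 --out runs/sim
yieldtrends evaluate --input runs/sim/panel.csv --models L,Q,C,DLM0,DLMs \
    --horizons 1:10 --out runs/eval
yieldtrends rates    --input runs/sim/panel.csv --out runs/rates
yieldtrends compare  --input runs/sim/panel.csv --horizons 1,10 --out runs/cmp
```

Real panels are read with `read_panel(path, dialect=...)`; named dialects
`faostat` (`Area`/`Year`/`Value`, optional hg/ha scale) and `agreste`
(`departement`/`annee`/`rendement`) ship as presets. Every CLI run writes a
`manifest.yaml` (config, seed, input checksums) so results are replayable.

## Acceptance script

`scripts/acceptance.py` re-runs the full pipeline from scratch on seeded
synthetic panels: it generates a mixed 50-unit panel (25 plateauing, 25
accelerating units), computes the RMSE/RMSEP comparison across all seven
evaluable models, the win-rate of the trend model over the random-walk
model stratified by final-year yield-increase rate, the linear-plus-plateau
convergence contrast between scenarios, and an example rate trajectory,
then writes the summary JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
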