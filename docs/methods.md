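# Methods

## The problem

A yearly yield series Y_t (t ha⁻¹, T = 1..M with T = 1 at the series'
first year) mixes a slowly-moving agronomic trend — varieties, inputs,
practices, climate — with year-to-year weather noise. Two questions drive
the design: which trend model predicts future yield best, and what is the
yearly yield-increase rate (and its uncertainty) right now? The second
question is what detects stagnation: a rate indistinguishable from zero.

## Models and estimation

**Polynomial regressions (L, Q, C).** OLS on the time index with degrees
1–3. Errors are assumed independent Gaussian; `residual_autocorrelation`
provides the sample ACF with the ±1.96/√M white-noise band to check this.
The design matrices are nested, so in-sample RMSE can only improve from L
to Q to C — asserted as an invariant. A single step of iterative
refinement follows the least-squares solve because the cubic Vandermonde
basis on T = 1..M is ill-conditioned enough to cost a few digits.

**Linear-plus-plateau (LP).** Y rises at rate R until break date T\*, then
stays at Ymax; continuity pins Ymax = a + R·T\*, leaving three free
parameters. The break enters non-smoothly, so the fit profiles the RSS
over every observed T from the 3rd to the (M−2)-th point — the
conditionally linear parameters are solved exactly at each candidate — and
refines the best candidate with bounded nonlinear least squares.
*Identifiability:* a series without a plateau gives the optimizer nothing
to find; the fit is reported `converged=False` (never an exception, so
panel runs can count failures) when (a) the refined break leaves
[T_min, T_max − 5] — a plateau supported by fewer than ~5 years at the end
of a rising series is indistinguishable from noise, (b) the Gauss-Newton
curvature at the optimum is numerically singular, or (c) the broken line
fails to beat the nested pure line in an F(1, n−3) test at the 1% level.
On seeded 50-unit panels this yields ≥ 98% convergence on plateau-shaped
units and ≤ 2% on linear units. Rule (c) uses the F reference loosely —
under the no-break null the statistic does not follow F(1, ·) exactly
(the break parameter vanishes under the null) — but it only needs to
separate F ≈ 1–13 (no plateau) from F ≈ 75+ (plateau), which it does with
a wide margin.

**Holt-Winters (HW0, HWs).** Level (and for HWs slope) updated
recursively with constants α, β ∈ [0, 1]; forecasts â_t + k·b̂_t.
Initialization is the textbook convention — level at y₁, slope at y₂ − y₁
— and the one-step squared-error objective starts accumulating at the
third observation so the initialization itself earns no credit. The
objective is optimized on the unit box; it is flat near α → 0, so the
bounded optimizer restarts from a coarse grid (9 points for HWs) and the
best optimum is kept. Missing years propagate the state along its own
forecast. Exact linear data is a fixed point of the HWs recursion for any
(α, β): used as an algebraic test.

**Dynamic linear models (DLM0, DLMs).** Gaussian state-space models with
observation noise σ²_y; DLM0 has a random-walk level (parameters σ²_y,
σ²_L), DLMs adds a random-walk slope (σ²_b) driving the level. The forward
Kalman filter gives one-step prediction errors and the
prediction-error-decomposition log-likelihood; the smoother conditions
every state on the full series. All reporting uses smoothed quantities —
the point of the model is retrospective trend reconstruction. Slope bands
are Gaussian-posterior quantiles with fixed constants 0.67448975
(quartiles) and 1.959964 (95%).

*Initialization.* Near-diffuse: prior mean 0, prior covariance 1e7·I on a
pre-initial state propagated one system step before the first update; the
first d prediction-error terms (d = state dimension) are excluded from the
likelihood. This matches the convention of the reference R implementation
of dynamic linear models. Exact-diffuse initialization would be the
cleaner limit but is not required; the difference is O(10⁻⁷) on the
moments.

*Numerics of the smoother.* The classical RTS backward pass inverts the
predicted covariance, and with a 1e7 prior its error grows with the
squared condition number: the first years' smoothed slope variances come
out wrong by ~1e-2 absolute in double precision (independent
implementations with approximate-diffuse initialization even return
negative variances there). The smoother here is therefore a two-filter
form: a backward pass accumulates the information (Λ_t, λ_t) that future
observations carry about x_t — all moderate numbers, with the propagation
Λ ← F'(I + ΛQ)⁻¹ΛF valid for singular Λ and singular Q — and each smoothed
state combines it with the forward filtered moments as
Σ_t = (I + P_tΛ_t)⁻¹P_t, never inverting P_t. Against a brute-force
joint-Gaussian conditioning oracle (extended-precision linear algebra,
M ≤ 12) the filter and smoother agree to ~1e-9.

*Variance estimation.* Maximum likelihood over log-variances (the natural
scale for parameters spanning orders of magnitude, bounded below at
1e-12) with Nelder-Mead restarted from five moment-based points derived
from the variance of first differences. Log-variance coordinates plus
multi-start address the flat likelihood near zero variances. Noiseless
series legitimately drive all variances to the floor. Forecasting uses the
filtered state at the training end; the k-step forecast variance
propagates the state covariance through k system steps
(P + k·σ²_L + σ²_b·Σ_{i<k} i² for DLMs) plus observation noise, verified
against Monte-Carlo simulation.

*Known limitation (plug-in bands).* The 95% slope bands condition on the
estimated variances. At M = 60 with a realistic signal-to-noise for the
slope disturbance (σ²_b/σ²_y ~ 10⁻³), the MLE of σ²_b piles up at zero in
roughly a quarter of replicates — a boundary-estimation property, not an
optimizer defect; an independent implementation returns the same medians —
and band coverage of the true slope path drops to ~0.73, versus exactly
0.95 when the true variances are plugged in. Rate-uncertainty statements
on short series should be read with this in mind; the coefficient of
variation categories (>100% uninformative, <25% precise) are deliberately
coarse for the same reason.

**Why DLM0 ≈ HW0.** The steady-state Kalman gain of the local-level model
with signal-to-noise q = σ²_L/σ²_y is α = (√(q² + 4q) − q)/2, which is an
exponential-smoothing constant: after burn-in the two forecasters coincide
(asserted to < 1e-3 on a 500-point series). This explains why their
panel-averaged prediction errors are nearly identical.

## Evaluation protocol

In-sample RMSE uses the model fitted to the whole series (smoothed level
for the DLMs; the Holt-Winters forecasters have no in-sample trend and are
excluded). Rolling-origin RMSEP refits the model from scratch on all data
up to t − k for every target year t in a fixed window of calendar years at
the end of the series (default: final 20 years, identical across
horizons) and scores the k-step forecast; the per-unit RMSEPs are averaged
arithmetically over units (a pooled-error aggregation is available behind
a flag). Units where a model cannot be fitted are dropped from that
model's average and counted. LP is excluded from RMSEP because refits on
plateau-free training windows do not converge, so no honest forecast path
exists. Fits are memoized by (unit, model, training-end year): identical
training data gives an identical fit, so the cache changes nothing but
runtime. Window conventions differ in the literature between "targets
1991–2010" and "origins 1991–2010"; the window here is the set of target
years and is configurable, so both readings can be run.

The trend-vs-random-walk comparison (`dlms_vs_dlm0_winrate`) reports the
percentage of units where DLMs attains strictly lower RMSEP than DLM0,
overall and within two strata split at the cross-unit median of the
final-year smoothed rate (lower central value for even counts; ties go
low, so neither stratum is ever empty). The expected direction — the trend
model wins mainly where yields are still improving — is an acceptance
property.

## Synthetic data

The generator emits seeded panels (numpy PCG64; identical config + seed is
bit-identical) in four scenarios, with per-unit truth (latent level and
slope paths) written separately so no analysis stage can consume it:

- `dlm_draw`: exact draws from the local-linear-trend model. Defaults
  σ²_y = 0.09, σ²_L = 0.01, σ²_b = 1e-4 — observation noise of
  0.3 t/ha around a trend starting at 2.5 t/ha, rising 0.13 t/ha/yr.
- `plateau` ("France-like"): 2.5 t/ha in 1961 rising at 0.13 t/ha/yr to a
  plateau at the 1992 break (≈ 6.53 t/ha), plus Gaussian noise
  (σ = 0.3 default; 0.25 in panel fixtures).
- `accelerating` ("Brazil-like"): 0.5 t/ha in 1961 with a rate growing
  linearly from 0.02 to 0.08 t/ha/yr, reaching ≈ 2.95 t/ha by 2010;
  σ = 0.15 in fixtures, smaller than the plateau scenario because absolute
  variability scales with the low yield level (σ = 0.3 would truncate ~7%
  of first-decade draws at the positivity floor).
- `linear`: a plain noisy line — the regime where LP must refuse to fit.

Unit-level shape parameters are jittered (5% relative) for heterogeneity.
Yields are floored at 0.05 t/ha; any configuration whose noise would floor
more than 1% of draws is rejected rather than silently truncated, because
truncation distorts recovery tests. Default span 1961–2010 (M = 50).

What a green test does not establish: the scenarios have Gaussian,
homoscedastic, serially independent noise and no missing years, unlike
real agency data with revisions, wars, and reporting changes; and
deterministic-trend scenarios are exactly the shapes some models assume.
Qualitative rankings on these panels demonstrate that the pipeline
reproduces the expected structure, not that the same margins hold on any
real panel.

## Missing data

Years absent inside a series are explicit missing observations: the
state-space filter skips the measurement update, Holt-Winters propagates
its own forecast, and the regressions drop the rows. Real FAOSTAT-like
series are typically gap-free; this generalization is for robustness, not
a modeling claim.
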