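# Methods

`tgepop` re-implements, as one pipeline, an analysis chain linking
laboratory thermal-performance experiments on a *Drosophila* host and its
*Asobara* parasitoid wasp to coupled population-dynamic simulations of
time-to-extinction under warming. This note records the models, the
numerical choices, and what the synthetic data can and cannot show.

## 1. Host thermal performance (fly_tpc)

Per-vial emergence counts are modelled with an asymmetric thermal
performance curve,

    mu(T) = Rmax exp(-((T - Topt) / (2a))^2)                    T <= Topt
    mu(T) = Rmax (1 - ((T - Topt) / (Topt - CTmax))^2)          Topt < T < CTmax
    mu(T) = 0                                                   T >= CTmax

with `CTmax` fixed at 30 °C (outside the 19–27 °C trial range) and a
negative-binomial likelihood, `Var = mu + mu^2/theta`, with a *single*
shared dispersion `theta` per model. The exponent uses the `(2a)`
denominator of the `deutsch_2008` form in rTPC; the quadratic branch is
clamped at zero beyond `CTmax`, where the raw formula would go negative
(never triggered inside the experimental range, but the simulator
extrapolates to 30 °C).

Seven variants encode how the parental temperature G0 enters: `1a`
Poisson/shared (3 parameters), `1b` NB/shared (4), `1c` each curve
parameter affine in G0 (7), `1d` free per G0 level (10), and `1e–1g` with
exactly one parameter shared (8 each). Parameter counts fix the
dispersion-sharing rule: `theta` is always one shared parameter.

**Optimization.** `Rmax`, `a`, `theta` are log-transformed; `Topt` is
bounded in [15, 29.9] °C. Each fit runs L-BFGS-B from a moment-based start
(per-cell means) plus 20 Latin-hypercube restarts (configurable), with
`ftol = 1e-10`; TPC likelihoods are multimodal and the restarts are not
optional. Ties in ΔAIC are broken by fewer parameters, then variant id.
Predicted means are floored at 1e-6 before the log-likelihood (only
reachable at or beyond `CTmax`), with a warning outside the optimizer.

**Identifiability caveat.** When the true optimum sits at the warm edge of
the tested range (as it does in the default synthetic truth) and the
curves are wide, `Topt` is weakly identified: the profile likelihood can
rise monotonically to the upper bound, and the MLE lands there in a
substantial fraction of replicate datasets. `Rmax` and model selection are
unaffected; interval estimates of `Topt` from this design should not be
trusted near the range edge. This is a property of the design, not of the
optimizer (checked by comparing boundary-fit and truth likelihoods).

## 2. Parasitoid performance (wasp_glm)

Each vial's (wasp, fly) emergence pair is one binomial draw with success
probability `eta(T) = expit(intercept + slope * G1)`. Variants: `2a` no
G0 (2 parameters), `2b` + numeric G0 main effect (3), `2c` + G0×G1 product
(4), `2d` separate (intercept, slope) per G0 level, log-likelihoods summed
(6). Fits use IRLS (statsmodels GLM); divergence or perfect separation
raises a diagnostic error. The proportion model assumes total emergences
are independent of G1; `total_count_independence` runs the supporting OLS
regression (F on 1 and n−2 df).

## 3. Transgenerational interpolation (tge_interpolation)

The simulator needs parameters at arbitrary parental temperatures.
Fly curve parameters (from `1d`) are interpolated piecewise-linearly
through the three G0 nodes and extrapolated beyond 19–27 °C with the
nearest segment's slope; interpolated `Rmax` is floored at 0.1 (and `a` at
1e-3 for numerical safety — the only bounds applied). Wasp logit
coefficients (from `2d`) use the unique parabola through the three nodes,
also for extrapolation; interpolating on the coefficient scale keeps
`eta` inside (0, 1). With equal node values both schemes are constant —
the transgenerational effect switches off implicitly. The NB dispersion
is carried through but unused downstream: the simulator is deterministic
given the temperature trajectory.

## 4. Temperature regime (environment)

A trajectory is 500 burn-in generations at 24 °C, then a linear rise of
5 °C over 2000 generations (~80 years at ~2 weeks/generation), with
Gaussian AR(1) noise superimposed and the sum capped at 30 °C = `CTmax`.
`sigma = 1` °C is the *marginal* SD of the noise: the AR(1) innovation is
scaled by `sqrt(1 - rho^2)`, so rho ∈ {0, 0.8} trajectories have the same
stationary variance and differ only in clustering. The underlying normal
draws depend only on the seed, never on rho — trajectories with the same
seed are deterministic transformations of one another, which is what makes
the paired scenario design work. No lower cap is applied; the cold branch
of the TPC handles cool excursions.

## 5. Population dynamics (dynamics)

Both models produce potential hosts by a logistic step
`N* = max(0, gamma r(T) N (1 - N/K_H))` (floored where `N > K_H` would
drive it negative) and differ in parasitism:

* **Model A** (Type II): `kills = P alpha N*/(1 + alpha h N*)`, truncated
  at `N*` so hosts cannot go negative; `N' = N* - kills`, `P' = kills + d`.
* **Model B** (aggregated attacks): survival
  `S = (1 + alpha P / (k (1 + alpha h N*)))^(-k)`; `N' = N* S`,
  `P' = N* (1 - S) + d`. `k -> inf` recovers exponential (random) escape.

`alpha = t_p * eta(T)`; with transgenerational modes off, `r` uses the
`1b` curve and `eta` the `2a` coefficients; with a mode on, the
interpolators evaluated at the previous generation's temperature supply
the parameters (the current temperature still enters the curve itself).
`T_prev` at the first generation is the first trajectory value.
Populations are continuous; extinction is the first generation the host
falls below 1 individual.

**Defaults** (all config-overridable; stand-ins where the original
study's parameter table is not publicly archived): `K_H = 2000`,
`h = 0.01` (per-wasp kill ceiling `1/h = 100`, an egg-limitation figure),
`d = 0.5` immigrants/generation, `k = 1`, threshold 1.

**Growth scaling.** `gamma` is set so that the realized per-generation
multiplier at the burn-in temperature, `gamma * r_1b(24 °C)`, equals 3.2.
This quantity — not `gamma` itself — controls the dynamics. The value was
chosen, once, so that the calibrated no-TGE system holds a stable
host–parasitoid coexistence at ~50 % parasitism through thousands of noisy
generations: the coexistence equilibrium of the Type II model is locally
stable only in a window of growth multipliers (roughly 2.7–3.6 here);
below it the 0.45–0.55 parasitism band is dynamically unreachable, above
it the boom–crash oscillation diverges.

**Calibration and initialization.** `t_p` is tuned by bisection (modes
off, constant 24 °C) until the late-window mean of `(N* - N')/N*` lies in
[0.45, 0.55]; a host collapse during a probe counts as overshoot, so the
bisection backs off the instability cliff. Each probe — and every
simulation run — starts at the coexistence fixed point, solved from the
one-dimensional fixed-point condition in `N`. That is what a burn-in is
for; starting far from equilibrium injects a parasitoid boom that wipes
out the host within a handful of generations regardless of the long-run
stability of the equilibrium.

## 6. Extinction experiment (experiment, lmm)

Eight scenarios — rho ∈ {0, 0.8} × fly TGE on/off × wasp TGE on/off — run
over the same 100 trajectory seeds (paired across scenarios and across
rho). Summaries report per-scenario geometric means, quantiles and
censoring. Log extinction time is analysed with

    log(T_ext) ~ autocorr * fly_tge * wasp_tge + (1 | seed)

using sum-to-zero (−1/+1) coding, REML variance components (closed-form
compound-symmetry likelihood, Nelder-Mead on log variances from three
starts), Type III Wald F per one-df term, and Satterthwaite denominator
df: `df = 2 (c'Cc)^2 / Var(c'Cc)` with the variance by delta method
(finite-difference gradient in the two variance components, covariance
from the inverse observed REML information). On a balanced grid this
reproduces the exact within-seed df, `n_obs − n_seeds − 7` (693 for
100 seeds), and the implementation agrees with R's lmerTest on test
fixtures. Censored runs are excluded with a logged count; a singular
random-intercept fit falls back to fixed-effects ANOVA with a warning.
P-values are reported unadjusted (one pre-specified interaction test per
model). All randomness derives from one master seed via spawned child
seeds, logged in the outputs.

## 7. The synthetic data, and what the tests do not show

The generator emulates the two factorial experiments: a 3×5 design with
40 vials/cell of NB fly counts around per-G0 curves (shared θ = 1.5), and
18 vials/cell of Poisson totals (mean 90, independent of G1 — the
distribution of totals is a modelling choice; only its G1-independence is
asserted by the design) split binomially with per-G0 logit-linear wasp
shares. The default "truth" (Topt 25.5/27/26 °C, Rmax 22/38/12, a 6/7/8;
wasp coefficients giving a falling share after cool parents and a rising
share after hot parents) mimics the qualitative ordering of the real
system — intermediate parental temperature best for flies,
parent–offspring matching best for wasps — and is *not* an estimate of
the real parameters.

Consequences worth stating plainly:

* Passing tests show the pipeline's machinery and the direction of
  effects, not the published extinction generations or F statistics,
  which depend on the original fitted values and the undistributed
  parameter table.
* Under Model A, the synthetic transgenerational contrast raises the
  effective growth multiplier by ~1.3× when the fly TGE is switched on,
  which pushes those scenarios outside the Type II model's narrow
  stability window: fly-TGE runs collapse during burn-in rather than
  mid-ramp. The qualitative orderings (fly-TGE earlier; wasp-only
  indistinguishable from none) still hold, but Model A's fly-TGE
  extinction *times* are burn-in instabilities, not warming responses.
  Model B (aggregation, k = 1) is robust for all scenarios and shows the
  paper-like pattern of mid-ramp extinctions.
* Real vial data have features the generator omits: acclimatisation
  mortality, sex-ratio and development-time differences, and
  between-vial heterogeneity beyond a single shared dispersion.

## 8. Problem sizes

Default test and acceptance runs use the study-scale design throughout:
600 / 270 vials, 100 trajectory seeds × 8 scenarios × 2500 generations.
Replicate-heavy checks (parameter recovery, type-I error simulations) use
20–400 replicates with seeded generators.
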