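# tgepop

Transgenerational thermal effects in host–parasitoid population dynamics.

Parasitoid wasps and their insect hosts are tightly coupled: wasp
recruitment *is* parasitised hosts. If the temperature a generation's
parents experienced changes that generation's performance — a
transgenerational effect (TGE) — then autocorrelated warming can act on
both trophic levels at once, with emergent consequences for persistence.
`tgepop` implements the full analysis chain for a *Drosophila*–*Asobara*
style system:

1. **Host thermal performance.** Per-vial emergence counts follow
   `mu(T) = Rmax exp(-((T-Topt)/(2a))²)` below the optimum and a quadratic
   fall to zero at `CTmax = 30 °C` above it, with a negative-binomial
   likelihood (shared dispersion θ). Seven variants encode how the
   parental temperature G0 enters (none / affine / free per level /
   two-of-three), compared by AIC.
2. **Parasitoid performance.** The wasp share of emergences is binomial
   with logit-linear dependence on the offspring temperature G1; four
   variants again differ in the role of G0.
3. **Interpolation.** Fitted per-G0 parameters become continuous
   functions of the previous generation's temperature (piecewise-linear
   for the host curve, floored `Rmax ≥ 0.1`; quadratic on the logit scale
   for the wasp).
4. **Simulation.** Two discrete-generation models — a Type II functional
   response (`N' = N* − PαN*/(1+αhN*)`) and an aggregated-attack model
   (`N' = N*(1+αP/(k(1+αhN*)))^(−k)`) — are driven by warming
   trajectories (500 generations at 24 °C, +5 °C over 2000 generations,
   AR(1) noise with marginal SD 1 and lag-1 autocorrelation 0 or 0.8,
   capped at 30 °C). The attack coefficient `t_p` is calibrated to ~50 %
   parasitism at the pre-warming baseline.
5. **Experiment.** 8 scenarios (autocorrelation × fly TGE × wasp TGE) ×
   100 paired trajectories; log time-to-extinction analysed with a
   random-intercept-per-seed mixed model and Type III F tests with
   Satterthwaite denominator degrees of freedom.

A synthetic-data module generates vial-level datasets with the full
statistical structure of both factorial experiments, so every stage is
testable without the archived raw data. See `docs/methods.md` for models,
defaults and limitations.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (each writes its tables under `results/`):

```sh
python analysis/01_generate_data.py
python analysis/02_fit_fly_tpc.py
python analysis/03_fit_wasp_glm.py
python analysis/04_calibrate_dynamics.py
python analysis/05_run_extinction_grid.py
python analysis/06_analyze_extinctions.py
```

Stage 3 prints the wasp model comparison — the per-G0-level model `2d`
wins decisively when the generating coefficients differ by parental
temperature —

```
variant  n_params       loglik         aic   delta_aic
     2d         6  -775.968387 1563.936775    0.000000
     2c         4  -901.805243 1811.610486  247.673711
     2b         3 -1850.696860 3707.393720 2143.456945
     2a         2 -2016.947970 4037.895940 2473.959165

total count ~ G1: F(1, 268) = 1.436, p = 0.232
```

and the independence regression supports treating the wasp share as a
binomial proportion. Stage 4 reports the calibrated baseline (growth
multiplier 3.2 at 24 °C, attack coefficient tuned into the 45–55 %
parasitism band):

```
model A: gamma=0.1296 t_p=0.00094 equilibrium N=856 P=712 parasitism=0.454
model B: gamma=0.1296 t_p=0.00175 equilibrium N=847 P=716 parasitism=0.458
```

Stage 6 summarises the experiment. Under Model B every scenario survives
the burn-in and dies during the ramp, with fly-TGE scenarios going extinct
first and wasp-only TGE indistinguishable from no TGE:

```
 rho  scenario  geometric_mean  median
 0.0      none     1849.890277  1879.5
 0.0 wasp-only     1849.890277  1879.5
 0.0  fly-only     1422.947438  1481.0
 0.0      both     1476.892878  1575.0
 0.8      none     1935.023046  1953.0
 0.8 wasp-only     1935.023046  1953.0
 0.8  fly-only     1381.405129  1441.5
 0.8      both     1407.558324  1448.0
three-way interaction: F(1, 694) = 0.228, p = 0.633
```

Geometric means are generations until the host first drops below one
individual; the F test is the three-way interaction of autocorrelation
and the two transgenerational effects on log extinction time, on ~693
denominator df for the balanced 100-seed grid.

There is also a CLI over the same library (`tgepop synth|fit-fly|
fit-wasp|trajectory|simulate|experiment|analyze|pipeline`); `tgepop
pipeline --out DIR` runs everything with a manifest and run log.

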