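# Methods

`tgitte` implements a two-stage translational modeling framework for
preclinical xenograft efficacy studies: a population tumor-growth-
inhibition (TGI) model fitted to longitudinal caliper measurements, and
a parametric time-to-event (TTE) model for the survival surrogate
(tumor volume reaching a predefined threshold), whose scale parameter
depends on the TGI-derived per-animal growth rates and on drug exposure.

## Tumor growth model

Tumor volume TV (mm³) evolves as

    dTV/dt = λ0·TV / [1 + ((λ0/λ1)·TV)^ψ]^(1/ψ)  −  k·Cp(t)·TV

with exponential growth rate λ0 (1/h), linear growth rate λ1 (mm³/h),
kill rate constant k (mL/ng/h), plasma concentration Cp(t) (ng/mL) and
switching exponent ψ = 20 (fixed, not estimated). Growth is exponential
well below the switch volume TV* = λ1/λ0, linear well above it; the
large exponent makes the transition sharp. The drug kills proliferating
cells at a rate linear in concentration; an optional Michaelis–Menten
effect `k·Cp/(KC50+Cp)·TV` is available for structural screens but off
by default, as the saturable form tends to be unstable at this design.
Alternative natural-growth structures (exponential; Koch
`2λ0λ1TV/(λ1+2λ0TV)`; quadratic-in-time `TV0+λ0t+λ1t²`, a documented
choice of polynomial form since only the family name is conventional)
are provided for AIC-based model screens.

Numerics: the ODE is integrated on u = log TV, which enforces
positivity and removes the stiffness of the steep bracket. The default
integrator is a numba-compiled adaptive Dormand–Prince RK45 with
mandatory step boundaries at dose and output times (bolus doses make
Cp(t) discontinuous, so no step ever straddles a dose); default
tolerances rtol 1e-8 / atol 1e-10 on log TV change volumes by < 0.1 %
when halved. A scipy LSODA path (`backend="scipy"`) provides an
independent cross-check and agrees to ~1e-6 relative.

## Pharmacokinetics and exposure

A one-compartment IV-bolus model with linear elimination provides
Cp(t) by superposition of mono-exponential terms; clearance CL
(mL/h/kg) and distribution volume V (mL/kg) are typical-value inputs
with no between-animal variability. Per-kg dosing with per-kg volume
cancels body weight; mg/kg doses convert to ng/mL via 1 mg = 1e6 ng.

The PK parameters of the compound studied are not public and are a
configuration input. The shipped default (CL = 100 mL/h/kg,
V = 150 mL/kg, t½ ≈ 1 h) is a **placeholder** on the scale typical of
mouse IV small molecules, chosen once so the study's dose range spans
minimal to tumor-regressing activity; every recovery analysis uses the
same configuration for generation and fitting, so conclusions do not
depend on it.

Regimen exposure is summarized as Cavg = AUC/Δt by non-compartmental
analysis: trapezoid on a 100-point-per-interval grid with log-down
interpolation (exact for mono-exponential decay), windowed from the
first dose to the last dose plus the final inter-dose interval
(configurable; whether a washout period belongs in the window is a
design choice, and the treatment-period window was adopted as the
natural "regimen-specific" average). Built-in schedules: Q1dx5 (0–96 h
daily), Q3dx6 (every 72 h × 6), BIWx6 (six doses with alternating
72/96 h gaps — the exact weekday spacing is not conventional, so it is
configurable).

## Population (NLME) estimation

Observations follow y = f + (a + b·f)·ε with ε ~ N(0,1) — a combined
residual error in the `sd = a + b·f` ("combined1") convention; additive
and proportional alternatives are selectable. Individual parameters are
log-normal, p_i = p_pop·exp(η_i), η ~ N(0, ω²), diagonal covariance,
reported as CV% = 100·√(exp(ω²)−1). The baseline volume TV0 is a
per-animal regressor fixed at the observed (noisy) baseline
measurement — what an analyst of real data would use — not an estimated
parameter.

Estimation modes:

* **two-stage** (default): per-animal weighted least squares on the
  log-parameter scale, pooled by a DerSimonian–Laird random-effects
  summary of the log-estimates, then refined by an iterative two-stage
  (EM-like) loop: per-animal MAP η under the current population
  distribution, typical values recentred by the mean MAP η, and each ω²
  updated as mean(η̂²) + mean posterior variance from the curvature of
  the log joint — animals carrying no information on a parameter (e.g.
  vehicle animals and the kill rate) contribute exactly their prior
  variance and are neutral. Deterministic and fast (~1 min for 104
  animals).
* **saem**: stochastic-approximation EM — componentwise random-walk
  Metropolis on η per animal (three sweeps per iteration by default),
  stochastic averaging of the lognormal sufficient statistics over an
  exploration phase (step 1) and a smoothing phase (step 1/k), with
  simulated annealing (omegas may shrink at most 2 % per exploration
  iteration) to prevent premature variance collapse. Residual (a, b) is
  re-estimated by ML each iteration and SA-smoothed; because residuals
  taken against posterior draws carry the draws' own spread, the final
  (a, b) is re-estimated once more at the conditional modes (MAP
  predictions), which is the convention the IWRES diagnostics assume.
  Seeded and reproducible.

The recommended recipe — used by the pipeline and the acceptance
analyses — initializes SAEM from the two-stage fit. The marginal
likelihood for AIC/model comparison is evaluated by the Laplace
approximation at the MAP (default), with importance sampling and
adaptive Gauss–Hermite quadrature (tensor grid, small datasets)
available; IS and AGQ agree within 0.5 on toy data by test.
Empirical-Bayes estimates are MAP η per animal;
shrinkage = 100·(1 − sd(η̂)/ω).

Identifiability at this design, learned from simulation: λ0 is rich
(daily early sampling); k is informed only by treated arms, weakly at
the lowest dose; λ1 is informed only by observations above the switch
volume (~941 mm³ at the published values), a window the event rule
truncates. Animals whose realized switch volume exceeds the 1,500 mm³
endpoint never show linear-phase data at all, and which animals those
are correlates with their η — a selection effect that moment-based
pooling cannot correct, which is why the SAEM refinement (posterior
sampling extracts the partial "no bend observed" information) is the
recommended final stage. Residual a and b are individually
soft-identified (most volumes are large enough that b dominates); their
sum a + b·f is recovered well.

## Time-to-event model

The event is the first scheduled measurement at or above 1,500 mm³
(discrete detection, matching caliper practice; continuous
interpolation is available for sensitivity analysis); animals never
reaching it are right-censored at their last observation. The primary
family is the log-logistic hazard

    h(t) = (s/Te)·(t/Te)^(s−1) / [1 + (t/Te)^s],   S(t) = 1/(1+(t/Te)^s)

with shape s = 4 (fixed by default; an estimate-s mode serves the
family screen against Weibull `h=(s/Te)(t/Te)^(s−1)`, Gompertz
`h=(1/Te)exp(s·t/Te)` and exponential `h=1/Te` — parameterizations as
written, since scale/shape conventions vary across texts). The scale Te
is exactly the median event time (S(Te) = ½).

Covariates act on the scale of animal i:

    Te_i = Te_pop · exp(βλ0·(λ0i/med(λ0) − 1))
                  · exp(βλ1·(λ1i/med(λ1) − 1))
                  · exp(βCavg·Cavg_i/med(Cavg)) · exp(η_i)

The growth-rate terms are median-centered; the exposure term is
ratio-scaled **without** the −1 offset, so a vehicle animal (Cavg = 0)
has multiplier one — the natural zero-exposure reference. Medians are
computed over all fitted animals, controls included (configurable).
Negative growth coefficients mean faster tumors reach the endpoint
sooner; a positive exposure coefficient means higher Cavg prolongs
survival.

Fitting is right-censored maximum likelihood (events contribute
log h + log S, censored records log S), L-BFGS-B with a Nelder–Mead
polish on log-scale/shape and raw coefficients; SEs come from the
finite-difference observed information with delta-method back-
transformation. The frailty η (log-normal with SD ω_Te) is marginalized
by 30-node Gauss–Hermite quadrature; with one event per animal it is
weakly identified and typically collapses to its positivity floor
(1e-4) — consistent with the near-zero published estimate — so fixed-ω
and no-frailty modes are provided. Event simulation inverts the closed-
form survival functions (log-logistic: t = Te·(1/u − 1)^{1/s}).

## Evaluation toolkit

* **Kaplan–Meier** curves via lifelines' product-limit estimator,
  wrapped as right-continuous step functions with at-risk counts; an
  exhaustive counting oracle verifies all small instances exactly.
* **VPC**: replicate studies are simulated from the fitted TTE model at
  the observed covariates and censoring times; a KM curve per replicate
  and arm is evaluated on a common grid, and the pointwise 5th/50th/95th
  percentiles form the 90 % prediction band (the band construction is a
  package choice; pointwise percentiles on a fixed grid). 1000
  replicates for reporting; self-simulation calibration is verified at
  300 replicates in the tests.
* **Bootstrap**: subjects resampled with replacement, stratified by arm
  so every replicate preserves per-arm counts; refit failures are
  excluded, counted, and flagged above 10 %. Percentile 95 % CIs.
  TGI-stage bootstraps default to the fast two-stage mode.
* **GOF tables**: population predictions (typical values), individual
  predictions (EBEs) and IWRES = (obs − ipred)/(a + b·ipred); under a
  correctly specified model IWRES are approximately standard normal
  (checked: mean within ±0.1, SD within [0.9, 1.1] at the study scale).

## Synthetic study generator

The generator is the study-design oracle for every recovery analysis.
Defaults emulate the source study's stated conditions: 104 mice in
seven arms over three experiments — vehicle (n=20); 0.3/0.6/0.9 mg/kg
Q1dx5 (n=14 each); 2.40 mg/kg Q3dx6 in two experiments (n=14 each);
2.85 mg/kg BIWx6 (n=14) — per-arm sizes are not public, so the split is
a documented choice totalling 104, configurable. Baselines are uniform
on 37–251 mm³; sampling is daily through each arm's dosing period
(vehicle follows the 96 h experiment-1 window) then twice weekly
(72/96 h alternating) to day 100; the event threshold is 1,500 mm³.
Residual noise is applied to the observations only (the latent
trajectory is noise-free, matching the NLME observation model), floored
at 0.5 mm³ (a caliper cannot record a non-positive volume; with the
published error magnitudes this floor is hit in well under 1 % of
measurements). The observation at which the (noisy) measurement first
reaches the threshold is retained — it defines the event — and later
rows are dropped; otherwise the animal is censored at its last
scheduled measurement. Every generated animal's true (λ0, λ1, k, TV0,
η) is recorded in a truth table so recovery bias can be computed
without re-derivation.

What the generator does **not** emulate: inter-experiment batch
effects, pooling with historical controls, body-weight or toxicity
dynamics, PK variability between animals, and measurement-schedule
irregularities of real colonies. Passing recovery tests therefore shows
the estimation machinery is faithful to its own assumptions at the
study's scale and design — not that those assumptions hold in any
particular real dataset.

## Problem sizes and seeds

All analyses are seeded and deterministic given the seed. The package's
own acceptance analyses use: one 104-mouse study for TGI recovery
(two-stage + SAEM at 300+200 iterations, ~6 min); 20 replicate
104-animal event datasets for TTE recovery (~2 min); 300-replicate VPC
calibration; bootstrap coverage at 20 outer × 60 inner replicates.
These sizes were chosen so the complete analysis reruns comfortably on
a laptop while leaving Monte-Carlo error well below the tolerances
being checked; the reporting defaults (1000 VPC simulations, 1000
bootstrap runs) remain the pipeline defaults.

## Known limitations

* The spec of the real studies (per-arm sizes, censoring pattern,
  experiment batches) is only partially public; recovery targets are
  defined under the synthetic design above.
* λ1 recovery is structurally hampered by the endpoint rule (see
  identifiability note); at unlucky seeds the maximum-likelihood
  estimate of λ0/λ1 can sit >20 % from the generating value even when
  the optimizer is verified to have found the likelihood optimum.
* SAEM standard errors are asymptotic lognormal-summary approximations;
  bootstrap is the supported route to interval estimates.
* The TTE stage treats covariates as fixed known quantities; EBE
  estimation error is not propagated (the two-stage framework's usual
  caveat).
* Cavg is regimen-level, so the exposure-survival association is a
  between-regimen, not individual-level, relationship.
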