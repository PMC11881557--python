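# Methods

## Structural and covariate model

The concentration model is the linear two-compartment model with zero-order
infusion input, parameterized by clearance CL (L/h), central volume V1 (L),
inter-compartmental clearance Q (L/h), and peripheral volume V2 (L), all
referenced to a 70-kg subject. The primary evaluator is the closed-form
bi-exponential solution: hybrid rate constants λ1, λ2 are the roots of
λ² − (k10+k12+k21)λ + k10·k21 with k10 = CL/V1, k12 = Q/V1, k21 = Q/V2, and
each infusion contributes

    C(t) = (R/V1) Σ_i (A_i/λ_i) (1 − e^{−λ_i t_e}) e^{−λ_i t_p}

with t_e the time infused and t_p the time since the infusion ended;
profiles superpose over doses. The same system is also integrated
numerically (LSODA, rtol 1e-10, atol 1e-12, segment-by-segment between
input discontinuities) as an independent oracle; the two agree to better
than 1e-6 relative across randomized parameter/regimen suites. When the two
disposition roots (nearly) coincide — detected as a discriminant below
1e-10 of its natural scale — the closed form loses precision and the
evaluator falls back to the ODE path rather than an analytic limit.

Covariate effects multiply the typical values: fixed allometric weight
scaling (exponent 0.75 on CL and Q, 1 on V1 and V2, center 70 kg), power
models on continuous covariates such as creatinine clearance (center
120 mL/min/1.73 m²), and factor models for categorical covariates. The
bedside Schwartz helper (0.413 · height / serum creatinine) is provided for
deriving CrCL; the synthetic generator samples CrCL directly. Covariates
are treated as constant per subject (baseline values); time-varying renal
function is not supported.

Individual parameters are θ_i = θ_typ · exp(η + IOV-term). IIV is estimated
on CL and V1 only; the variability of Q and V2 is fixed at zero (a sparse
opportunistic design cannot inform it). IOV applies to CL with one extra η
per (subject, occasion-category), one variance per category (pre- and
post-operative), and the intra-operative occasion as the zero reference.
Occasions are half-open time windows [start, end).

**Occasion convention.** The parameter set of an observation's occasion is
applied to the subject's entire dosing history when predicting that
observation (the realization interface takes a single occasion label). This
differs from integrating through piecewise parameter changes at occasion
boundaries; it is used consistently in simulation, estimation, and
diagnostics, so all self-consistency properties hold under it.

## Estimation

The marginal likelihood is approximated in the FOCE-I family. For subject i
with proportional residual variance v_j = σ²·f_j², the conditional objective

    h(η) = Σ_j [(y_j − f_j(η))²/v_j + ln v_j] + ηᵀΩ⁻¹η

is minimized over the active η components by damped Gauss–Newton with a
finite-difference Jacobian (cold start at η = 0, inner improvement tolerance
1e-8, at most 60 iterations), and the subject's −2·log-likelihood
contribution is the Laplacian approximation at the mode with the
Gauss–Newton Hessian and interaction (v evaluated at conditional
predictions):

    OFV_i = Σ_j [(y−f̂)²/v̂ + ln(2π v̂)] + η̂ᵀΩ⁻¹η̂ + ln|Ω| + ln|GᵀV⁻¹G + Ω⁻¹|

With no random effects this reduces exactly to the proportional-error
weighted least-squares deviance. Predictions inside the likelihood are
floored at 1e-8 mg/L to keep the proportional-error model non-degenerate.
No claim of bit-compatibility with any specific commercial estimator is
made; the contract is the behavior verified by the test suite (closed-form
reduction at ω = 0, parameter recovery, selection operating
characteristics).

The outer problem estimates typical values and variance parameters on the
log scale (positivity by construction) and free covariate exponents
unconstrained, by Nelder–Mead with adaptive simplex (function tolerance
1e-6). Empirical Bayes estimates are the per-subject η modes at the
solution; η-shrinkage is 1 − SD(EBE)/ω per component. ω, IOV, and σ are
reported as CV% = 100·sqrt(variance), the usual convention for exponential
models. AIC = OFV + 2p ranks nested structural alternatives (a
one-compartment reduction is fit by fixing Q and V2). Additive and combined
residual-error models are not implemented as defaults; the proportional
model is the package's error model.

Stepwise covariate selection uses greedy forward inclusion (largest ΔOFV,
strictly > 3.84 per 1-df effect) followed by backward elimination (an effect
is removed unless its removal worsens OFV strictly by > 6.63). The
nonparametric bootstrap resamples subjects with replacement to the original
subject count, refits, and reports per-parameter medians and 2.5/97.5
percentile intervals; replicate failures are counted and excluded, with a
warning above 20%. Standard errors are bootstrap-based; no
inverse-Hessian covariance step is attempted.

The pcVPC bins observations on time-after-dose into equal-count bins
(default 8), scales observed and simulated values by (bin-median population
prediction)/(row population prediction), and compares observed 5/50/95th
percentiles with the 90% interval of each simulated percentile over the
replicates. Simulated replicates keep the original design (doses, times,
covariates, occasions) and include residual error. Degenerate designs with
a single time-after-dose collapse to one bin; empty bins are dropped with a
warning.

## Synthetic study generator

The generator emulates the study conditions and is the source of every
dataset the tests use: 34 subjects by default; log-normal marginals matched
to the reported medians and IQRs (weight 20.0 [12.65–55.33] kg, age 7.07
[3.05–14.48] y, CrCL 143 [102.81–181.53] mL/min/1.73 m², surgery duration
5.32 [2.93–8.89] h) by setting μ = ln(median) and σ from the symmetric
log-quartile spread; surgery-type frequencies 15/2/9/8 out of 34 for
liver transplant/TPIAT/abdominal/ENT. Weight and age share a latent normal
factor (rank correlation 0.8) for pediatric plausibility; other covariates
are independent. Dosing is 80–90 mg/kg per 30-min infusion every 2–3 h,
capped at 3,000 or 4,000 mg above 45 kg. Sampling is opportunistic: uniform
draw times over the treated span, draws during any 30-min infusion window
rejected, per-subject counts from a shifted binomial spanning 1–19 with
mean 286/34. Pre-operative windows exist for ~30% of subjects (the study
reports "a subset" without a number; 30% is a design choice, 2–8 h long),
and post-operative follow-up spans 4–12 h — both uniform draws chosen once
as plausible perioperative logistics. Observations are y = f·(1+ε) with ε
normal and redrawn if y < 0 (truncation; immaterial at the fitted error
magnitude). A rich-design variant doses every 2 h and samples a fixed
informative grid (distribution phase of the first interval plus a washout
tail past the last dose) for recovery experiments.

What the generator does not emulate: assay quantification limits, sample
timing errors, time-varying renal function, free-fraction nonlinearity, and
drug accumulation across parameter changes at occasion boundaries (see the
occasion convention above). Passing tests therefore demonstrate the
machinery's correctness under the stated generative model, not the clinical
accuracy of any fitted value on real data.

## Dosing simulation

Virtual populations sample weight and CrCL independently and uniformly
within each stratum (weight bands 10–29/30–49/50–69/70–89 kg; CrCL bands
20–29/30–59/60–89/90–119/130–159 mL/min/1.73 m²; the published tables label
the fourth CrCL band 90–129 and that labeling is available as an option —
the two conventions disagree in the source and the narrower band is the
default). Simulations draw IIV (and, outside the intra-operative reference,
IOV) per subject and evaluate the closed form on a 0.05-h grid over an 8-h
horizon (the upper IQR of surgery duration; configurable). Residual error
is excluded: the attainment targets concern true model concentrations.

Q2H attainment reads the concentration at exactly t = 2 h (the instant
before the second dose) and requires it to exceed the target; continuous
infusion requires the concentration at or above the target at every grid
point from the end of the 30-min loading infusion (t = 0.5 h) to the
horizon — the stricter reading of "during the entire surgery period",
configurable via the window start. Loading doses are fixed at 10 mg/kg for
the 8 mg/L target and 20 mg/kg for 32 mg/L. The minimal-dose search walks a
grid (0.5 mg/kg for Q2H, 0.25 mg/kg/h for CI, the granularity of the
published tables) and returns the first dose with PTA ≥ 0.90. Common random
numbers are used across the entire dose grid and stratum table: the
kinetics are linear in dose, so one unit-dose simulation per stratum is
rescaled exactly, and one seed drives every cell. This preserves the
monotone table structure (per-kg dose non-increasing in weight,
non-decreasing in CrCL) that the published tables show.

The packaged model is the total-drug parameter set; the published dose
tables derive from a free-drug model whose parameters appear only in
supplementary material. Any parameter set can be supplied as a YAML config,
and the dosing engine is agnostic to which it is given.

## Numerical choices and problem sizes

Kernels are numba-jitted when numba is available, with identical pure-Python
semantics otherwise. Division follows IEEE semantics inside kernels;
non-finite objectives are caught and treated as rejected points by the
outer optimizer. The test suite runs its simulation experiments at sizes
chosen to characterize behavior precisely while staying economical:
parameter recovery at 100 subjects × 10 samples over 10 seeds; selection
operating characteristics at 40 subjects over 10 replicates per arm;
pcVPC self-consistency as the mean coverage over 10 replicate 34-subject
studies at 200 simulations each (the coverage of a single study fluctuates
around its ~91% expectation, so the averaged estimate is the stable
quantity); dose-table structure on a reduced 2×2 stratum grid at 1,000
virtual patients per cell. The analysis drivers default to 100 bootstrap
replicates and 500 virtual patients per table cell; both procedures scale
to the conventional 1,000 by a flag.

## Known limitations

- The estimator is a FOCE-I-type approximation; OFV values are not
  numerically interchangeable with other implementations, though ΔOFV-based
  decisions are.
- Ω is diagonal; CL–V1 correlation is not estimated.
- Saturable elimination and protein-binding nonlinearity are out of scope;
  "free" vs "total" drug is purely a choice of parameter set.
- Tazobactam is not modeled.
- The IOV occasion convention (above) approximates piecewise-parameter
  integration; with occasion-constant histories the two coincide.
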