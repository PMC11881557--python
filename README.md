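# pippk — population PK and dose optimization of perioperative piperacillin

Piperacillin/tazobactam is standard surgical prophylaxis in critically ill
children, but the guideline regimen (80–100 mg/kg of piperacillin every 2 h)
produces very high peaks, carries nephrotoxicity risk, and is hard to deliver
in an operating room. `pippk` re-implements, as a reusable Python pipeline,
the population-pharmacokinetic analysis behind model-informed alternatives:
a two-compartment nonlinear mixed-effects (NLME) model of piperacillin in
perioperative pediatric patients, its estimation and validation machinery,
and a Monte-Carlo probability-of-target-attainment (PTA) engine that derives
weight- and renal-function-stratified minimal doses.

It is written for pharmacometricians and method developers who want an
open, testable implementation of this analysis chain — not a replacement for
NONMEM on real data.

## The model

Structural model: linear two-compartment kinetics with zero-order (infusion)
input and first-order elimination,

    dA1/dt = rate_in(t) − (CL/V1 + Q/V1)·A1 + (Q/V2)·A2
    dA2/dt = (Q/V1)·A1 − (Q/V2)·A2,          C = A1/V1

solved in closed form (bi-exponential disposition, superposition over doses)
with an ODE integrator retained as an independent oracle.

Fixed effects carry allometric weight scaling, exponent 0.75 on clearances
and 1 on volumes, and a power effect of creatinine clearance on CL. The
final clearance equation is

    CL (L/h) = 7.1 · (WT/70)^0.75 · (CrCL/120)^0.484

Random effects are log-normal: θ_i = θ_pop · exp(η_i + IOV), with
inter-individual variability (IIV) on CL and V1, inter-occasion variability
(IOV) on CL for the pre- and post-operative occasions (intra-operative is
the zero reference), and a proportional residual error. Estimation is a
FOCE-with-interaction-type approximation: per-subject conditional η modes by
penalized least squares, Laplacian objective with a Gauss–Newton Hessian,
residual variance at conditional predictions. Covariates are selected
stepwise with likelihood-ratio gates ΔOFV > 3.84 in (p<0.05), > 6.63 out
(p<0.01); validation uses a nonparametric bootstrap and a
prediction-corrected visual predictive check (pcVPC).

Dose optimization simulates virtual populations per body-weight × CrCL
stratum and finds the smallest dose attaining free-drug targets of 8 mg/L
(1× MIC) and 32 mg/L (4× MIC) in ≥90% of patients: for Q2H 30-min
infusions the first trough must exceed the target; for a 30-min loading dose
plus continuous infusion the concentration must stay above the target from
the end of the loading infusion to the end of surgery.

## Worked example

```python
import pippk as pk

spec = pk.load_final_model()                       # packaged final model
cov = pk.SubjectCovariates(weight=20, crcl=143)    # the median study subject
print(pk.typical_params(spec, cov).cl)             # 3.0204123301071175 L/h

ds = pk.make_study(spec, seed=1)                   # synthetic 34-subject study
print(ds.n_subjects, ds.n_observations)            # 34 273

fit = pk.fit(ds, spec)                             # FOCE-I refit
print(round(fit.ofv, 2))                           # 3064.66
print(round(fit.estimates["cl"], 2))               # 7.36
```

The typical 20-kg subject with CrCL 143 clears piperacillin at ~3.0 L/h —
the allometric factor (20/70)^0.75 ≈ 0.39 times the 70-kg typical value of
7.1 L/h, raised ~9% by the above-reference renal function. The refit of one
synthetic study recovers the generating clearance (7.1) within its sparse-data
sampling error.

The numbered drivers under `analysis/` run the full chain and write their
tables to `results/`:

```sh
python analysis/01_simulate_study.py --seed 1     # cohort + dataset
python analysis/02_fit_model.py                   # stepwise covariates + fit
python analysis/03_validate_model.py              # bootstrap + pcVPC
python analysis/04_dosing_tables.py --n 500       # stratified dose tables
```

`04_dosing_tables.py` prints, e.g., a minimal Q2H dose of 11.5 mg/kg for
the 10–29 kg / CrCL ≥130 stratum at the 8 mg/L target under the packaged
total-drug model, and the loading-dose comparison (10 mg/kg reaches 8 mg/L
in ~6 min, 5 mg/kg in ~13 min — halving the load about doubles the time).
The published dose recommendations were derived from a free-drug parameter
set that is not part of the packaged model; supply it via
`--model your_free_model.yaml` to regenerate those tables.

A CLI mirrors the drivers: `pippk simulate-data | fit | covariate-search |
bootstrap | vpc | pta | dosing-table` (see `pippk --help`).

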