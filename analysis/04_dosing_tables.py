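#!/usr/bin/env python
"""Regenerate the stratified dosing tables and the loading-dose comparison.

Monte-Carlo PTA over the body-weight x CrCL stratum grid for 30-min Q2H
infusions and loading-dose + continuous-infusion regimens, at free-drug
targets 8 mg/L (1x MIC) and 32 mg/L (4x MIC), adequacy = 90% of the virtual
population.  Uses the packaged total-piperacillin model; the study's dose
recommendations were derived from its free-drug model (supplementary
parameters), which can be supplied via --model to reproduce those numbers.

Writes results/dose_table_q2h.csv and results/dose_table_ci.csv.
"""

import argparse
from pathlib import Path

import numpy as np

import pippk as pk
from pippk import dosing

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--n", type=int, default=500)
ap.add_argument("--model", type=Path, default=None,
                help="alternative model config (e.g. free-drug parameters)")
args = ap.parse_args()

root = Path(__file__).resolve().parents[1] / "results"
root.mkdir(exist_ok=True)
spec = pk.read_model_config(args.model) if args.model else pk.load_final_model()

table = pk.dosing_table(spec, targets=(8.0, 32.0), n=args.n, seed=args.seed)
for family, fname in (("q2h", "dose_table_q2h.csv"), ("ldci", "dose_table_ci.csv")):
    sub = table[table["regimen_kind"] == family]
    pk.write_table(sub, root / fname)
    for target in (8.0, 32.0):
        grid = dosing.dose_grid(table, family, target)
        unit = "mg/kg" if family == "q2h" else "mg/kg/h"
        print(f"\n{family.upper()} minimal doses ({unit}), target {target} mg/L:")
        print(grid.to_string())

# loading-dose rationale: time to reach 8 mg/L for the representative subject
typ = pk.typical_params(spec, pk.SubjectCovariates(weight=20.0, crcl=143.0))
for ld in (10.0, 5.0):
    t = pk.time_to_target(typ, ld, 20.0, 8.0)
    print(f"\nloading dose {ld:.0f} mg/kg reaches 8 mg/L in "
          f"{t:.0f} min" if np.isfinite(t) else
          f"\nloading dose {ld:.0f} mg/kg does not reach 8 mg/L during the infusion")
print(f"\nwrote {root / 'dose_table_q2h.csv'} and {root / 'dose_table_ci.csv'}")
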