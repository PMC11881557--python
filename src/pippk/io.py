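"""Dataset and configuration I/O.

The analysis dataset follows the NONMEM rectangular convention: one row per
event, dose rows flagged EVID=1 (AMT in mg, infusion described by DUR in h or
RATE in mg/h), observation rows EVID=0 with the measured concentration in DV
(mg/L).  Times are absolute hours from the first record of the subject's
record block; occasions are labeled pre/intra/post.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .model import (OCCASIONS, CovariateEffect, ModelSpec, RandomEffectSpec,
                    StructuralParams, allometric_effects)

COLUMNS = ["ID", "TIME", "AMT", "RATE", "DUR", "EVID", "DV", "MDV",
           "OCC", "WT", "CRCL", "AGE", "SURG"]
_REQUIRED = ["ID", "TIME", "EVID"]


class DatasetError(ValueError):
    """Dataset violates the PKDataset contract; message lists offending rows."""


@dataclass
class PKDataset:
    """Longitudinal dose/observation records with covariates and occasions."""

    df: pd.DataFrame

    def __post_init__(self):
        self.df = _normalize(self.df)
        errs = validate(self.df)
        if errs:
            raise DatasetError("invalid dataset:\n" + "\n".join(errs))

    @property
    def n_subjects(self) -> int:
        return self.df["ID"].nunique()

    @property
    def n_observations(self) -> int:
        return int((self.df["EVID"] == 0).sum())

    def subject_ids(self) -> list:
        return list(self.df["ID"].drop_duplicates())

    def subject_frame(self, sid) -> pd.DataFrame:
        return self.df[self.df["ID"] == sid]

    def resample_subjects(self, rng: np.random.Generator) -> "PKDataset":
        """Bootstrap replicate: subjects drawn with replacement, re-labeled."""
        ids = self.subject_ids()
        chosen = rng.choice(len(ids), size=len(ids), replace=True)
        parts = []
        for new_id, j in enumerate(chosen):
            block = self.subject_frame(ids[j]).copy()
            block["ID"] = new_id
            parts.append(block)
        return PKDataset(pd.concat(parts, ignore_index=True))

    def fingerprint(self) -> str:
        obs = self.df[self.df["EVID"] == 0]
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(obs[["TIME", "DV"]].to_numpy(float)).tobytes())
        return h.hexdigest()[:16]


def _normalize(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in _REQUIRED:
        if col not in df.columns:
            raise DatasetError(f"missing required column {col}")
    for col in COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    # reconcile RATE and DUR on dose rows: RATE = AMT / DUR
    dose = df["EVID"] == 1
    has_dur = dose & df["DUR"].notna() & (df["DUR"] > 0)
    has_rate = dose & df["RATE"].notna() & (df["RATE"] > 0)
    df.loc[has_dur & ~has_rate, "RATE"] = df.loc[has_dur & ~has_rate, "AMT"] / df.loc[has_dur & ~has_rate, "DUR"]
    df.loc[has_rate & ~has_dur, "DUR"] = df.loc[has_rate & ~has_dur, "AMT"] / df.loc[has_rate & ~has_dur, "RATE"]
    df.loc[dose & df["MDV"].isna(), "MDV"] = 1
    df.loc[(df["EVID"] == 0) & df["MDV"].isna(), "MDV"] = 0
    df.loc[df["OCC"].isna(), "OCC"] = "intra"
    return df[COLUMNS]


def validate(df: pd.DataFrame) -> list[str]:
    """Row-addressed violations of the dataset invariants (empty list = valid)."""
    errs = []
    for i, row in df.iterrows():
        if row["TIME"] < 0:
            errs.append(f"row {i}: negative TIME {row['TIME']}")
        if row["EVID"] == 1:
            if not row["AMT"] > 0:
                errs.append(f"row {i}: dose row with AMT <= 0")
            if not row["DUR"] > 0:
                errs.append(f"row {i}: dose row without positive DUR/RATE")
            if row["MDV"] != 1:
                errs.append(f"row {i}: dose row must have MDV=1")
        elif row["EVID"] == 0:
            if row["MDV"] == 0 and (pd.isna(row["DV"]) or row["DV"] < 0):
                errs.append(f"row {i}: observation with missing/negative DV")
            if row["OCC"] not in OCCASIONS:
                errs.append(f"row {i}: unresolvable occasion {row['OCC']!r}")
        else:
            errs.append(f"row {i}: unknown EVID {row['EVID']}")
    for sid, block in df.groupby("ID", sort=False):
        t = block["TIME"].to_numpy()
        if np.any(np.diff(t) < 0):
            errs.append(f"subject {sid}: TIME not non-decreasing")
        if block["WT"].notna().any() and not (block["WT"].dropna() > 0).all():
            errs.append(f"subject {sid}: non-positive WT")
    return errs


def read_dataset(path) -> PKDataset:
    return PKDataset(pd.read_csv(path))


def write_dataset(ds: PKDataset, path) -> None:
    ds.df.to_csv(path, index=False)


def write_table(result, path) -> None:
    """Write any DataFrame-like result table as canonical CSV."""
    df = result if isinstance(result, pd.DataFrame) else pd.DataFrame(result)
    df.to_csv(path, index=False)


# --------------------------------------------------------------------------
# model configuration files

def spec_to_dict(spec: ModelSpec) -> dict:
    return {
        "theta": {"cl": spec.theta.cl, "v1": spec.theta.v1,
                  "q": spec.theta.q, "v2": spec.theta.v2},
        "covariate_effects": [
            {"parameter": e.parameter, "covariate": e.covariate, "kind": e.kind,
             "exponent_or_factor": e.exponent_or_factor, "center": e.center,
             "fixed": e.fixed}
            for e in spec.covariate_effects],
        "random": {"omega2": dict(spec.random.omega2),
                   "pi2": dict(spec.random.pi2),
                   "sigma2_prop": spec.random.sigma2_prop},
    }


def spec_from_dict(d: dict) -> ModelSpec:
    theta = StructuralParams(**{k: float(v) for k, v in d["theta"].items()})
    effects = []
    for e in d.get("covariate_effects", []):
        if e == "allometric":
            effects.extend(allometric_effects())
        else:
            effects.append(CovariateEffect(
                parameter=e["parameter"], covariate=e["covariate"], kind=e["kind"],
                exponent_or_factor=float(e["exponent_or_factor"]),
                center=float(e.get("center", 1.0)), fixed=bool(e.get("fixed", False))))
    rnd = d.get("random", {})
    random = RandomEffectSpec(
        omega2={k: float(v) for k, v in rnd.get("omega2", {}).items()},
        pi2={k: float(v) for k, v in rnd.get("pi2", {}).items()},
        sigma2_prop=float(rnd.get("sigma2_prop", 0.0)))
    return ModelSpec(theta=theta, covariate_effects=tuple(effects), random=random)


def read_model_config(path) -> ModelSpec:
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))


def write_model_config(spec: ModelSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=False)


def load_final_model() -> ModelSpec:
    """The packaged final total-piperacillin model (allometry + CrCL power on CL)."""
    from importlib.resources import files
    with (files("pippk") / "data" / "final_model.yaml").open() as fh:
        return spec_from_dict(yaml.safe_load(fh))
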