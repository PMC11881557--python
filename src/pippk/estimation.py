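"""Nonlinear mixed-effects estimation for the population PK model.

The marginal likelihood is approximated FOCE-I style: for each subject the
conditional mode of the random effects (eta) is found by penalized
least-squares, and the Laplacian approximation with a Gauss-Newton Hessian is
evaluated there, with the proportional residual variance taken at the
conditional predictions (the "interaction").  The objective function value
(OFV) reported everywhere is -2 x this approximate log-likelihood, so
likelihood-ratio gates of 3.84 (forward, p<0.05) and 6.63 (backward, p<0.01)
at 1 df apply directly.

Also here: AIC ranking, stepwise covariate selection, the nonparametric
bootstrap, the prediction-corrected visual predictive check, and residual
tables for goodness-of-fit plots.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from . import _kernels
from .io import PKDataset
from .model import (OCC_CODE, ModelSpec, RandomEffectSpec, StructuralParams,
                    SubjectCovariates, typical_params)

PRED_FLOOR = 1e-8  # mg/L floor inside the proportional-error likelihood
INNER_TOL = 1e-8
OUTER_TOL = 1e-6
ETA_LABELS = ("eta_cl", "eta_v1", "iov_pre", "iov_post")


# --------------------------------------------------------------------------
# design extraction

class _Design:
    """Flat-array view of a dataset, ready for the numeric kernels."""

    def __init__(self, dataset: PKDataset, spec: ModelSpec):
        self.ids = dataset.subject_ids()
        n = len(self.ids)
        dose_t, dose_dur, dose_rate = [], [], []
        obs_t, obs_y, obs_occ = [], [], []
        self.dose_off = np.zeros(n + 1, dtype=np.int64)
        self.obs_off = np.zeros(n + 1, dtype=np.int64)
        self.covariates: list[SubjectCovariates] = []
        self.has_occ = np.zeros((n, 3), dtype=bool)
        for i, sid in enumerate(self.ids):
            block = dataset.subject_frame(sid)
            doses = block[block["EVID"] == 1]
            obs = block[(block["EVID"] == 0) & (block["MDV"] == 0)]
            dose_t.extend(doses["TIME"])
            dose_dur.extend(doses["DUR"])
            dose_rate.extend(doses["RATE"])
            obs_t.extend(obs["TIME"])
            obs_y.extend(obs["DV"])
            occ = [OCC_CODE[o] for o in obs["OCC"]]
            obs_occ.extend(occ)
            for c in occ:
                self.has_occ[i, c] = True
            self.dose_off[i + 1] = len(dose_t)
            self.obs_off[i + 1] = len(obs_t)
            wt = block["WT"].dropna()
            crcl = block["CRCL"].dropna()
            age = block["AGE"].dropna()
            surg = block["SURG"].dropna()
            self.covariates.append(SubjectCovariates(
                weight=float(wt.iloc[0]) if len(wt) else 70.0,
                crcl=float(crcl.iloc[0]) if len(crcl) else 120.0,
                age=float(age.iloc[0]) if len(age) else None,
                surgery_type=str(surg.iloc[0]) if len(surg) else "abdominal"))
        self.dose_t = np.array(dose_t, dtype=float)
        self.dose_dur = np.array(dose_dur, dtype=float)
        self.dose_rate = np.array(dose_rate, dtype=float)
        self.obs_t = np.array(obs_t, dtype=float)
        self.obs_y = np.array(obs_y, dtype=float)
        self.obs_occ = np.array(obs_occ, dtype=np.int64)
        self.n_subjects = n
        self.n_obs = len(obs_t)
        # per-effect covariate log-ratios / indicators for fast multiplier updates
        self._effect_x = {}
        for e in spec.covariate_effects:
            key = (e.covariate, e.kind, e.center)
            if key not in self._effect_x:
                x = np.array([c.value_of(e.covariate) for c in self.covariates])
                if e.kind in ("power-continuous", "allometric-fixed"):
                    if np.any(x <= 0):
                        raise ValueError(f"non-positive covariate {e.covariate!r}")
                    self._effect_x[key] = np.log(x / e.center)
                else:
                    self._effect_x[key] = x

    def typ_all(self, spec: ModelSpec) -> np.ndarray:
        """(n_subjects, 4) typical parameters under the spec's covariate model."""
        logm = np.zeros((self.n_subjects, 4))
        col = {"cl": 0, "v1": 1, "q": 2, "v2": 3}
        for e in spec.covariate_effects:
            x = self._effect_x[(e.covariate, e.kind, e.center)]
            if e.kind in ("power-continuous", "allometric-fixed"):
                logm[:, col[e.parameter]] += e.exponent_or_factor * x
            else:
                logm[:, col[e.parameter]] += math.log(e.exponent_or_factor) * x
        base = np.log(spec.theta.as_array())
        return np.exp(base[None, :] + logm)

    def active_mask(self, om2: np.ndarray) -> np.ndarray:
        act = np.zeros((self.n_subjects, 4), dtype=bool)
        act[:, 0] = om2[0] > 0
        act[:, 1] = om2[1] > 0
        act[:, 2] = (om2[2] > 0) & self.has_occ[:, 1]
        act[:, 3] = (om2[3] > 0) & self.has_occ[:, 2]
        return act


def _ofv_design(design: _Design, spec: ModelSpec, typ_all=None):
    om2 = spec.random.omega2_vector()
    sigma2 = spec.random.sigma2_prop
    if sigma2 <= 0:
        raise ValueError("proportional residual variance must be > 0 for the likelihood")
    if typ_all is None:
        typ_all = design.typ_all(spec)
    total, etas = _kernels.ofv_dataset(
        typ_all, om2, sigma2, design.dose_off, design.dose_t, design.dose_dur,
        design.dose_rate, design.obs_off, design.obs_t, design.obs_y,
        design.obs_occ, design.active_mask(om2), PRED_FLOOR, INNER_TOL, 60)
    if not math.isfinite(total):
        raise RuntimeError("non-finite objective; check predictions/parameters")
    return total, etas


def ofv(dataset: PKDataset, spec: ModelSpec) -> float:
    """FOCE-I objective (-2 approximate log-likelihood) at the spec's values."""
    return _ofv_design(_Design(dataset, spec), spec)[0]


# --------------------------------------------------------------------------
# maximum-likelihood fit

@dataclass
class FitResult:
    spec: ModelSpec                 # spec with fitted values substituted
    ofv: float
    n_params: int
    ebes: pd.DataFrame              # per-subject eta modes at the solution
    shrinkage: dict                 # component -> eta-shrinkage in %
    convergence: bool
    message: str = ""
    fingerprint: str = ""
    n_obs: int = 0

    @property
    def estimates(self) -> dict:
        """Flat scalar view of every estimated quantity (variances as CV%)."""
        s = self.spec
        out = {"cl": s.theta.cl, "v1": s.theta.v1, "q": s.theta.q, "v2": s.theta.v2}
        for e in s.covariate_effects:
            if not e.fixed:
                out[f"{e.covariate}_on_{e.parameter}"] = e.exponent_or_factor
        for p, v in s.random.omega2.items():
            if v > 0:
                out[f"iiv_{p}_cv"] = 100.0 * math.sqrt(v)
        for occ, v in s.random.pi2.items():
            if v > 0:
                out[f"iov_{occ}_cv"] = 100.0 * math.sqrt(v)
        out["prop_error_cv"] = 100.0 * math.sqrt(s.random.sigma2_prop)
        return out

    def aic(self) -> float:
        return self.ofv + 2.0 * self.n_params


class _FitProblem:
    """Maps the free parameter vector to a ModelSpec and evaluates the OFV.

    Scale parameters (thetas, standard deviations) live on the log scale so
    positivity is structural; covariate exponents are unconstrained.
    """

    def __init__(self, design: _Design, spec: ModelSpec, fix_theta=()):
        self.design = design
        self.spec0 = spec
        names = ("cl", "v1", "q", "v2")
        self.est_theta = [i for i, p in enumerate(names) if p not in fix_theta]
        self.est_effects = [i for i, e in enumerate(spec.covariate_effects) if not e.fixed]
        om2 = spec.random.omega2_vector()
        self.est_var = [k for k in range(4) if om2[k] > 0]
        theta0 = np.log(spec.theta.as_array())
        x0 = [theta0[i] for i in self.est_theta]
        for i in self.est_effects:
            x0.append(spec.covariate_effects[i].exponent_or_factor)
        for k in self.est_var:
            x0.append(0.5 * math.log(om2[k]))
        x0.append(0.5 * math.log(spec.random.sigma2_prop))
        self.x0 = np.array(x0)
        self.n_params = len(x0)

    def unpack(self, x: np.ndarray) -> ModelSpec:
        th = self.spec0.theta.as_array()
        for pos, i in enumerate(self.est_theta):
            th[i] = math.exp(x[pos])
        theta = StructuralParams(*th)
        effects = list(self.spec0.covariate_effects)
        pos = len(self.est_theta)
        for i in self.est_effects:
            effects[i] = replace(effects[i], exponent_or_factor=float(x[pos]))
            pos += 1
        om2 = self.spec0.random.omega2_vector()
        for k in self.est_var:
            om2[k] = math.exp(2.0 * x[pos])
            pos += 1
        sigma2 = math.exp(2.0 * x[pos])
        random = RandomEffectSpec(
            omega2={p: om2[j] for p, j in (("cl", 0), ("v1", 1)) if om2[j] > 0},
            pi2={occ: om2[j] for occ, j in (("pre", 2), ("post", 3)) if om2[j] > 0},
            sigma2_prop=sigma2)
        return ModelSpec(theta=theta, covariate_effects=tuple(effects), random=random)

    def __call__(self, x: np.ndarray) -> float:
        try:
            return _ofv_design(self.design, self.unpack(x))[0]
        except (ValueError, RuntimeError, ZeroDivisionError, OverflowError,
                FloatingPointError, np.linalg.LinAlgError):
            return 1e12


def fit(dataset: PKDataset, spec: ModelSpec, maxiter: int | None = None,
        fix_theta=()) -> FitResult:
    """Estimate fixed effects, variances, and free covariate exponents by FOCE-I.

    ``spec`` supplies both the model structure and the initial values;
    components with zero variance in ``spec`` stay fixed at zero, and any
    parameter named in ``fix_theta`` is held at its initial value (e.g. a
    one-compartment reduction fixes q and v2).
    """
    design = _Design(dataset, spec)
    if design.n_obs == 0:
        raise ValueError("dataset has no observations")
    prob = _FitProblem(design, spec, fix_theta=fix_theta)
    res = minimize(prob, prob.x0, method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": OUTER_TOL,
                            "maxiter": maxiter or 400 * prob.n_params,
                            "adaptive": True})
    fitted = prob.unpack(res.x)
    total, etas = _ofv_design(design, fitted)
    ebes = pd.DataFrame(etas, columns=list(ETA_LABELS))
    ebes.insert(0, "ID", design.ids)
    act = design.active_mask(fitted.random.omega2_vector())
    ebes[pd.DataFrame(~act, columns=list(ETA_LABELS))] = np.nan
    om2 = fitted.random.omega2_vector()
    shrink = {}
    for k, lab in enumerate(ETA_LABELS):
        if om2[k] > 0:
            vals = etas[act[:, k], k]
            if len(vals) > 1:
                shrink[lab] = 100.0 * (1.0 - np.std(vals, ddof=1) / math.sqrt(om2[k]))
    return FitResult(spec=fitted, ofv=total, n_params=prob.n_params, ebes=ebes,
                     shrinkage=shrink, convergence=bool(res.success),
                     message=res.message, fingerprint=dataset.fingerprint(),
                     n_obs=design.n_obs)


def compare_aic(fits: list[FitResult]) -> list[tuple[int, float]]:
    """Rank fits of the same dataset by AIC = OFV + 2 p; ties favor fewer parameters.

    Returns (index into ``fits``, AIC) pairs, best first.
    """
    prints = {f.fingerprint for f in fits}
    if len(prints) > 1:
        raise ValueError("AIC comparison requires fits of the identical dataset")
    order = sorted(range(len(fits)), key=lambda i: (fits[i].aic(), fits[i].n_params))
    return [(i, fits[i].aic()) for i in order]


# --------------------------------------------------------------------------
# stepwise covariate selection

FORWARD_GATE = 3.84   # chi^2(1), p < 0.05; inclusion requires dOFV > gate
BACKWARD_GATE = 6.63  # chi^2(1), p < 0.01; retention requires dOFV > gate


@dataclass
class CovariateSearchResult:
    forward_path: list = field(default_factory=list)   # (effect, dOFV, included)
    retained: list = field(default_factory=list)
    backward_removed: list = field(default_factory=list)
    base_ofv: float = float("nan")
    final_ofv: float = float("nan")
    final_fit: FitResult | None = None


def stepwise_covariates(dataset: PKDataset, spec: ModelSpec, candidates,
                        maxiter: int | None = None) -> CovariateSearchResult:
    """Greedy forward inclusion (dOFV > 3.84) then backward elimination (dOFV > 6.63).

    Both gates are strict inequalities at 1 degree of freedom per effect.
    Candidates whose fit fails are skipped with a warning.
    """
    result = CovariateSearchResult()
    base_fit = fit(dataset, spec, maxiter=maxiter)
    result.base_ofv = base_fit.ofv
    current_spec, current_ofv, current_fit = base_fit.spec, base_fit.ofv, base_fit
    remaining = list(candidates)
    while remaining:
        best = None
        for cand in remaining:
            try:
                f = fit(dataset, current_spec.with_effect(cand), maxiter=maxiter)
            except Exception as exc:  # noqa: BLE001 - candidate failure is data-dependent
                warnings.warn(f"candidate {cand.covariate} on {cand.parameter} "
                              f"failed to fit and was skipped: {exc}")
                result.forward_path.append((cand, float("nan"), False))
                continue
            drop = current_ofv - f.ofv
            result.forward_path.append((cand, drop, drop > FORWARD_GATE))
            if drop > FORWARD_GATE and (best is None or drop > best[1]):
                best = (cand, drop, f)
        if best is None:
            break
        cand, _, f = best
        remaining = [c for c in remaining if c is not cand]
        result.retained.append(cand)
        current_spec, current_ofv, current_fit = f.spec, f.ofv, f
    # backward elimination: drop the least-supported effect until all survive
    changed = True
    while changed and result.retained:
        changed = False
        worst = None
        for cand in result.retained:
            reduced = replace(current_spec, covariate_effects=tuple(
                e for e in current_spec.covariate_effects if e is not _match(current_spec, cand)))
            f = fit(dataset, reduced, maxiter=maxiter)
            rise = f.ofv - current_ofv
            if rise <= BACKWARD_GATE and (worst is None or rise < worst[1]):
                worst = (cand, rise, f)
        if worst is not None:
            cand, _, f = worst
            result.retained.remove(cand)
            result.backward_removed.append(cand)
            current_spec, current_ofv, current_fit = f.spec, f.ofv, f
            changed = True
    result.final_ofv = current_ofv
    result.final_fit = current_fit
    return result


def _match(spec: ModelSpec, cand):
    for e in spec.covariate_effects:
        if (e.parameter, e.covariate, e.kind) == (cand.parameter, cand.covariate, cand.kind):
            return e
    raise KeyError(f"effect {cand.covariate} on {cand.parameter} not in spec")


# --------------------------------------------------------------------------
# nonparametric bootstrap

@dataclass
class BootstrapResult:
    n_replicates: int
    n_failed: int
    estimates: pd.DataFrame       # one row per successful replicate
    summary: pd.DataFrame         # parameter, median, ci_lower, ci_upper
    warning: str = ""


def bootstrap(dataset: PKDataset, spec: ModelSpec, n: int, seed: int,
              maxiter: int | None = None) -> BootstrapResult:
    """Resample subjects with replacement, refit, summarize percentile CIs."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    rows, failed = [], 0
    for _ in range(n):
        rep = dataset.resample_subjects(rng)
        try:
            rows.append(fit(rep, spec, maxiter=maxiter).estimates)
        except Exception:  # noqa: BLE001 - replicate failure is expected occasionally
            failed += 1
    est = pd.DataFrame(rows)
    summary = pd.DataFrame({
        "parameter": est.columns,
        "median": est.median().to_numpy(),
        "ci_lower": est.quantile(0.025).to_numpy(),
        "ci_upper": est.quantile(0.975).to_numpy()})
    warning = ""
    if n and failed / n > 0.20:
        warning = f"{failed}/{n} bootstrap replicates failed"
        warnings.warn(warning)
    return BootstrapResult(n_replicates=n, n_failed=failed, estimates=est,
                           summary=summary, warning=warning)


# --------------------------------------------------------------------------
# prediction-corrected visual predictive check

@dataclass
class VPCResult:
    bin_edges: np.ndarray
    bin_mid: np.ndarray
    observed: pd.DataFrame        # p5/p50/p95 of prediction-corrected observations
    bands: pd.DataFrame           # lo/hi of each simulated percentile per bin
    n_sim: int


def _population_predictions(design: _Design, spec: ModelSpec) -> np.ndarray:
    typ = design.typ_all(spec)
    pred = np.empty(design.n_obs)
    zero = np.zeros(_kernels.N_ETA)
    for i in range(design.n_subjects):
        d0, d1 = design.dose_off[i], design.dose_off[i + 1]
        o0, o1 = design.obs_off[i], design.obs_off[i + 1]
        pred[o0:o1] = _kernels._predict(
            typ[i], zero, design.dose_t[d0:d1], design.dose_dur[d0:d1],
            design.dose_rate[d0:d1], design.obs_t[o0:o1], design.obs_occ[o0:o1])
    return pred


def _simulate_at_design(design: _Design, spec: ModelSpec,
                        rng: np.random.Generator) -> np.ndarray:
    """One replicate of the observations at the original design (with residual error)."""
    om2 = spec.random.omega2_vector()
    act = design.active_mask(om2)
    sigma = math.sqrt(spec.random.sigma2_prop)
    typ = design.typ_all(spec)
    y = np.empty(design.n_obs)
    for i in range(design.n_subjects):
        eta = np.where(act[i], rng.normal(0.0, np.sqrt(np.where(act[i], om2, 0.0))), 0.0)
        d0, d1 = design.dose_off[i], design.dose_off[i + 1]
        o0, o1 = design.obs_off[i], design.obs_off[i + 1]
        f = _kernels._predict(typ[i], eta, design.dose_t[d0:d1],
                              design.dose_dur[d0:d1], design.dose_rate[d0:d1],
                              design.obs_t[o0:o1], design.obs_occ[o0:o1])
        yy = f * (1.0 + rng.normal(0.0, sigma, f.shape))
        bad = yy < 0
        while np.any(bad):  # truncate residual draws at non-negative concentration
            yy[bad] = f[bad] * (1.0 + rng.normal(0.0, sigma, bad.sum()))
            bad = yy < 0
        y[o0:o1] = yy
    return y


def _time_after_dose(design: _Design) -> np.ndarray:
    tad = np.empty(design.n_obs)
    for i in range(design.n_subjects):
        d0, d1 = design.dose_off[i], design.dose_off[i + 1]
        o0, o1 = design.obs_off[i], design.obs_off[i + 1]
        starts = design.dose_t[d0:d1]
        for j in range(o0, o1):
            prior = starts[starts <= design.obs_t[j]]
            tad[j] = design.obs_t[j] - (prior.max() if prior.size else 0.0)
    return tad


def pcvpc(dataset: PKDataset, fit_result: FitResult, n_sim: int = 1000,
          bins: int = 8, seed: int = 0,
          percentiles=(5.0, 50.0, 95.0)) -> VPCResult:
    """Prediction-corrected VPC of ``dataset`` under the fitted model.

    Observations and simulations are scaled within each time-after-dose bin by
    (bin-median population prediction) / (row population prediction); bands are
    the 90% interval of each simulated percentile over ``n_sim`` replicates.
    """
    spec = fit_result.spec
    design = _Design(dataset, spec)
    pred = np.maximum(_population_predictions(design, spec), PRED_FLOOR)
    tad = _time_after_dose(design)
    edges = np.quantile(tad, np.linspace(0, 1, bins + 1))
    edges = np.unique(edges)
    if len(edges) < 2:  # all observations share one time-after-dose
        edges = np.array([edges[0] - 0.5, edges[0] + 0.5])
    idx = np.clip(np.searchsorted(edges, tad, side="right") - 1, 0, len(edges) - 2)
    n_bins = len(edges) - 1
    binmed = np.array([np.median(pred[idx == b]) if np.any(idx == b) else np.nan
                       for b in range(n_bins)])
    keep = [b for b in range(n_bins) if np.any(idx == b)]
    if len(keep) < n_bins:
        warnings.warn("empty pcVPC bins dropped")
    corr = binmed[idx] / pred

    def bin_pcts(y):
        out = np.empty((len(keep), len(percentiles)))
        ypc = y * corr
        for r, b in enumerate(keep):
            out[r] = np.percentile(ypc[idx == b], percentiles)
        return out

    obs_p = bin_pcts(design.obs_y)
    rng = np.random.default_rng(seed)
    sims = np.empty((n_sim, len(keep), len(percentiles)))
    for s in range(n_sim):
        sims[s] = bin_pcts(_simulate_at_design(design, spec, rng))
    lo = np.percentile(sims, 5.0, axis=0)
    hi = np.percentile(sims, 95.0, axis=0)
    cols = [f"p{int(p)}" for p in percentiles]
    mids = np.array([0.5 * (edges[b] + edges[b + 1]) for b in keep])
    observed = pd.DataFrame(obs_p, columns=cols)
    bands = pd.DataFrame(
        np.hstack([lo, hi]), columns=[f"{c}_lo" for c in cols] + [f"{c}_hi" for c in cols])
    return VPCResult(bin_edges=edges, bin_mid=mids, observed=observed,
                     bands=bands, n_sim=n_sim)


# --------------------------------------------------------------------------
# goodness of fit

def gof(fit_result: FitResult, dataset: PKDataset) -> pd.DataFrame:
    """Residual table: PRED, IPRED, IWRES, and population weighted residuals."""
    spec = fit_result.spec
    design = _Design(dataset, spec)
    pred = np.maximum(_population_predictions(design, spec), PRED_FLOOR)
    if len(fit_result.ebes):
        by_id = fit_result.ebes.set_index("ID")[list(ETA_LABELS)].fillna(0.0)
        etas = np.array([by_id.loc[sid].to_numpy() if sid in by_id.index
                         else np.zeros(4) for sid in design.ids])
    else:
        etas = np.zeros((design.n_subjects, 4))
    typ = design.typ_all(spec)
    ipred = np.empty(design.n_obs)
    ids = np.empty(design.n_obs, dtype=object)
    for i in range(design.n_subjects):
        d0, d1 = design.dose_off[i], design.dose_off[i + 1]
        o0, o1 = design.obs_off[i], design.obs_off[i + 1]
        ipred[o0:o1] = _kernels._predict(
            typ[i], etas[i], design.dose_t[d0:d1], design.dose_dur[d0:d1],
            design.dose_rate[d0:d1], design.obs_t[o0:o1], design.obs_occ[o0:o1])
        ids[o0:o1] = design.ids[i]
    ipred = np.maximum(ipred, PRED_FLOOR)
    sigma = math.sqrt(spec.random.sigma2_prop)
    return pd.DataFrame({
        "ID": ids, "TIME": design.obs_t, "TAD": _time_after_dose(design),
        "DV": design.obs_y, "PRED": pred, "IPRED": ipred,
        "IWRES": (design.obs_y - ipred) / (sigma * ipred),
        "PWRES": (design.obs_y - pred) / (sigma * pred)})
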