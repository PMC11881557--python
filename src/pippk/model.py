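"""Two-compartment infusion model, covariate model, and individual-parameter realization.

The structural model is the linear two-compartment model with first-order
elimination from the central compartment and zero-order (infusion) input:

    dA1/dt = rate_in(t) - (CL/V1 + Q/V1) A1 + (Q/V2) A2
    dA2/dt = (Q/V1) A1 - (Q/V2) A2,        C(t) = A1 / V1

Typical parameters are modified multiplicatively by covariate effects
(allometric weight scaling with fixed exponents 0.75 on clearances and 1 on
volumes; power models on continuous covariates such as creatinine clearance;
multiplicative factors for categorical covariates), and individual parameters
are realized as typical * exp(eta + IOV term), with the intra-operative
occasion as the zero-reference for inter-occasion variability.

Units: time h, amount mg, volume L, concentration mg/L, clearance L/h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernels

OCCASIONS = ("intra", "pre", "post")
OCC_CODE = {"intra": 0, "pre": 1, "post": 2}
PARAM_NAMES = ("cl", "v1", "q", "v2")

#: reference body weight (kg) for allometric scaling
WT_REF = 70.0
#: reference creatinine clearance (mL/min/1.73 m^2) for the renal-function effect
CRCL_REF = 120.0

BEDSIDE_SCHWARTZ_K = 0.413


class ConfigurationError(ValueError):
    """A model specification is internally inconsistent."""


@dataclass(frozen=True)
class StructuralParams:
    """PK parameters of one (typical or individual) two-compartment model.

    cl/q in L/h, v1/v2 in L.  Typical values are referenced to a 70-kg subject.
    """

    cl: float
    v1: float
    q: float
    v2: float

    def __post_init__(self):
        for name in PARAM_NAMES:
            if not getattr(self, name) > 0:
                raise ValueError(f"structural parameter {name!r} must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.cl, self.v1, self.q, self.v2])


@dataclass(frozen=True)
class CovariateEffect:
    """One multiplicative covariate effect on a PK parameter.

    kind:
      * ``power-continuous``      -> (cov / center) ** exponent_or_factor
      * ``multiplicative-categorical`` -> exponent_or_factor ** indicator(cov)
      * ``allometric-fixed``      -> (weight / 70) ** exponent_or_factor,
        with the exponent fixed at 0.75 (clearances) or 1 (volumes).
    """

    parameter: str
    covariate: str
    kind: str
    exponent_or_factor: float
    center: float = 1.0
    fixed: bool = False  # allometric effects are always fixed; others estimable

    def __post_init__(self):
        if self.kind == "allometric-fixed":
            object.__setattr__(self, "fixed", True)
        if self.parameter not in PARAM_NAMES:
            raise ConfigurationError(f"unknown parameter {self.parameter!r}")
        if self.kind not in ("power-continuous", "multiplicative-categorical",
                             "allometric-fixed"):
            raise ConfigurationError(f"unknown effect kind {self.kind!r}")
        if self.kind in ("power-continuous", "allometric-fixed") and not self.center > 0:
            raise ConfigurationError("center must be > 0 for continuous effects")
        if self.kind == "allometric-fixed" and self.exponent_or_factor not in (0.75, 1.0):
            raise ConfigurationError("allometric exponents are fixed at 0.75 or 1")


def allometric_effects() -> list[CovariateEffect]:
    """The standard fixed allometric scaling set: 0.75 on CL and Q, 1 on V1 and V2."""
    return [
        CovariateEffect("cl", "weight", "allometric-fixed", 0.75, WT_REF),
        CovariateEffect("q", "weight", "allometric-fixed", 0.75, WT_REF),
        CovariateEffect("v1", "weight", "allometric-fixed", 1.0, WT_REF),
        CovariateEffect("v2", "weight", "allometric-fixed", 1.0, WT_REF),
    ]


@dataclass(frozen=True)
class RandomEffectSpec:
    """Variances of the log-normal random effects and the residual model.

    omega2: IIV variances keyed by parameter (CL and V1 only; Q and V2 carry
    no IIV).  pi2: IOV variances keyed by occasion category ('pre', 'post');
    the intra-operative occasion is the IOV reference and is identically 0.
    sigma2_prop: proportional residual variance.
    """

    omega2: dict = field(default_factory=dict)
    pi2: dict = field(default_factory=dict)
    sigma2_prop: float = 0.0

    def __post_init__(self):
        for p, v in self.omega2.items():
            if p not in ("cl", "v1"):
                raise ConfigurationError(
                    f"IIV supported on cl and v1 only (got {p!r}); Q and V2 variability is fixed at 0")
            if v < 0:
                raise ConfigurationError("variances must be >= 0")
        for occ, v in self.pi2.items():
            if occ == "intra" and v != 0:
                raise ConfigurationError("intra-operative IOV is the zero reference")
            if occ not in OCCASIONS:
                raise ConfigurationError(f"unknown occasion {occ!r}")
            if v < 0:
                raise ConfigurationError("variances must be >= 0")
        if self.sigma2_prop < 0:
            raise ConfigurationError("sigma2_prop must be >= 0")

    def omega2_vector(self) -> np.ndarray:
        """Variances in kernel component order (iiv_cl, iiv_v1, iov_pre, iov_post)."""
        return np.array([
            self.omega2.get("cl", 0.0), self.omega2.get("v1", 0.0),
            self.pi2.get("pre", 0.0), self.pi2.get("post", 0.0)])


@dataclass(frozen=True)
class ModelSpec:
    """Full definition of a population PK model: fixed effects + random effects."""

    theta: StructuralParams
    covariate_effects: tuple = ()
    random: RandomEffectSpec = field(default_factory=RandomEffectSpec)

    def with_effect(self, effect: CovariateEffect) -> "ModelSpec":
        return replace(self, covariate_effects=self.covariate_effects + (effect,))


@dataclass(frozen=True)
class SubjectCovariates:
    weight: float
    crcl: float
    surgery_type: str = "abdominal"
    age: float | None = None
    occasion_windows: tuple = ()  # ((start, end, label), ...), half-open [start, end)

    def __post_init__(self):
        if not self.weight > 0:
            raise ValueError("weight must be > 0")
        if not self.crcl > 0:
            raise ValueError("crcl must be > 0")

    def occasion_at(self, t: float) -> str:
        for start, end, label in self.occasion_windows:
            if start <= t < end:
                return label
        return "intra"

    def value_of(self, name: str) -> float:
        if name == "weight":
            return self.weight
        if name == "crcl":
            return self.crcl
        if name == "age":
            if self.age is None:
                raise ConfigurationError("age covariate requested but not provided")
            return self.age
        if name.startswith("surgery:"):
            return 1.0 if self.surgery_type == name.split(":", 1)[1] else 0.0
        raise ConfigurationError(f"unknown covariate {name!r}")


@dataclass(frozen=True)
class DoseEvent:
    """Zero-order infusion: ``amount`` mg over ``duration`` h starting at ``start_time``."""

    start_time: float
    amount: float
    duration: float = 0.5

    def __post_init__(self):
        if not self.amount > 0:
            raise ValueError("dose amount must be > 0")
        if not self.duration > 0:
            raise ValueError("infusion duration must be > 0")

    @property
    def rate(self) -> float:
        return self.amount / self.duration


@dataclass(frozen=True)
class Observation:
    time: float
    concentration: float
    occasion: str = "intra"
    excluded: bool = False

    def __post_init__(self):
        if self.time < 0:
            raise ValueError("observation time must be >= 0")
        if self.occasion not in OCCASIONS:
            raise ValueError(f"unknown occasion {self.occasion!r}")


def typical_params(spec: ModelSpec, cov: SubjectCovariates) -> StructuralParams:
    """Typical parameters for a subject: theta_pop times the product of covariate effects."""
    mult = {p: 1.0 for p in PARAM_NAMES}
    for eff in spec.covariate_effects:
        x = cov.value_of(eff.covariate)
        if eff.kind in ("power-continuous", "allometric-fixed"):
            if not x > 0:
                raise ValueError(
                    f"covariate {eff.covariate!r} must be > 0 for a power effect (got {x})")
            mult[eff.parameter] *= (x / eff.center) ** eff.exponent_or_factor
        else:  # multiplicative-categorical: factor ** indicator
            mult[eff.parameter] *= eff.exponent_or_factor ** x
    t = spec.theta
    return StructuralParams(cl=t.cl * mult["cl"], v1=t.v1 * mult["v1"],
                            q=t.q * mult["q"], v2=t.v2 * mult["v2"])


def realize_individual(typ: StructuralParams, eta: dict | None = None,
                       iov_draw: dict | None = None,
                       occasion: str = "intra") -> StructuralParams:
    """Individual parameters: typical * exp(eta + IOV term of the occasion).

    The IOV term applies to clearance; the intra-operative occasion is the
    zero reference regardless of any draw supplied for it.
    """
    eta = eta or {}
    iov_draw = iov_draw or {}
    if occasion not in OCCASIONS:
        raise ValueError(f"unknown occasion {occasion!r}")
    for d in (eta, iov_draw):
        for v in d.values():
            if not math.isfinite(v):
                raise ValueError("random-effect draws must be finite")
    iov = 0.0 if occasion == "intra" else iov_draw.get(occasion, 0.0)
    return StructuralParams(
        cl=typ.cl * math.exp(eta.get("cl", 0.0) + iov),
        v1=typ.v1 * math.exp(eta.get("v1", 0.0)),
        q=typ.q * math.exp(eta.get("q", 0.0)),
        v2=typ.v2 * math.exp(eta.get("v2", 0.0)))


def _dose_arrays(doses) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    dt = np.array([d.start_time for d in doses], dtype=float)
    dd = np.array([d.duration for d in doses], dtype=float)
    dr = np.array([d.rate for d in doses], dtype=float)
    return dt, dd, dr


def _roots_degenerate(p: StructuralParams) -> bool:
    k10, k12, k21 = p.cl / p.v1, p.q / p.v1, p.q / p.v2
    a = k10 + k12 + k21
    disc = a * a - 4.0 * k10 * k21
    return disc < 1e-10 * a * a


def conc_profile(p: StructuralParams, doses, times) -> np.ndarray:
    """Central concentration (mg/L) at ``times`` by closed-form superposition.

    Falls back to the ODE integrator when the two disposition roots (nearly)
    coincide and the bi-exponential coefficients lose precision.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or (times.size > 1 and np.any(np.diff(times) < 0)):
        raise ValueError("times must be a sorted 1-D grid")
    if times.size and times[0] < 0:
        raise ValueError("times must be >= 0")
    if len(doses) == 0:
        return np.zeros_like(times)
    if _roots_degenerate(p):
        return conc_profile_ode(p, doses, times)
    dt, dd, dr = _dose_arrays(doses)
    return _kernels.profile(p.cl, p.v1, p.q, p.v2, dt, dd, dr, times)


def conc_profile_ode(p: StructuralParams, doses, times,
                     rtol: float = 1e-10, atol: float = 1e-12) -> np.ndarray:
    """Central concentration by direct numerical integration of the mass balance.

    Integrates segment-by-segment between input discontinuities (infusion
    starts/ends) so the piecewise-constant infusion rate never crosses a
    solver step.  Serves as the independent check on the closed form.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return np.zeros(0)
    if len(doses) == 0:
        return np.zeros_like(times)
    k10, k12, k21 = p.cl / p.v1, p.q / p.v1, p.q / p.v2

    starts = [d.start_time for d in doses]
    ends = [d.start_time + d.duration for d in doses]
    breaks = np.unique(np.concatenate([[0.0], starts, ends, [times[-1]]]))
    breaks = breaks[(breaks >= 0) & (breaks <= times[-1])]

    def rate_in(t):
        r = 0.0
        for d in doses:
            if d.start_time <= t < d.start_time + d.duration:
                r += d.rate
        return r

    def rhs(t, y, r):
        a1, a2 = y
        return (r - (k10 + k12) * a1 + k21 * a2, k12 * a1 - k21 * a2)

    out = np.zeros_like(times)
    y = np.zeros(2)
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        if hi <= lo:
            continue
        r = rate_in(0.5 * (lo + hi))
        mask = (times > lo) & (times <= hi)
        # always evaluate at `hi` so the carried state sits exactly on the breakpoint
        t_eval = np.unique(np.append(times[mask], hi))
        sol = solve_ivp(rhs, (lo, hi), y, args=(r,), method="LSODA",
                        rtol=rtol, atol=atol, t_eval=t_eval)
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"ODE integration failed on [{lo}, {hi}]: {sol.message}")
        lookup = dict(zip(sol.t, sol.y[0]))
        out[mask] = np.array([lookup[t] for t in times[mask]]) / p.v1
        y = sol.y[:, -1]
    return out


def terminal_half_life(p: StructuralParams) -> float:
    """Half-life (h) of the slow disposition phase."""
    k10, k12, k21 = p.cl / p.v1, p.q / p.v1, p.q / p.v2
    a = k10 + k12 + k21
    lam_slow = 0.5 * (a - math.sqrt(a * a - 4.0 * k10 * k21))
    return math.log(2.0) / lam_slow


def schwartz_crcl(height_cm: float, serum_creatinine: float) -> float:
    """Estimated creatinine clearance (mL/min/1.73 m^2), bedside Schwartz equation.

    CrCL = 0.413 * height / SCr with height in cm and serum creatinine in mg/dL.
    """
    if not height_cm > 0 or not serum_creatinine > 0:
        raise ValueError("height and serum creatinine must be > 0")
    return BEDSIDE_SCHWARTZ_K * height_cm / serum_creatinine
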