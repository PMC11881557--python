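"""Low-level numeric kernels for the two-compartment model and FOCE-I inner problem.

Everything here operates on flat float64/int64 arrays so the hot paths can be
jitted with numba when it is available.  The pure-Python definitions are the
reference semantics; numba only accelerates them.

Random-effect component order used throughout (ETA_* indices):
  0: inter-individual eta on CL
  1: inter-individual eta on V1
  2: inter-occasion eta on CL, pre-operative category
  3: inter-occasion eta on CL, post-operative category
Occasion codes: 0 = intra-operative (IOV reference, term 0), 1 = pre, 2 = post.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


N_ETA = 4
ETA_CL, ETA_V1, ETA_IOV_PRE, ETA_IOV_POST = 0, 1, 2, 3
OCC_INTRA, OCC_PRE, OCC_POST = 0, 1, 2


@njit(cache=True, error_model="numpy")
def conc_at(cl, v1, q, v2, dose_t, dose_dur, dose_rate, t):
    """Central concentration at time ``t`` by superposition of zero-order infusions.

    Bi-exponential disposition with hybrid rate constants lam1/lam2 derived from
    (CL, V1, Q, V2).  Valid only away from the degenerate equal-root case, which
    callers detect and route to the ODE path.
    """
    k10 = cl / v1
    k12 = q / v1
    k21 = q / v2
    a = k10 + k12 + k21
    disc = a * a - 4.0 * k10 * k21
    if disc < 0.0:
        disc = 0.0
    root = math.sqrt(disc)
    lam1 = 0.5 * (a + root)
    lam2 = 0.5 * (a - root)
    # bolus unit-response coefficients: C(t) = (1/V1)(A1 e^-lam1 t + A2 e^-lam2 t)
    c1 = (k21 - lam1) / (lam2 - lam1)
    c2 = (k21 - lam2) / (lam1 - lam2)
    total = 0.0
    for i in range(dose_t.shape[0]):
        tau = t - dose_t[i]
        if tau <= 0.0:
            continue
        dur = dose_dur[i]
        te = tau if tau < dur else dur
        tp = tau - dur if tau > dur else 0.0
        total += (dose_rate[i] / v1) * (
            c1 / lam1 * (1.0 - math.exp(-lam1 * te)) * math.exp(-lam1 * tp)
            + c2 / lam2 * (1.0 - math.exp(-lam2 * te)) * math.exp(-lam2 * tp)
        )
    return total


@njit(cache=True, error_model="numpy")
def profile(cl, v1, q, v2, dose_t, dose_dur, dose_rate, times):
    out = np.empty(times.shape[0])
    for j in range(times.shape[0]):
        out[j] = conc_at(cl, v1, q, v2, dose_t, dose_dur, dose_rate, times[j])
    return out


@njit(cache=True, error_model="numpy")
def _predict(typ4, eta, dose_t, dose_dur, dose_rate, obs_t, obs_occ):
    """Model prediction for every observation of one subject.

    CL carries the IIV eta plus the IOV eta of the observation's occasion
    category (intra-operative is the zero reference); V1 carries its IIV eta.
    Parameters are constant over the whole dosing history for a given
    observation — realized at that observation's occasion.
    """
    n = obs_t.shape[0]
    f = np.empty(n)
    v1 = typ4[1] * math.exp(eta[ETA_V1])
    for j in range(n):
        iov = 0.0
        if obs_occ[j] == OCC_PRE:
            iov = eta[ETA_IOV_PRE]
        elif obs_occ[j] == OCC_POST:
            iov = eta[ETA_IOV_POST]
        cl = typ4[0] * math.exp(eta[ETA_CL] + iov)
        f[j] = conc_at(cl, v1, typ4[2], typ4[3], dose_t, dose_dur, dose_rate, obs_t[j])
    return f


@njit(cache=True, error_model="numpy")
def _h2(typ4, eta, om2, active, sigma2, dose_t, dose_dur, dose_rate,
        obs_t, obs_y, obs_occ, floor):
    """Twice the negative log joint density, without 2*pi constants."""
    f = _predict(typ4, eta, dose_t, dose_dur, dose_rate, obs_t, obs_occ)
    s = 0.0
    for j in range(f.shape[0]):
        ff = f[j] if f[j] > floor else floor
        v = sigma2 * ff * ff
        r = obs_y[j] - f[j]
        s += r * r / v + math.log(v)
    for k in range(N_ETA):
        if active[k]:
            s += eta[k] * eta[k] / om2[k]
    return s


@njit(cache=True, error_model="numpy")
def foce_subject(typ4, om2, active, sigma2, dose_t, dose_dur, dose_rate,
                 obs_t, obs_y, obs_occ, floor, inner_tol, max_iter):
    """FOCE-I contribution of one subject and its eta mode.

    Minimizes the penalized conditional objective over the active etas by
    damped Gauss-Newton (cold start at 0), then evaluates the Laplacian
    approximation with the Gauss-Newton Hessian and interaction (residual
    variance at conditional predictions):

        OFV_i = sum_j [(y-f)^2/v + ln(2 pi v)] + eta' Om^-1 eta
                + ln|Om| + ln|G' V^-1 G + Om^-1|
    """
    n_obs = obs_t.shape[0]
    idx = np.empty(N_ETA, dtype=np.int64)
    d = 0
    for k in range(N_ETA):
        if active[k]:
            idx[d] = k
            d += 1
    eta = np.zeros(N_ETA)
    if d > 0 and n_obs > 0:
        h = _h2(typ4, eta, om2, active, sigma2, dose_t, dose_dur, dose_rate,
                obs_t, obs_y, obs_occ, floor)
        lam = 1e-3
        fd = 1e-5
        for _ in range(max_iter):
            f0 = _predict(typ4, eta, dose_t, dose_dur, dose_rate, obs_t, obs_occ)
            G = np.empty((n_obs, d))
            for kk in range(d):
                eta[idx[kk]] += fd
                fp = _predict(typ4, eta, dose_t, dose_dur, dose_rate, obs_t, obs_occ)
                eta[idx[kk]] -= fd
                for j in range(n_obs):
                    G[j, kk] = (fp[j] - f0[j]) / fd
            grad = np.zeros(d)
            H = np.zeros((d, d))
            for j in range(n_obs):
                ff = f0[j] if f0[j] > floor else floor
                v = sigma2 * ff * ff
                r = obs_y[j] - f0[j]
                # d/deta of (r^2/v + ln v) with v = sigma2 f^2 (interaction)
                coef = -2.0 * r / v - 2.0 * r * r / (v * ff) + 2.0 / ff
                for kk in range(d):
                    grad[kk] += coef * G[j, kk]
                    for ll in range(d):
                        H[kk, ll] += 2.0 * G[j, kk] * G[j, ll] / v
            for kk in range(d):
                grad[kk] += 2.0 * eta[idx[kk]] / om2[idx[kk]]
                H[kk, kk] += 2.0 / om2[idx[kk]]
            # damped Newton step with step-halving acceptance
            improved = False
            for _trial in range(12):
                Hd = H.copy()
                for kk in range(d):
                    Hd[kk, kk] += lam
                step = np.linalg.solve(Hd, -grad)
                eta_new = eta.copy()
                for kk in range(d):
                    eta_new[idx[kk]] += step[kk]
                h_new = _h2(typ4, eta_new, om2, active, sigma2, dose_t, dose_dur,
                            dose_rate, obs_t, obs_y, obs_occ, floor)
                if h_new <= h:
                    improved = h - h_new > inner_tol
                    eta = eta_new
                    h = h_new
                    lam = max(lam * 0.3, 1e-8)
                    break
                lam *= 10.0
            if not improved:
                break
    # assemble OFV at the mode
    f0 = _predict(typ4, eta, dose_t, dose_dur, dose_rate, obs_t, obs_occ)
    ofv = 0.0
    for j in range(n_obs):
        ff = f0[j] if f0[j] > floor else floor
        v = sigma2 * ff * ff
        r = obs_y[j] - f0[j]
        ofv += r * r / v + math.log(2.0 * math.pi * v)
    if d > 0:
        fd = 1e-5
        G = np.empty((n_obs, d))
        for kk in range(d):
            eta[idx[kk]] += fd
            fp = _predict(typ4, eta, dose_t, dose_dur, dose_rate, obs_t, obs_occ)
            eta[idx[kk]] -= fd
            for j in range(n_obs):
                G[j, kk] = (fp[j] - f0[j]) / fd
        H = np.zeros((d, d))
        for j in range(n_obs):
            ff = f0[j] if f0[j] > floor else floor
            v = sigma2 * ff * ff
            for kk in range(d):
                for ll in range(d):
                    H[kk, ll] += G[j, kk] * G[j, ll] / v
        for kk in range(d):
            k = idx[kk]
            ofv += eta[k] * eta[k] / om2[k] + math.log(om2[k])
            H[kk, kk] += 1.0 / om2[k]
        # ln det via Cholesky (H is positive definite)
        L = np.linalg.cholesky(H)
        for kk in range(d):
            ofv += 2.0 * math.log(L[kk, kk])
    return ofv, eta


@njit(cache=True, error_model="numpy")
def ofv_dataset(typ_all, om2, sigma2, dose_off, dose_t, dose_dur, dose_rate,
                obs_off, obs_t, obs_y, obs_occ, iov_active, floor,
                inner_tol, max_iter):
    """Total FOCE-I OFV over subjects plus per-subject eta modes.

    ``iov_active[i, k]`` marks which random-effect components exist for
    subject i (IOV components only where the subject has observations in
    that occasion category and the category variance is positive).
    """
    n_sub = typ_all.shape[0]
    total = 0.0
    etas = np.zeros((n_sub, N_ETA))
    for i in range(n_sub):
        d0, d1 = dose_off[i], dose_off[i + 1]
        o0, o1 = obs_off[i], obs_off[i + 1]
        ofv_i, eta = foce_subject(
            typ_all[i], om2, iov_active[i], sigma2,
            dose_t[d0:d1], dose_dur[d0:d1], dose_rate[d0:d1],
            obs_t[o0:o1], obs_y[o0:o1], obs_occ[o0:o1],
            floor, inner_tol, max_iter)
        total += ofv_i
        for k in range(N_ETA):
            etas[i, k] = eta[k]
    return total, etas
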