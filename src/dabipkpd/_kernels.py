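"""Numba kernels: closed-form trajectories and the FOCEI per-subject objective.

The two-compartment disposition with zero-order inputs is evaluated by
superposition of unit-rate infusion step responses (bi-exponential), the
effect site by exact convolution of those exponentials with the first-order
keo link, and the reversal compartment by mono-exponential input/decay.
Everything here is written against flat arrays so it can be jit-compiled and
called thousands of times inside the mixed-effects inner/outer loops.

Parameter vector layout (subject-scale typical values, BSV applied on top):
    0 CL    1 Q     2 V1    3 V2    4 t_half_keo
    5 E0    6 Emax  7 Ce50  8 hill
    9 k_ida 10 dur_ida 11 slope_ida
Event rows: (start time, amount mg, duration min, drug flag 0=dabigatran
1=idarucizumab).
"""

from __future__ import annotations

import numpy as np
from numba import njit

LOG2PI = float(np.log(2.0 * np.pi))
LN2 = float(np.log(2.0))

#: minimum zero-order input duration (min); a "bolus" is a very short infusion
MIN_DURATION = 1e-3


@njit(cache=True)
def _disposition_constants(CL, Q, V1, V2):
    k10 = CL / V1
    k12 = Q / V1
    k21 = Q / V2
    s = k10 + k12 + k21
    p = k10 * k21
    disc = s * s - 4.0 * p
    floor = 1e-24 * s * s + 1e-300
    if disc < floor:
        disc = floor
    rt = np.sqrt(disc)
    al = 0.5 * (s + rt)
    be = 0.5 * (s - rt)
    if be < 1e-12:
        be = 1e-12
    ca = (al - k21) / (al - be)
    cb = (k21 - be) / (al - be)
    return k12, al, be, ca, cb


@njit(cache=True)
def _ce_step_term(lam, keo, tau):
    # effect-site response to a unit step of the (1 - e^{-lam t}) kind
    return 1.0 - (keo * np.exp(-lam * tau) - lam * np.exp(-keo * tau)) / (keo - lam)


@njit(cache=True)
def profiles(times, events, CL, Q, V1, V2, keo, k_ida, dur_ida):
    """Closed-form C1, C2 (mg/L), Ce (mg/L) and reversal amount at `times`."""
    nt = times.size
    C1 = np.zeros(nt)
    A2 = np.zeros(nt)
    Ce = np.zeros(nt)
    Aida = np.zeros(nt)
    k12, al, be, ca, cb = _disposition_constants(CL, Q, V1, V2)
    # avoid exact keo/eigenvalue coincidence (removable singularity)
    if abs(keo - al) <= 1e-6 * (keo + al):
        keo = keo * 1.0000025 + 1e-12
    if abs(keo - be) <= 1e-6 * (keo + be):
        keo = keo * 1.0000025 + 1e-12
    for i in range(events.shape[0]):
        ts = events[i, 0]
        amt = events[i, 1]
        dur = events[i, 2]
        drug = events[i, 3]
        if drug < 0.5:
            if amt <= 0.0:
                continue
            d = dur if dur > MIN_DURATION else MIN_DURATION
            r = amt / d
            for j in range(nt):
                tau = times[j] - ts
                if tau <= 0.0:
                    continue
                ea = -np.expm1(-al * tau)
                eb = -np.expm1(-be * tau)
                c1 = (ca * ea / al + cb * eb / be) / V1
                a2 = k12 / (al - be) * (eb / be - ea / al)
                ce = (ca / al * _ce_step_term(al, keo, tau)
                      + cb / be * _ce_step_term(be, keo, tau)) / V1
                if tau > d:
                    t2 = tau - d
                    ea2 = -np.expm1(-al * t2)
                    eb2 = -np.expm1(-be * t2)
                    c1 -= (ca * ea2 / al + cb * eb2 / be) / V1
                    a2 -= k12 / (al - be) * (eb2 / be - ea2 / al)
                    ce -= (ca / al * _ce_step_term(al, keo, t2)
                           + cb / be * _ce_step_term(be, keo, t2)) / V1
                C1[j] += r * c1
                A2[j] += r * a2
                Ce[j] += r * ce
        else:
            # unit-normalised input over dur_ida regardless of the mg amount
            d = dur_ida if dur_ida > MIN_DURATION else MIN_DURATION
            r = 1.0 / d
            for j in range(nt):
                tau = times[j] - ts
                if tau <= 0.0:
                    continue
                aa = -np.expm1(-k_ida * tau) / k_ida
                if tau > d:
                    aa -= -np.expm1(-k_ida * (tau - d)) / k_ida
                Aida[j] += r * aa
    return C1, A2, Ce, Aida


@njit(cache=True)
def predict_obs(times, ch, events, p):
    """Model prediction per observation row (channel 1: C1; channel 2: R)."""
    keo = LN2 / p[4]
    C1, A2, Ce, Aida = profiles(times, events, p[0], p[1], p[2], p[3],
                                keo, p[9], p[10])
    f = np.empty(times.size)
    for j in range(times.size):
        if ch[j] == 1:
            f[j] = C1[j]
        else:
            ce = Ce[j]
            if ce <= 0.0:
                frac = 0.0
            elif p[8] == 1.0:
                frac = ce / (p[7] + ce)
            else:
                cn = ce ** p[8]
                frac = cn / (p[7] ** p[8] + cn)
            r = p[5] + p[6] * frac - p[11] * Aida[j]
            f[j] = r if r > 0.0 else 0.0
    return f


@njit(cache=True)
def _apply_eta(p_typ, eta_idx, eta):
    p = p_typ.copy()
    for k in range(eta_idx.size):
        e = eta[k]
        # clamp so an extreme trial step cannot underflow a parameter to
        # zero (or overflow to inf) before the step is rejected
        if e > 40.0:
            e = 40.0
        elif e < -40.0:
            e = -40.0
        p[eta_idx[k]] *= np.exp(e)
    return p


@njit(cache=True)
def _residual_sd_components(ch, sig):
    # per-row proportional and additive sigma
    n = ch.size
    sp = np.empty(n)
    sa = np.empty(n)
    for j in range(n):
        if ch[j] == 1:
            sp[j] = sig[0]
            sa[j] = sig[1]
        else:
            sp[j] = sig[2]
            sa[j] = sig[3]
    return sp, sa


@njit(cache=True)
def naive_neg2ll(times, y, ch, events, p, sig):
    """-2 log-likelihood with no random effects (naive pooled kernel)."""
    f = predict_obs(times, ch, events, p)
    sp, sa = _residual_sd_components(ch, sig)
    total = 0.0
    for j in range(y.size):
        v = (f[j] * sp[j]) ** 2 + sa[j] ** 2
        if v < 1e-300:
            v = 1e-300
        r = y[j] - f[j]
        total += LOG2PI + np.log(v) + r * r / v
    return total


@njit(cache=True)
def _joint_neg2pen(times, y, ch, events, p_typ, eta_idx, omega, sig, eta):
    """l(eta) + eta' Omega^-1 eta with l = sum[log v + res^2/v] (no 2pi)."""
    p = _apply_eta(p_typ, eta_idx, eta)
    f = predict_obs(times, ch, events, p)
    sp, sa = _residual_sd_components(ch, sig)
    total = 0.0
    for j in range(y.size):
        v = (f[j] * sp[j]) ** 2 + sa[j] ** 2
        if v < 1e-300:
            v = 1e-300
        r = y[j] - f[j]
        total += np.log(v) + r * r / v
    for k in range(eta.size):
        total += eta[k] * eta[k] / omega[k]
    return total


@njit(cache=True)
def foce_subject(times, y, ch, events, p_typ, eta_idx, omega, sig):
    """FOCE-with-interaction contribution of one subject.

    Inner Newton (Fisher-scoring with Levenberg damping) finds the empirical
    Bayes eta; the marginal -2ll uses the Laplace expression with the Fisher
    (Gauss-Newton + interaction) Hessian of the joint objective.

    Returns (objective_i, eta_hat, converged_flag).
    """
    n = times.size
    q = eta_idx.size
    h = 1e-4
    eta = np.zeros(q)
    g0 = _joint_neg2pen(times, y, ch, events, p_typ, eta_idx, omega, sig, eta)
    lam = 0.0
    converged = False
    J = np.empty((n, q))
    grad = np.empty(q)
    M = np.empty((q, q))
    for _ in range(60):
        p = _apply_eta(p_typ, eta_idx, eta)
        f0 = predict_obs(times, ch, events, p)
        for k in range(q):
            e2 = eta.copy()
            e2[k] += h
            p2 = _apply_eta(p_typ, eta_idx, e2)
            f2 = predict_obs(times, ch, events, p2)
            for j in range(n):
                J[j, k] = (f2[j] - f0[j]) / h
        sp, sa = _residual_sd_components(ch, sig)
        for k in range(q):
            grad[k] = 2.0 * eta[k] / omega[k]
        for a in range(q):
            for b in range(q):
                M[a, b] = 0.0
        for k in range(q):
            M[k, k] = 1.0 / omega[k]
        for j in range(n):
            v = (f0[j] * sp[j]) ** 2 + sa[j] ** 2
            if v < 1e-300:
                v = 1e-300
            res = y[j] - f0[j]
            dvf = 2.0 * f0[j] * sp[j] * sp[j]  # dv/df
            for k in range(q):
                gjk = J[j, k]
                dv = dvf * gjk
                grad[k] += dv / v - 2.0 * res * gjk / v - res * res * dv / (v * v)
            for a in range(q):
                for b in range(q):
                    M[a, b] += (J[j, a] * J[j, b] / v
                                + (dvf * J[j, a]) * (dvf * J[j, b]) / (2.0 * v * v))
        # damped Newton step on G, Hessian approx = 2 M
        accepted = False
        improvement = 0.0
        for _try in range(12):
            H = 2.0 * M.copy()
            if lam > 0.0:
                for k in range(q):
                    H[k, k] += lam
            step = np.linalg.solve(H, grad)
            trial = eta - step
            g1 = _joint_neg2pen(times, y, ch, events, p_typ, eta_idx, omega,
                                sig, trial)
            if g1 <= g0 + 1e-10:
                improvement = g0 - g1
                eta = trial
                g0 = g1
                lam = lam * 0.25
                if lam < 1e-10:
                    lam = 0.0
                accepted = True
                break
            lam = lam * 10.0 if lam > 0.0 else 1e-4
        if not accepted:
            break
        maxstep = 0.0
        for k in range(q):
            if abs(step[k]) > maxstep:
                maxstep = abs(step[k])
        # forward-difference Jacobians limit attainable step accuracy, so
        # stop on either a tiny step or a stalled objective
        if maxstep < 1e-7 or improvement < 1e-9:
            converged = True
            break
    # final curvature at eta_hat
    p = _apply_eta(p_typ, eta_idx, eta)
    f0 = predict_obs(times, ch, events, p)
    for k in range(q):
        e2 = eta.copy()
        e2[k] += h
        p2 = _apply_eta(p_typ, eta_idx, e2)
        f2 = predict_obs(times, ch, events, p2)
        for j in range(n):
            J[j, k] = (f2[j] - f0[j]) / h
    sp, sa = _residual_sd_components(ch, sig)
    for a in range(q):
        for b in range(q):
            M[a, b] = 0.0
    for k in range(q):
        M[k, k] = 1.0 / omega[k]
    for j in range(n):
        v = (f0[j] * sp[j]) ** 2 + sa[j] ** 2
        if v < 1e-300:
            v = 1e-300
        dvf = 2.0 * f0[j] * sp[j] * sp[j]
        for a in range(q):
            for b in range(q):
                M[a, b] += (J[j, a] * J[j, b] / v
                            + (dvf * J[j, a]) * (dvf * J[j, b]) / (2.0 * v * v))
    L = np.linalg.cholesky(M)
    logdet = 0.0
    for k in range(q):
        logdet += 2.0 * np.log(L[k, k])
    logom = 0.0
    for k in range(q):
        logom += np.log(omega[k])
    obj = n * LOG2PI + logom + g0 + logdet
    return obj, eta, converged
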