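"""Compiled inner loops shared by the simulation and Lyapunov modules.

All kernels work on a packed parameter vector
``p = (alpha13, alpha23, alpha31, alpha32, beta, gamma, x1T, x3T, delta)``
and advance the six neural states with classical fixed-step RK4; the stimulus
phase is advanced analytically (``theta = theta0 + pi * eta * kappa``), which
keeps the tangent space six-dimensional.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_PI = np.pi


@njit(cache=True, fastmath=True, inline="always")
def _deriv(s, th, zeta, eta, p):
    a13, a23, a31, a32, beta, gamma, x1T, x3T, delta = (
        p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8])
    c = np.cos(th)
    x2T = zeta * np.exp(-2.0 * delta * c * c)
    O3 = 1.0 / (1.0 + gamma * np.exp(-(s[1] + s[2] + x3T)))
    O1 = 1.0 / (1.0 + gamma * np.exp(-(a13 * s[0] + x1T)))
    O2 = 1.0 / (1.0 + gamma * np.exp(-(a23 * s[0] + x2T)))
    d = np.empty(6)
    d[0] = s[3]
    d[1] = s[4]
    d[2] = s[5]
    d[3] = O3 - 2.0 * s[3] - s[0]
    d[4] = a31 * O1 - 2.0 * s[4] - s[1]
    d[5] = a32 * O2 - 2.0 * beta * s[5] - beta * beta * s[2]
    return d


@njit(cache=True, fastmath=True, inline="always")
def _jac(s, th, zeta, eta, p):
    a13, a23, a31, a32, beta, gamma, x1T, x3T, delta = (
        p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8])
    c = np.cos(th)
    x2T = zeta * np.exp(-2.0 * delta * c * c)
    O3 = 1.0 / (1.0 + gamma * np.exp(-(s[1] + s[2] + x3T)))
    O1 = 1.0 / (1.0 + gamma * np.exp(-(a13 * s[0] + x1T)))
    O2 = 1.0 / (1.0 + gamma * np.exp(-(a23 * s[0] + x2T)))
    dO3 = O3 * (1.0 - O3)
    dO1 = O1 * (1.0 - O1)
    dO2 = O2 * (1.0 - O2)
    J = np.zeros((6, 6))
    J[0, 3] = 1.0
    J[1, 4] = 1.0
    J[2, 5] = 1.0
    J[3, 0] = -1.0
    J[3, 1] = dO3
    J[3, 2] = dO3
    J[3, 3] = -2.0
    J[4, 0] = a31 * a13 * dO1
    J[4, 1] = -1.0
    J[4, 4] = -2.0
    J[5, 0] = a32 * a23 * dO2
    J[5, 2] = -beta * beta
    J[5, 5] = -2.0 * beta
    return J


@njit(cache=True, fastmath=True, inline="always")
def _rk4_step(s, th, dt, zeta, eta, p):
    dth = 0.5 * dt * _PI * eta
    k1 = _deriv(s, th, zeta, eta, p)
    k2 = _deriv(s + 0.5 * dt * k1, th + dth, zeta, eta, p)
    k3 = _deriv(s + 0.5 * dt * k2, th + dth, zeta, eta, p)
    k4 = _deriv(s + dt * k3, th + 2.0 * dth, zeta, eta, p)
    return s + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


@njit(cache=True, fastmath=True)
def integrate_fixed(s0, theta0, zeta, eta, p, span, dt, transient, samp_every):
    """Advance the forced system and return uniformly resampled states.

    Output rows are ``(x03, x31, x32, y30, y31, y32, theta)`` sampled every
    ``samp_every`` steps after discarding ``transient`` of normalized time.
    Returns an empty array on blow-up; the caller checks finiteness.
    """
    s = s0.copy()
    th = theta0
    n_tr = int(np.ceil(transient / dt))
    for _ in range(n_tr):
        s = _rk4_step(s, th, dt, zeta, eta, p)
        th += dt * _PI * eta
    n = int(np.ceil(span / dt))
    n_out = n // samp_every
    out = np.empty((n_out, 7))
    j = 0
    for i in range(n):
        s = _rk4_step(s, th, dt, zeta, eta, p)
        th += dt * _PI * eta
        if (i + 1) % samp_every == 0 and j < n_out:
            out[j, :6] = s
            out[j, 6] = th
            j += 1
        if not np.isfinite(s[0]):
            return out[:j]
    return out[:j]


@njit(cache=True, fastmath=True, inline="always")
def _deriv_w(s, th, zeta, eta, p, w):
    """Same vector field as :func:`_deriv` with noise ``w`` on the pulse."""
    a13, a23, a31, a32, beta, gamma, x1T, x3T, delta = (
        p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8])
    c = np.cos(th)
    x2T = zeta * np.exp(-2.0 * delta * c * c) + w
    O3 = 1.0 / (1.0 + gamma * np.exp(-(s[1] + s[2] + x3T)))
    O1 = 1.0 / (1.0 + gamma * np.exp(-(a13 * s[0] + x1T)))
    O2 = 1.0 / (1.0 + gamma * np.exp(-(a23 * s[0] + x2T)))
    d = np.empty(6)
    d[0] = s[3]
    d[1] = s[4]
    d[2] = s[5]
    d[3] = O3 - 2.0 * s[3] - s[0]
    d[4] = a31 * O1 - 2.0 * s[4] - s[1]
    d[5] = a32 * O2 - 2.0 * beta * s[5] - beta * beta * s[2]
    return d


@njit(cache=True, fastmath=True, inline="always")
def _rk4_step_w(s, th, dt, zeta, eta, p, w):
    dth = 0.5 * dt * _PI * eta
    k1 = _deriv_w(s, th, zeta, eta, p, w)
    k2 = _deriv_w(s + 0.5 * dt * k1, th + dth, zeta, eta, p, w)
    k3 = _deriv_w(s + 0.5 * dt * k2, th + dth, zeta, eta, p, w)
    k4 = _deriv_w(s + dt * k3, th + 2.0 * dth, zeta, eta, p, w)
    return s + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


@njit(cache=True, fastmath=True)
def integrate_noisy_stimulus(s0, theta0, zeta, eta, p, span, dt, transient,
                             samp_every, noise, noise_every):
    """Like :func:`integrate_fixed` but with additive stimulus noise.

    ``noise`` is a pre-drawn Gaussian stream (units of the stimulus) held
    piecewise constant for ``noise_every`` integration steps; it perturbs
    the pulse train seen by the inhibitory interneurons while the
    deterministic pulse advances through the RK4 stages exactly as in the
    noise-free path (a zero stream reproduces it bitwise).  The stream must
    cover transient plus span.
    """
    s = s0.copy()
    th = theta0
    n_tr = int(np.ceil(transient / dt))
    n = int(np.ceil(span / dt))
    n_out = n // samp_every
    out = np.empty((n_out, 7))
    j = 0
    idx = 0
    for i in range(n_tr + n):
        w = noise[min(idx, noise.shape[0] - 1)]
        if (i + 1) % noise_every == 0:
            idx += 1
        s = _rk4_step_w(s, th, dt, zeta, eta, p, w)
        th += dt * _PI * eta
        if i >= n_tr and (i - n_tr + 1) % samp_every == 0 and j < n_out:
            out[j, :6] = s
            out[j, 6] = th
            j += 1
        if not np.isfinite(s[0]):
            return out[:j]
    return out[:j]


@njit(cache=True, fastmath=True, inline="always")
def _jac_mul(s, th, zeta, p, Qin, Kout):
    """Kout = J(s, th) @ Qin with the sparse Jacobian applied row-wise."""
    a13, a23, a31, a32, beta, gamma, x1T, x3T, delta = (
        p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8])
    c = np.cos(th)
    x2T = zeta * np.exp(-2.0 * delta * c * c)
    O3 = 1.0 / (1.0 + gamma * np.exp(-(s[1] + s[2] + x3T)))
    O1 = 1.0 / (1.0 + gamma * np.exp(-(a13 * s[0] + x1T)))
    O2 = 1.0 / (1.0 + gamma * np.exp(-(a23 * s[0] + x2T)))
    dO3 = O3 * (1.0 - O3)
    dO1 = a31 * a13 * O1 * (1.0 - O1)
    dO2 = a32 * a23 * O2 * (1.0 - O2)
    b2 = beta * beta
    for j in range(6):
        q0 = Qin[0, j]
        q1 = Qin[1, j]
        q2 = Qin[2, j]
        q3 = Qin[3, j]
        q4 = Qin[4, j]
        q5 = Qin[5, j]
        Kout[0, j] = q3
        Kout[1, j] = q4
        Kout[2, j] = q5
        Kout[3, j] = -q0 + dO3 * (q1 + q2) - 2.0 * q3
        Kout[4, j] = dO1 * q0 - q1 - 2.0 * q4
        Kout[5, j] = dO2 * q0 - b2 * q2 - 2.0 * beta * q5


@njit(cache=True, fastmath=True)
def lyapunov_qr(s0, theta0, zeta, eta, p, span, dt, transient, renorm_every):
    """Full six-exponent spectrum by tangent-space RK4 + QR renormalization.

    Returns ``(exponents, half_exponents, final_state)`` where
    ``half_exponents`` are accumulated over the first half of the span only,
    so the caller can form a trailing-window drift estimate.  Exponents are
    natural-log rates per unit normalized time, ordered descending by
    construction of the Gram-Schmidt sweep.
    """
    s = s0.copy()
    th = theta0
    n_tr = int(np.ceil(transient / dt))
    for _ in range(n_tr):
        s = _rk4_step(s, th, dt, zeta, eta, p)
        th += dt * _PI * eta
    Q = np.eye(6)
    acc = np.zeros(6)
    acc_half = np.zeros(6)
    K1 = np.empty((6, 6))
    K2 = np.empty((6, 6))
    K3 = np.empty((6, 6))
    K4 = np.empty((6, 6))
    W = np.empty((6, 6))
    n = int(np.ceil(span / dt))
    n_half = n // 2
    dth = 0.5 * dt * _PI * eta
    for i in range(n):
        th2 = th + dth
        th4 = th + 2.0 * dth
        k1 = _deriv(s, th, zeta, eta, p)
        _jac_mul(s, th, zeta, p, Q, K1)
        s2 = s + 0.5 * dt * k1
        k2 = _deriv(s2, th2, zeta, eta, p)
        for a in range(6):
            for b in range(6):
                W[a, b] = Q[a, b] + 0.5 * dt * K1[a, b]
        _jac_mul(s2, th2, zeta, p, W, K2)
        s3 = s + 0.5 * dt * k2
        k3 = _deriv(s3, th2, zeta, eta, p)
        for a in range(6):
            for b in range(6):
                W[a, b] = Q[a, b] + 0.5 * dt * K2[a, b]
        _jac_mul(s3, th2, zeta, p, W, K3)
        s4 = s + dt * k3
        k4 = _deriv(s4, th4, zeta, eta, p)
        for a in range(6):
            for b in range(6):
                W[a, b] = Q[a, b] + dt * K3[a, b]
        _jac_mul(s4, th4, zeta, p, W, K4)
        s = s + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        for a in range(6):
            for b in range(6):
                Q[a, b] += (dt / 6.0) * (K1[a, b] + 2.0 * K2[a, b]
                                         + 2.0 * K3[a, b] + K4[a, b])
        th = th4
        if not np.isfinite(s[0]):
            raise FloatingPointError("trajectory diverged during Lyapunov integration")
        if (i + 1) % renorm_every == 0 or i == n - 1:
            # modified Gram-Schmidt QR; log of the diagonal accumulates
            for j in range(6):
                for k in range(j):
                    r = 0.0
                    for m in range(6):
                        r += Q[m, k] * Q[m, j]
                    for m in range(6):
                        Q[m, j] -= r * Q[m, k]
                nrm = 0.0
                for m in range(6):
                    nrm += Q[m, j] * Q[m, j]
                nrm = np.sqrt(nrm)
                acc[j] += np.log(nrm)
                if i < n_half:
                    acc_half[j] += np.log(nrm)
                for m in range(6):
                    Q[m, j] /= nrm
    out_full = acc / (n * dt)
    out_half = acc_half / (n_half * dt)
    final = np.empty(7)
    final[:6] = s
    final[6] = th
    return out_full, out_half, final


@njit(cache=True, fastmath=True)
def two_trajectory_rate(s0, theta0, zeta, eta, p, span, dt, transient,
                        d0, renorm_time):
    """Direct divergence-rate estimate from a perturbed trajectory pair.

    The companion trajectory starts ``d0`` away along the first coordinate
    and is rescaled back to distance ``d0`` every ``renorm_time`` of
    normalized time; the average log stretching rate estimates lambda1.
    """
    s = s0.copy()
    th = theta0
    n_tr = int(np.ceil(transient / dt))
    for _ in range(n_tr):
        s = _rk4_step(s, th, dt, zeta, eta, p)
        th += dt * _PI * eta
    u = s.copy()
    u[0] += d0
    acc = 0.0
    n = int(np.ceil(span / dt))
    every = max(1, int(round(renorm_time / dt)))
    for i in range(n):
        s = _rk4_step(s, th, dt, zeta, eta, p)
        u = _rk4_step(u, th, dt, zeta, eta, p)
        th += dt * _PI * eta
        if (i + 1) % every == 0:
            d = 0.0
            for m in range(6):
                d += (u[m] - s[m]) ** 2
            d = np.sqrt(d)
            if d > 0.0:
                acc += np.log(d / d0)
                for m in range(6):
                    u[m] = s[m] + (u[m] - s[m]) * (d0 / d)
    return acc / (n * dt)


@njit(cache=True, fastmath=True)
def stroboscopic_section(s0, theta0, zeta, eta, p, n_periods, dt0, transient):
    """States sampled once per stimulus period (theta advanced by pi).

    The step is snapped to divide the stimulus period exactly so samples land
    on the section without interpolation.
    """
    T = 1.0 / eta
    m = max(1, int(round(T / dt0)))
    dt = T / m
    s = s0.copy()
    th = theta0
    n_tr = int(np.ceil(transient / dt))
    for _ in range(n_tr):
        s = _rk4_step(s, th, dt, zeta, eta, p)
        th += dt * _PI * eta
    out = np.empty((n_periods, 6))
    for jj in range(n_periods):
        for _ in range(m):
            s = _rk4_step(s, th, dt, zeta, eta, p)
            th += dt * _PI * eta
        out[jj] = s
    return out


@njit(cache=True, fastmath=True)
def wolf_fixed_evolution(emb, evolve, min_scale, max_scale, exclude, dt_sec):
    """Wolf fixed-evolution-time estimate of lambda1 from embedded vectors.

    ``emb`` is the (n_vectors, dim) delay-embedded series.  A nearest
    neighbor of the fiducial point (temporally separated by more than
    ``exclude`` samples, at distance within [min_scale, max_scale]) is
    evolved alongside it for ``evolve`` samples at a time while the log
    separation growth accumulates.  The neighbor is replaced only when the
    separation leaves the admissible scale range (then the best-aligned
    admissible point is chosen), so between replacements the accumulated
    logs telescope and bounded oscillations of the embedded distance cancel
    instead of ratcheting the estimate.  Returns the exponent in nats per
    second (``dt_sec`` seconds per sample) and the number of evolution
    steps, or (NaN, 0) if no admissible neighbor is ever found.
    """
    n = emb.shape[0]
    dim = emb.shape[1]
    i = 0
    # initial neighbor: closest admissible point
    j = -1
    best = 1e300
    for k in range(n - evolve):
        if abs(k - i) <= exclude:
            continue
        d = 0.0
        for m in range(dim):
            d += (emb[i, m] - emb[k, m]) ** 2
        d = np.sqrt(d)
        if min_scale <= d <= max_scale and d < best:
            best = d
            j = k
    if j < 0:
        # no neighbor within the scale bounds: relax them and take the
        # closest temporally separated point (standard fallback when the
        # admissible shell is empty, e.g. on near-rationally sampled orbits)
        for k in range(n - evolve):
            if abs(k - i) <= exclude:
                continue
            d = 0.0
            for m in range(dim):
                d += (emb[i, m] - emb[k, m]) ** 2
            d = np.sqrt(d)
            if 0.0 < d < best:
                best = d
                j = k
        if j < 0:
            return np.nan, 0
    d_old = best
    total_log = 0.0
    n_steps = 0
    while i + evolve < n and j + evolve < n:
        i2 = i + evolve
        j2 = j + evolve
        d_new = 0.0
        for m in range(dim):
            d_new += (emb[i2, m] - emb[j2, m]) ** 2
        d_new = np.sqrt(d_new)
        if d_new > 0.0 and d_old > 0.0:
            total_log += np.log(d_new / d_old)
            n_steps += 1
        i = i2
        if d_new <= max_scale and d_new > 0.0:
            # keep evolving the same pair
            j = j2
            d_old = d_new
            continue
        # separation left the admissible range: replace with the
        # best-aligned admissible neighbor of the evolved fiducial point
        bestscore = 1e300
        cand = -1
        for k in range(n - evolve):
            if abs(k - i) <= exclude:
                continue
            d = 0.0
            for m in range(dim):
                d += (emb[i, m] - emb[k, m]) ** 2
            d = np.sqrt(d)
            if d < min_scale or d > max_scale:
                continue
            if d_new > 0.0:
                dot = 0.0
                for m in range(dim):
                    dot += (emb[k, m] - emb[i, m]) * (emb[j2, m] - emb[i, m])
                cosang = dot / (d * d_new)
                score = d * (2.0 - cosang)
            else:
                score = d
            if score < bestscore:
                bestscore = score
                cand = k
        if cand >= 0:
            j = cand
            d = 0.0
            for m in range(dim):
                d += (emb[i, m] - emb[cand, m]) ** 2
            d_old = np.sqrt(d)
        else:
            # nothing admissible: continue with the evolved pair as-is
            j = j2
            d_old = d_new
    if n_steps == 0:
        return np.nan, 0
    return total_log / (n_steps * evolve * dt_sec), n_steps
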