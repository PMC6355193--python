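"""Compiled (numba) integration kernels for the network ODE/SDE system.

The network state is three flat arrays in canonical population order:
membrane potential V (mV), NaP inactivation gate h (unused entries carried as
1.0 for plain populations) and the Ornstein-Uhlenbeck noise current (pA).
Deterministic integration uses a fixed-step classical Runge-Kutta (RK4)
scheme; stochastic integration uses fixed-step Euler-Maruyama.  Step sizes
are chosen small against the fastest membrane time constant (~0.4 ms) and a
step-halving convergence check lives in the test suite.

All kernels are verified against the pure-NumPy reference derivative in
``population_dynamics.state_derivative``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["rhs", "run_fixed"]

STATUS_OK = 0
STATUS_BLOWUP = 1


@njit(cache=True)
def rhs(
    V,
    h,
    noise,
    drive,
    is_nap,
    C,
    gL,
    EL,
    Vthr,
    Vmax,
    gNaP,
    ENa,
    mHalf,
    mSlope,
    hHalf,
    hSlope,
    tauMax,
    conn_src,
    conn_tgt,
    conn_w,
    EsynE,
    EsynI,
    gBarE,
    gBarI,
    gBarD,
    dV,
    dh,
):
    n = V.shape[0]
    f = np.empty(n)
    for i in range(n):
        x = (V[i] - Vthr[i]) / (Vmax[i] - Vthr[i])
        if x < 0.0:
            x = 0.0
        elif x > 1.0:
            x = 1.0
        f[i] = x
    exc = np.zeros(n)
    inh = np.zeros(n)
    for k in range(conn_w.shape[0]):
        w = conn_w[k]
        if w > 0.0:
            exc[conn_tgt[k]] += w * f[conn_src[k]]
        elif w < 0.0:
            inh[conn_tgt[k]] -= w * f[conn_src[k]]
    for i in range(n):
        d = drive[i]
        if d < 0.0:
            d = 0.0
        gE = gBarE * exc[i] + gBarD * d
        gI = gBarI * inh[i]
        current = (
            gL[i] * (V[i] - EL[i])
            + gE * (V[i] - EsynE)
            + gI * (V[i] - EsynI)
            + noise[i]
        )
        if is_nap[i]:
            m_inf = 1.0 / (1.0 + np.exp((V[i] - mHalf[i]) / mSlope[i]))
            current += gNaP[i] * m_inf * h[i] * (V[i] - ENa[i])
            h_inf = 1.0 / (1.0 + np.exp((V[i] - hHalf[i]) / hSlope[i]))
            tau = tauMax[i] / np.cosh((V[i] - hHalf[i]) / (2.0 * hSlope[i]))
            dh[i] = (h_inf - h[i]) / tau
        else:
            dh[i] = 0.0
        dV[i] = -current / C[i]


@njit(cache=True)
def run_fixed(
    V,
    h,
    noise,
    drive,
    is_nap,
    C,
    gL,
    EL,
    Vthr,
    Vmax,
    gNaP,
    ENa,
    mHalf,
    mSlope,
    hHalf,
    hSlope,
    tauMax,
    conn_src,
    conn_tgt,
    conn_w,
    EsynE,
    EsynI,
    gBarE,
    gBarI,
    gBarD,
    sigma,
    tauNoise,
    dt,
    n_steps,
    record_every,
    record_idx,
    out,
    stochastic,
    seed,
):
    """Integrate ``n_steps`` of size ``dt`` (ms), recording f(V) of selected populations.

    Deterministic mode advances (V, h) with RK4 while the noise current decays
    analytically (it is zero throughout in practice); stochastic mode uses
    Euler-Maruyama with one shared normal stream consumed in canonical
    population order.  Records raw V every ``record_every`` steps into
    ``out`` (row r = state after step (r+1)*record_every).
    Returns (status, step).
    """
    n = V.shape[0]
    dV1 = np.empty(n)
    dh1 = np.empty(n)
    dV2 = np.empty(n)
    dh2 = np.empty(n)
    dV3 = np.empty(n)
    dh3 = np.empty(n)
    dV4 = np.empty(n)
    dh4 = np.empty(n)
    Vt = np.empty(n)
    ht = np.empty(n)
    if stochastic:
        np.random.seed(seed)
    rec = 0
    for step in range(n_steps):
        if stochastic:
            rhs(
                V, h, noise, drive, is_nap, C, gL, EL, Vthr, Vmax, gNaP, ENa,
                mHalf, mSlope, hHalf, hSlope, tauMax, conn_src, conn_tgt,
                conn_w, EsynE, EsynI, gBarE, gBarI, gBarD, dV1, dh1,
            )
            for i in range(n):
                V[i] += dt * dV1[i]
                h[i] += dt * dh1[i]
                noise[i] += -noise[i] * dt / tauNoise[i] + sigma[i] * np.sqrt(
                    2.0 * dt / tauNoise[i]
                ) * np.random.standard_normal()
        else:
            rhs(
                V, h, noise, drive, is_nap, C, gL, EL, Vthr, Vmax, gNaP, ENa,
                mHalf, mSlope, hHalf, hSlope, tauMax, conn_src, conn_tgt,
                conn_w, EsynE, EsynI, gBarE, gBarI, gBarD, dV1, dh1,
            )
            for i in range(n):
                Vt[i] = V[i] + 0.5 * dt * dV1[i]
                ht[i] = h[i] + 0.5 * dt * dh1[i]
            rhs(
                Vt, ht, noise, drive, is_nap, C, gL, EL, Vthr, Vmax, gNaP, ENa,
                mHalf, mSlope, hHalf, hSlope, tauMax, conn_src, conn_tgt,
                conn_w, EsynE, EsynI, gBarE, gBarI, gBarD, dV2, dh2,
            )
            for i in range(n):
                Vt[i] = V[i] + 0.5 * dt * dV2[i]
                ht[i] = h[i] + 0.5 * dt * dh2[i]
            rhs(
                Vt, ht, noise, drive, is_nap, C, gL, EL, Vthr, Vmax, gNaP, ENa,
                mHalf, mSlope, hHalf, hSlope, tauMax, conn_src, conn_tgt,
                conn_w, EsynE, EsynI, gBarE, gBarI, gBarD, dV3, dh3,
            )
            for i in range(n):
                Vt[i] = V[i] + dt * dV3[i]
                ht[i] = h[i] + dt * dh3[i]
            rhs(
                Vt, ht, noise, drive, is_nap, C, gL, EL, Vthr, Vmax, gNaP, ENa,
                mHalf, mSlope, hHalf, hSlope, tauMax, conn_src, conn_tgt,
                conn_w, EsynE, EsynI, gBarE, gBarI, gBarD, dV4, dh4,
            )
            for i in range(n):
                V[i] += dt / 6.0 * (dV1[i] + 2.0 * dV2[i] + 2.0 * dV3[i] + dV4[i])
                h[i] += dt / 6.0 * (dh1[i] + 2.0 * dh2[i] + 2.0 * dh3[i] + dh4[i])
        for i in range(n):
            if not np.isfinite(V[i]) or V[i] > 200.0 or V[i] < -200.0:
                return STATUS_BLOWUP, step
        if record_every > 0 and (step + 1) % record_every == 0:
            for j in range(record_idx.shape[0]):
                out[rec, j] = V[record_idx[j]]
            rec += 1
    return STATUS_OK, n_steps
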