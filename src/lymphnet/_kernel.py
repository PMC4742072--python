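"""Numba-jitted scalar kernels for the network flow solve and ODE right-hand side.

Everything here operates in cgs units (cm, s, g, dyn/cm^2) on a packed
parameter vector ``pk`` (see layout constants below) so the hot loop — one
nonlinear scalar solve per valved segment plus one per junction, at every ODE
right-hand-side evaluation — compiles to native code.

The same constitutive relations are exposed in plain numpy in
:mod:`lymphnet.model_core`; a test pins the two to 1e-14 agreement.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# --- pk layout ----------------------------------------------------------------
MU = 0      # viscosity, g/(cm s)
LL = 1      # lymphangion length, cm
PD = 2      # tube-law pressure scale, dyn/cm^2
DD = 3      # tube-law diameter constant, cm
M0 = 4      # active tension scale, dyn/cm
FREQ = 5    # contraction frequency, Hz
TR = 6      # diastolic period, s
RVN = 7     # min valve resistance, g/(cm^4 s)
RVX = 8     # max valve resistance, g/(cm^4 s)
SF = 9      # valve failure slope, cm^2/dyn
SO = 10     # valve closing slope, cm^2/dyn
DPF = 11    # valve failure pressure, dyn/cm^2
DPO = 12    # valve closing threshold, dyn/cm^2
C1 = 13
C2 = 14
C3 = 15
C4 = 16
C5 = 17
C6 = 18
C7 = 19
C8 = 20
C10 = 21
C11 = 22
C9 = 23     # characteristic diameter, cm (derived)
SD = 24     # muscle length-factor slope, 1/cm (derived)
DA = 25     # lower muscle support diameter, cm (derived)
DB = 26     # upper muscle support diameter, cm (derived)
HALF = 27   # 1.0 -> each half-drop uses full-L Rves (literal); 0.5 -> L/2
MDLIT = 28  # 1.0 -> literal (degenerate) Md with Da in both sigmoids
NPK = 29

_EXP_CLIP = 700.0  # keeps exp() finite; only reachable far outside physiology


@njit(cache=False)
def sigmoid(x):
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    ex = np.exp(x)
    return ex / (1.0 + ex)


@njit(cache=False)
def fp(D, pk):
    """Passive tube-law pressure (dyn/cm^2) at diameter D."""
    x = D / pk[C9]
    ex = pk[C4] * (x - pk[C5])
    if ex > _EXP_CLIP:
        ex = _EXP_CLIP
    return pk[PD] * (
        pk[C1] * (x - pk[C2]) ** 2
        + pk[C3] * np.exp(ex)
        + pk[C6]
        + pk[C7] * (x - pk[C8])
        + pk[C10] / (x * x * x)
    )


@njit(cache=False)
def md(D, pk):
    """Diameter-dependent (muscle length) modulation of active tension."""
    if pk[MDLIT] != 0.0:
        # literal rendering: both sigmoids centred on Da -> identically 0
        return sigmoid(pk[SD] * (D - pk[DA])) + sigmoid(-pk[SD] * (D - pk[DA])) - 1.0
    return sigmoid(pk[SD] * (D - pk[DA])) + sigmoid(-pk[SD] * (D - pk[DB])) - 1.0


@njit(cache=False)
def mt(t, t_start, pk):
    """Normalized muscle activation in [0, 1]; period 1/f + tr, 0 in diastole."""
    Tc = 1.0 / pk[FREQ]
    T = Tc + pk[TR]
    tau = (t - t_start) % T
    if tau <= Tc:
        return 0.5 * (1.0 - np.cos(2.0 * np.pi * pk[FREQ] * tau))
    return 0.0


@njit(cache=False)
def midpressure(D, t, t_start, pe, pk):
    """Explicit lymphangion midpoint pressure p_im = pe + fp(D) + fa(D, t)."""
    m = pk[M0] * md(D, pk) * mt(t, t_start, pk)
    return pe + fp(D, pk) + 2.0 * m / D


@njit(cache=False)
def rv(dp, pk):
    """Valve resistance at trans-valve pressure dp (forward positive)."""
    return pk[RVN] + pk[RVX] * (
        sigmoid(pk[SF] * (dp - pk[DPF])) + sigmoid(-pk[SO] * (dp - pk[DPO])) - 1.0
    )


@njit(cache=False)
def rv_prime(dp, pk):
    s1 = sigmoid(pk[SF] * (dp - pk[DPF]))
    s2 = sigmoid(-pk[SO] * (dp - pk[DPO]))
    return pk[RVX] * (pk[SF] * s1 * (1.0 - s1) - pk[SO] * s2 * (1.0 - s2))


@njit(cache=False)
def rves(D, pk):
    """Half-segment Poiseuille resistance of one lymphangion."""
    return pk[HALF] * 64.0 * pk[MU] * pk[LL] / (np.pi * D ** 4)


@njit(cache=False)
def segment_solve(dpt, R, pk):
    """Flow through (series resistance R | valve) under total drop dpt.

    Solves g(dp) = dp/RV(dp) - (dpt - dp)/R = 0 for the trans-valve pressure
    dp by safeguarded Newton (bisection fallback); the root is bracketed by
    [0, dpt] since the valve and the series resistor pass the same flow.
    Returns (Q, dp).
    """
    if dpt == 0.0:
        return 0.0, 0.0
    lo = min(0.0, dpt)
    hi = max(0.0, dpt)
    x = 0.5 * (lo + hi)
    for _ in range(200):
        RVv = rv(x, pk)
        Qv = x / RVv
        Ql = (dpt - x) / R
        g = Qv - Ql
        if abs(g) <= 1e-13 * (abs(Qv) + abs(Ql)) + 1e-300:
            break
        if g > 0.0:
            hi = x
        else:
            lo = x
        gp = (RVv - x * rv_prime(x, pk)) / (RVv * RVv) + 1.0 / R
        if gp > 0.0:
            xn = x - g / gp
        else:
            xn = 0.5 * (lo + hi)
        if xn <= lo or xn >= hi:
            xn = 0.5 * (lo + hi)
        if abs(xn - x) <= 1e-14 * (1.0 + abs(dpt)):
            x = xn
            break
        x = xn
    return (dpt - x) / R, x


@njit(cache=False)
def dq_ddpt(dp, R, pk):
    """d(flow)/d(total drop) of a (R | valve) segment at its solved dp."""
    RVv = rv(dp, pk)
    a = (RVv - dp * rv_prime(dp, pk)) / (RVv * RVv)
    return a / (1.0 + a * R)


@njit(cache=False)
def junction_solve(pc1, R1, pc2, R2, ppm, Rp, pk):
    """Converging junction: two valved child branches feeding one parent half.

    Root-find on the junction node pressure pJ such that the valved child
    inflows balance the purely resistive parent outflow. Returns
    (pJ, Q1, Q2, dp1, dp2); the parent flow is Q1 + Q2 by construction.
    """
    lo = min(pc1, min(pc2, ppm))
    hi = max(pc1, max(pc2, ppm))
    if hi - lo <= 0.0:
        return ppm, 0.0, 0.0, 0.0, 0.0
    x = 0.5 * (lo + hi)
    Q1 = 0.0
    Q2 = 0.0
    dp1 = 0.0
    dp2 = 0.0
    for _ in range(200):
        Q1, dp1 = segment_solve(pc1 - x, R1, pk)
        Q2, dp2 = segment_solve(pc2 - x, R2, pk)
        Qp = (x - ppm) / Rp
        f = Q1 + Q2 - Qp
        if abs(f) <= 1e-13 * (abs(Q1) + abs(Q2) + abs(Qp)) + 1e-300:
            break
        if f > 0.0:
            lo = x
        else:
            hi = x
        fp_ = -(dq_ddpt(dp1, R1, pk) + dq_ddpt(dp2, R2, pk)) - 1.0 / Rp
        xn = x - f / fp_
        if xn <= lo or xn >= hi:
            xn = 0.5 * (lo + hi)
        if abs(xn - x) <= 1e-15 * (1.0 + abs(x)):
            x = xn
            break
        x = xn
    Q1, dp1 = segment_solve(pc1 - x, R1, pk)
    Q2, dp2 = segment_solve(pc2 - x, R2, pk)
    return x, Q1, Q2, dp1, dp2


@njit(cache=False)
def network_flows(t, D, pk, pa, pb, pe, offsets, seg_up, seg_dn,
                  jn_c1, jn_c2, jn_p):
    """Resolve every segment and junction of the network at one instant.

    seg_up/seg_dn index the lymphangion upstream/downstream of each simple
    valved segment (-1 meaning the pa / pb boundary); junctions are given by
    the global indices of their two child-last and parent-first lymphangions.

    Returns (pm, Qin, Qout, segQ, segdp, jn_pJ, jn_Q1, jn_Q2, jn_dp1, jn_dp2).
    """
    NL = D.shape[0]
    pm = np.empty(NL)
    Rh = np.empty(NL)
    for i in range(NL):
        pm[i] = midpressure(D[i], t, offsets[i], pe, pk)
        Rh[i] = rves(D[i], pk)

    Qin = np.zeros(NL)
    Qout = np.zeros(NL)
    NS = seg_up.shape[0]
    segQ = np.empty(NS)
    segdp = np.empty(NS)
    for s in range(NS):
        u = seg_up[s]
        d = seg_dn[s]
        pu = pa if u < 0 else pm[u]
        pd = pb if d < 0 else pm[d]
        R = (0.0 if u < 0 else Rh[u]) + (0.0 if d < 0 else Rh[d])
        Q, dpv = segment_solve(pu - pd, R, pk)
        segQ[s] = Q
        segdp[s] = dpv
        if u >= 0:
            Qout[u] = Q
        if d >= 0:
            Qin[d] = Q

    NJ = jn_c1.shape[0]
    jn_pJ = np.empty(NJ)
    jn_Q1 = np.empty(NJ)
    jn_Q2 = np.empty(NJ)
    jn_dp1 = np.empty(NJ)
    jn_dp2 = np.empty(NJ)
    for j in range(NJ):
        c1 = jn_c1[j]
        c2 = jn_c2[j]
        p = jn_p[j]
        pJ, Q1, Q2, dp1, dp2 = junction_solve(
            pm[c1], Rh[c1], pm[c2], Rh[c2], pm[p], Rh[p], pk
        )
        Qout[c1] = Q1
        Qout[c2] = Q2
        Qin[p] = Q1 + Q2
        jn_pJ[j] = pJ
        jn_Q1[j] = Q1
        jn_Q2[j] = Q2
        jn_dp1[j] = dp1
        jn_dp2[j] = dp2
    return pm, Qin, Qout, segQ, segdp, jn_pJ, jn_Q1, jn_Q2, jn_dp1, jn_dp2


@njit(cache=False)
def rhs(t, y, pk, pa, pb, pe, offsets, seg_up, seg_dn, jn_c1, jn_c2, jn_p,
        outlet_seg, inlet_segs):
    """ODE right-hand side: dD/dt per lymphangion + outlet/inlet volume rates.

    State vector y = [D_0..D_{NL-1}, V_out, V_in]; V_out integrates the
    outlet-valve flow and V_in the summed inlet-valve flows, giving
    error-controlled cycle averages for free.
    """
    NL = offsets.shape[0]
    D = y[:NL]
    res = network_flows(t, D, pk, pa, pb, pe, offsets, seg_up, seg_dn,
                        jn_c1, jn_c2, jn_p)
    Qin = res[1]
    Qout = res[2]
    segQ = res[3]
    dy = np.empty(NL + 2)
    for i in range(NL):
        dy[i] = 2.0 * (Qin[i] - Qout[i]) / (np.pi * D[i] * pk[LL])
    dy[NL] = segQ[outlet_seg]
    s = 0.0
    for k in inlet_segs:
        s += segQ[k]
    dy[NL + 1] = s
    return dy
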