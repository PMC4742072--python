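"""Independent brute-force oracles for the test suite.

Nothing here is imported by the simulation code paths, and the physics is
re-typed from the governing relations rather than imported from
:mod:`lymphnet.model_core` / :mod:`lymphnet._kernel`, so agreement between
the decomposed solver and these oracles is a genuine cross-check, not a
tautology. Only the topology *structure* (graph indices) is shared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import root

from .topology import ContractionSchedule, NetworkTopology

__all__ = [
    "OracleReport", "oracle_formulas", "monolithic_flow_oracle",
    "bisection_segment_oracle",
]


@dataclass(frozen=True)
class OracleReport:
    """One comparison between the primary path and an oracle."""

    instance: str
    primary: float
    oracle: float

    @property
    def discrepancy(self) -> float:
        scale = max(abs(self.primary), abs(self.oracle), 1e-300)
        return abs(self.primary - self.oracle) / scale


def oracle_formulas(pp) -> dict:
    """Literal re-typings of the printed constitutive relations.

    Takes any object exposing the constant names (a PhysicalParams works) and
    returns plain closures over python floats/math — no shared numerics.
    """
    Pd, c9 = pp.Pd, pp.Dd / pp.c11
    c = (pp.c1, pp.c2, pp.c3, pp.c4, pp.c5, pp.c6, pp.c7, pp.c8)
    c10 = pp.c10
    sd, Da, Db = 3.25 / pp.Dd, 0.85 * c9, 2.0 * c9
    RVn, RVx, sf, so = pp.RVn, pp.RVx, pp.sf, pp.so
    dpf, dpo = pp.dpf_cmH2O * 980.665, pp.dpo_dyncm2
    f, tr, M0, mu, L = pp.f, pp.tr, pp.M0, pp.mu, pp.L

    def fp(D):
        x = D / c9
        return Pd * (c[0] * (x - c[1]) ** 2 + c[2] * math.exp(min(c[3] * (x - c[4]), 700.0))
                     + c[5] + c[6] * (x - c[7]) + c10 * (c9 / D) ** 3)

    def Md(D):
        return (1.0 / (1.0 + math.exp(-sd * (D - Da)))
                + 1.0 / (1.0 + math.exp(sd * (D - Db))) - 1.0)

    def Mt(t, tc):
        T = 1.0 / f + tr
        tau = (t - tc) % T
        return (1.0 - math.cos(2.0 * math.pi * f * tau)) / 2.0 if tau <= 1.0 / f else 0.0

    def fa(D, t, tc):
        return 2.0 * M0 * Md(D) * Mt(t, tc) / D

    def RV(dp):
        def sig(x):
            if x < -700.0:
                return 0.0
            if x > 700.0:
                return 1.0
            return 1.0 / (1.0 + math.exp(-x))
        return RVn + RVx * (sig(sf * (dp - dpf)) + 1.0 / (1.0 + math.exp(min(so * (dp - dpo), 700.0))) - 1.0)

    def Rves(D):
        return 64.0 * mu * L / (math.pi * D ** 4)

    return {"fp": fp, "Md": Md, "Mt": Mt, "fa": fa, "RV": RV, "Rves": Rves}


def bisection_segment_oracle(dpt: float, R: float, pp, tol: float = 1e-14) -> float:
    """Flow through (series R | valve) by plain interval bisection on the
    trans-valve pressure; independent of the production safeguarded-Newton."""
    RV = oracle_formulas(pp)["RV"]
    if dpt == 0.0:
        return 0.0
    lo, hi = min(0.0, dpt), max(0.0, dpt)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        g = mid / RV(mid) - (dpt - mid) / R
        if g > 0.0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol * max(1.0, abs(dpt)):
            break
    dp = 0.5 * (lo + hi)
    return (dpt - dp) / R


def monolithic_flow_oracle(t: float, D: np.ndarray, topology: NetworkTopology,
                           schedule: ContractionSchedule, bc, pp,
                           tol: float = 1e-11):
    """Solve the complete simultaneous flow system by multivariate root-find.

    Unknowns: one flow per segment (simple valved segments in topology
    order, then per junction child1/child2 flows) plus one pressure per
    junction node. Residuals: the momentum drop along every segment and mass
    balance at every junction, all evaluated with the literal formula
    re-typings. Intended for small networks (<= 3 generations, nv <= 4).

    Returns (Q_simple, Q_junction_children (NJ, 2), p_junction, report) where
    ``report`` is the final residual norm.
    """
    F = oracle_formulas(pp)
    fp_, fa_, RV_, Rves_ = F["fp"], F["fa"], F["RV"], F["Rves"]
    NL = topology.n_lymphangions
    pm = np.array([bc.pe + fp_(D[i]) + fa_(D[i], t, schedule.offsets[i])
                   for i in range(NL)])
    Rh = np.array([Rves_(D[i]) for i in range(NL)])

    NS = topology.seg_up.size
    NJ = topology.jn_c1.size
    nvar = NS + 2 * NJ + NJ

    # Unknowns: trans-valve pressure per valved segment (flows follow from
    # the valve law Q = dp / RV(dp)) plus the junction node pressures. This
    # parametrization keeps every residual smooth and O(1)-scaled even where
    # valves are shut and the tube law is steep.
    seg_pu = np.array([bc.pa if u < 0 else pm[u] for u in topology.seg_up])
    seg_pd = np.array([bc.pb if d < 0 else pm[d] for d in topology.seg_dn])
    seg_R = np.array([(0.0 if u < 0 else Rh[u]) + (0.0 if d < 0 else Rh[d])
                      for u, d in zip(topology.seg_up, topology.seg_dn)])
    seg_ps = np.maximum(np.maximum(np.abs(seg_pu), np.abs(seg_pd)), 1.0)
    jc = np.stack([topology.jn_c1, topology.jn_c2], axis=1) if NJ else \
        np.zeros((0, 2), dtype=int)
    jn_ps = np.maximum(np.abs(pm[jc]).max(axis=1), 1.0) if NJ else np.ones(0)
    jn_qs = (jn_ps / Rh[topology.jn_p]) if NJ else np.ones(0)

    def unpack(x):
        dps = x[:NS] * seg_ps
        dpj = x[NS:NS + 2 * NJ].reshape(NJ, 2) * jn_ps[:, None]
        pJ = x[NS + 2 * NJ:] * jn_ps
        Q = np.array([dps[s] / RV_(dps[s]) for s in range(NS)])
        Qj = np.array([[dpj[j, k] / RV_(dpj[j, k]) for k in range(2)]
                       for j in range(NJ)]).reshape(NJ, 2)
        return dps, dpj, pJ, Q, Qj

    def residuals(x):
        dps, dpj, pJ, Q, Qj = unpack(x)
        r = np.empty(nvar)
        for s in range(NS):
            # momentum along the segment: total drop = series drop + valve drop
            r[s] = (seg_pu[s] - seg_pd[s] - seg_R[s] * Q[s] - dps[s]) / seg_ps[s]
        for j in range(NJ):
            p = topology.jn_p[j]
            for k in range(2):
                c = jc[j, k]
                r[NS + 2 * j + k] = (pm[c] - pJ[j] - Rh[c] * Qj[j, k]
                                     - dpj[j, k]) / jn_ps[j]
            # mass balance: parent inflow equals summed child flows
            r[NS + 2 * NJ + j] = (Qj[j, 0] + Qj[j, 1]
                                  - (pJ[j] - pm[p]) / Rh[p]) / jn_qs[j]
        return r

    # start from fully dropped-across-the-valve, node at parent midpoint
    x0 = np.zeros(nvar)
    x0[:NS] = (seg_pu - seg_pd) / seg_ps
    if NJ:
        x0[NS:NS + 2 * NJ] = ((pm[jc] - pm[topology.jn_p][:, None])
                              / jn_ps[:, None]).ravel()
        x0[NS + 2 * NJ:] = pm[topology.jn_p] / jn_ps
    best = None
    for guess, method in ((x0, "hybr"), (np.zeros(nvar), "hybr"), (x0, "lm")):
        sol = root(residuals, guess, method=method, tol=1e-14)
        res_norm = float(np.max(np.abs(residuals(sol.x))))
        if best is None or res_norm < best[1]:
            best = (sol.x, res_norm)
        if res_norm <= tol:
            break
    x, res_norm = best
    if res_norm > tol:
        raise RuntimeError(f"monolithic oracle did not converge "
                           f"(residual {res_norm:.2e})")
    _, _, pJ, Q, Qj = unpack(x)
    return Q, Qj, pJ, res_norm
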