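"""Network flow solve and stiff time integration to a periodic pumping state.

At any instant the midpoint pressure of every lymphangion is an explicit
function of its diameter and the muscle activation, so the algebraic flow
stage decomposes into independent scalar solves: one per valved segment
(flow through a series resistance and a pressure-dependent valve) and one
per junction (node pressure balancing two valved child inflows against the
resistive parent outflow). The diameters then evolve by conservation of
mass, dD/dt = 2 (Q_in - Q_out) / (pi D L), a stiff ODE system integrated
with BDF. Cycles are integrated one contraction period at a time until two
successive cycle-averaged outlet flows agree, after which the last cycle
mean is reported as Q-bar.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernel as _k
from .model_core import (
    PhysicalParams, cmh2o_to_dyncm2, dyncm2_to_cmh2o,
    passive_equilibrium_diameter,
)
from .topology import ContractionSchedule, NetworkTopology

__all__ = [
    "BoundaryConditions", "SolverSettings", "FlowSolution", "SimulationResult",
    "SolverError", "solve_segment_flow", "solve_junction", "network_flow_solve",
    "ode_rhs", "initial_diameters", "run_simulation", "mean_outlet_flow",
    "periodic_time_average", "CM3S_TO_MLHR",
]

#: 1 cm^3/s = 3600 ml/hr (lymph density ~ water)
CM3S_TO_MLHR = 3600.0


class SolverError(RuntimeError):
    """Raised on inner-solve or integration failure."""


@dataclass(frozen=True)
class BoundaryConditions:
    """Inlet (pa, all inlets), outlet (pb) and external (pe) pressures, dyn/cm^2."""

    pa: float
    pb: float
    pe: float

    @classmethod
    def from_cmh2o(cls, pa: float, pb: float, pe: float) -> "BoundaryConditions":
        return cls(*(float(cmh2o_to_dyncm2(p)) for p in (pa, pb, pe)))

    @property
    def dP(self) -> float:
        """Axial pressure difference pb - pa the pump must overcome, dyn/cm^2."""
        return self.pb - self.pa

    @property
    def dP_cmh2o(self) -> float:
        return float(dyncm2_to_cmh2o(self.dP))


@dataclass(frozen=True)
class SolverSettings:
    """Integration tolerances and periodic-convergence policy.

    Converged when two successive cycle-averaged outlet flows differ by less
    than ``conv_rel`` relative or ``conv_abs_ml_hr`` absolute (floor for
    near-zero flows), after at least ``min_cycles`` cycles.
    """

    rtol: float = 1e-6
    atol_diameter: float = 1e-10   # cm
    atol_volume: float = 1e-12    # cm^3
    min_cycles: int = 10
    max_cycles: int = 200
    conv_rel: float = 0.005
    conv_abs_ml_hr: float = 1e-5
    samples_per_cycle: int = 64

    def __post_init__(self):
        if min(self.rtol, self.atol_diameter, self.atol_volume) <= 0:
            raise ValueError("tolerances must be positive")
        if self.min_cycles < 2:
            raise ValueError("min_cycles must be >= 2")


@dataclass(frozen=True)
class FlowSolution:
    """Pressures and flows of the whole network at one instant.

    ``seg_Q``/``seg_dp`` follow the topology's simple-segment arrays;
    junction child flows/valve drops and node pressures are per junction.
    """

    t: float
    p_mid: np.ndarray
    Q_in: np.ndarray
    Q_out: np.ndarray
    seg_Q: np.ndarray
    seg_dp: np.ndarray
    junction_p: np.ndarray
    junction_Q: np.ndarray      # (NJ, 3): child1, child2, parent
    junction_dp: np.ndarray     # (NJ, 2)
    residual: float

    @property
    def outlet_flow(self) -> float:
        return float(self.seg_Q[-1])


@dataclass
class SimulationResult:
    """Diameter time series, per-cycle means and the converged Q-bar."""

    topology: NetworkTopology
    schedule: ContractionSchedule
    bc: BoundaryConditions
    params: PhysicalParams
    settings: SolverSettings
    times: np.ndarray
    diameters: np.ndarray              # (NL, NT)
    cycle_out_ml_hr: np.ndarray        # per-cycle mean outlet-valve flow
    cycle_in_ml_hr: np.ndarray         # per-cycle summed mean inlet flows
    converged: bool
    n_cycles: int
    final_state: np.ndarray

    @property
    def period(self) -> float:
        return self.schedule.period

    @property
    def qbar_ml_hr(self) -> float:
        """Converged time-averaged outlet-valve flow, ml/hr."""
        return float(self.cycle_out_ml_hr[-1])

    def flow_at(self, t: float, D: Optional[np.ndarray] = None) -> FlowSolution:
        if D is None:
            idx = int(np.argmin(np.abs(self.times - t)))
            t, D = self.times[idx], self.diameters[:, idx]
        return network_flow_solve(t, D, self.topology, self.schedule,
                                  self.bc, self.params)

    def outlet_flow_series(self) -> np.ndarray:
        """Outlet-valve flow (cm^3/s) recomputed at every stored sample."""
        return np.array([
            self.flow_at(self.times[k], self.diameters[:, k]).outlet_flow
            for k in range(self.times.size)
        ])

    def to_series_frame(self):
        """Tidy long-form series: time_s, entity_type, entity_id, variable, value."""
        import pandas as pd
        rows = []
        labels = [f"{l.vessel.label}.{l.position}" for l in self.topology.lymphangions]
        for k, t in enumerate(self.times):
            sol = self.flow_at(t, self.diameters[:, k])
            for i, lab in enumerate(labels):
                rows.append((t, "lymphangion", lab, "D_cm", self.diameters[i, k]))
                rows.append((t, "lymphangion", lab, "p_dyncm2", sol.p_mid[i]))
            for s in range(sol.seg_Q.size):
                rows.append((t, "segment", f"s{s}", "Q_cm3s", sol.seg_Q[s]))
            for j in range(sol.junction_p.size):
                rows.append((t, "node", f"j{j}", "p_dyncm2", sol.junction_p[j]))
        return pd.DataFrame(
            rows, columns=["time_s", "entity_type", "entity_id", "variable", "value"])

    def summary_row(self) -> dict:
        return {
            "n_generations": self.topology.n_generations,
            "nv": self.topology.nv,
            "pa_cmH2O": dyncm2_to_cmh2o(self.bc.pa),
            "pb_cmH2O": dyncm2_to_cmh2o(self.bc.pb),
            "pe_cmH2O": dyncm2_to_cmh2o(self.bc.pe),
            "dtv_s": self.schedule.dtv,
            "dtg_s": self.schedule.dtg,
            "Tc_s": self.schedule.Tc,
            "tr_s": self.schedule.tr,
            "Qbar_ml_hr": self.qbar_ml_hr,
            "converged": self.converged,
            "n_cycles": self.n_cycles,
        }


def solve_segment_flow(p_up: float, p_down: float, R_up: float, R_down: float,
                       has_valve: bool, params: PhysicalParams):
    """Flow through (R_up | valve | R_down) between two known pressures.

    Returns (Q, dp_valve). Without a valve the solve is closed-form; with a
    valve the trans-valve pressure dp = (p_up - R_up Q) - (p_down + R_down Q)
    is found by a safeguarded scalar root-find (the valve and the series
    resistances pass the same flow, which brackets dp in [0, p_up - p_down]).
    """
    if R_up < 0 or R_down < 0:
        raise ValueError("resistances must be non-negative")
    dpt = p_up - p_down
    R = R_up + R_down
    if not has_valve:
        if R == 0:
            raise ValueError("valveless segment needs positive resistance")
        return dpt / R, 0.0
    if R == 0:
        raise ValueError("valved segment needs positive series resistance")
    Q, dp = _k.segment_solve(dpt, R, params.pack())
    return float(Q), float(dp)


def solve_junction(child_mid_pressures: Sequence[float],
                   child_R: Sequence[float], parent_mid_pressure: float,
                   parent_R_half: float, params: PhysicalParams):
    """Junction node pressure and branch flows.

    Each child branch is (half-resistance | terminal valve) from its midpoint
    pressure to the node; the parent path is the purely resistive upstream
    half of the parent's first lymphangion. Returns (p_J, (Q1, Q2, Q_parent))
    with Q_parent = Q1 + Q2 exactly.
    """
    (pc1, pc2), (R1, R2) = child_mid_pressures, child_R
    pJ, Q1, Q2, _, _ = _k.junction_solve(
        pc1, R1, pc2, R2, parent_mid_pressure, parent_R_half, params.pack())
    return float(pJ), (float(Q1), float(Q2), float(Q1 + Q2))


def network_flow_solve(t: float, D: np.ndarray, topology: NetworkTopology,
                       schedule: ContractionSchedule, bc: BoundaryConditions,
                       params: PhysicalParams) -> FlowSolution:
    """Resolve all pressures and flows of the network at time t, diameters D."""
    D = np.asarray(D, dtype=float)
    if np.any(D <= 0):
        raise ValueError("all diameters must be positive")
    pk = params.pack()
    pm, Qin, Qout, segQ, segdp, jpJ, jQ1, jQ2, jdp1, jdp2 = _k.network_flows(
        t, D, pk, bc.pa, bc.pb, bc.pe, schedule.offsets,
        topology.seg_up, topology.seg_dn,
        topology.jn_c1, topology.jn_c2, topology.jn_p)
    res = _flow_residual(topology, pm, D, segQ, segdp, jpJ, jQ1, jQ2, jdp1,
                         jdp2, bc, params)
    return FlowSolution(
        t=t, p_mid=pm, Q_in=Qin, Q_out=Qout, seg_Q=segQ, seg_dp=segdp,
        junction_p=jpJ, junction_Q=np.stack([jQ1, jQ2, jQ1 + jQ2], axis=-1),
        junction_dp=np.stack([jdp1, jdp2], axis=-1), residual=res)


def _flow_residual(topology, pm, D, segQ, segdp, jpJ, jQ1, jQ2, jdp1, jdp2,
                   bc, params) -> float:
    """Worst relative momentum residual over all segments and junctions."""
    pk = params.pack()
    Rh = np.array([_k.rves(d, pk) for d in D])
    scale = max(1.0, float(np.max(np.abs(pm))))
    worst = 0.0
    for s, (u, d) in enumerate(zip(topology.seg_up, topology.seg_dn)):
        pu = bc.pa if u < 0 else pm[u]
        pd_ = bc.pb if d < 0 else pm[d]
        R = (0.0 if u < 0 else Rh[u]) + (0.0 if d < 0 else Rh[d])
        r = abs(pu - pd_ - segdp[s] - R * segQ[s])
        rv_ = abs(_k.rv(segdp[s], pk) * segQ[s] - segdp[s])
        worst = max(worst, r / scale, rv_ / scale)
    for j in range(jpJ.size):
        c1, c2, p = topology.jn_c1[j], topology.jn_c2[j], topology.jn_p[j]
        for (c, Q, dp) in ((c1, jQ1[j], jdp1[j]), (c2, jQ2[j], jdp2[j])):
            r = abs(pm[c] - jpJ[j] - dp - Rh[c] * Q)
            rv_ = abs(_k.rv(dp, pk) * Q - dp)
            worst = max(worst, r / scale, rv_ / scale)
        r = abs(jpJ[j] - pm[p] - Rh[p] * (jQ1[j] + jQ2[j]))
        worst = max(worst, r / scale)
    return worst


def ode_rhs(t: float, D: np.ndarray, topology: NetworkTopology,
            schedule: ContractionSchedule, bc: BoundaryConditions,
            params: PhysicalParams) -> np.ndarray:
    """dD/dt = 2 (Q_in - Q_out) / (pi D L) for every lymphangion."""
    sol = network_flow_solve(t, D, topology, schedule, bc, params)
    return 2.0 * (sol.Q_in - sol.Q_out) / (np.pi * np.asarray(D) * params.L)


def initial_diameters(topology: NetworkTopology, bc: BoundaryConditions,
                      params: PhysicalParams) -> np.ndarray:
    """Passive-equilibrium diameters, muscle relaxed.

    The local resting pressure is interpolated linearly from pa at the inlet
    boundary to pb at the outlet along each flow path; the choice only
    affects the discarded transient.
    """
    D0 = np.empty(topology.n_lymphangions)
    for i in range(topology.n_lymphangions):
        frac = topology.path_position(i)
        ptm = bc.pa + frac * (bc.pb - bc.pa) - bc.pe
        D0[i] = passive_equilibrium_diameter(ptm, params)
    return D0


def run_simulation(topology: NetworkTopology, schedule: ContractionSchedule,
                   bc: BoundaryConditions, params: PhysicalParams,
                   settings: SolverSettings = SolverSettings(),
                   D0: Optional[np.ndarray] = None) -> SimulationResult:
    """Integrate to a periodic pumping state and report cycle-mean flows.

    Integration proceeds one period at a time with BDF (sparse
    finite-difference Jacobian); the outlet- and inlet-valve flows are
    integrated alongside the diameters as auxiliary volume states, so cycle
    means inherit the integrator's error control. Cycles before convergence
    constitute the discarded initial transient.
    """
    NL = topology.n_lymphangions
    T = schedule.period
    pk = params.pack()
    if D0 is None:
        D0 = initial_diameters(topology, bc, params)
    D0 = np.asarray(D0, dtype=float)
    if D0.shape != (NL,) or np.any(D0 <= 0):
        raise ValueError("D0 must be positive with one entry per lymphangion")

    args = (pk, bc.pa, bc.pb, bc.pe, schedule.offsets,
            topology.seg_up, topology.seg_dn,
            topology.jn_c1, topology.jn_c2, topology.jn_p,
            topology.outlet_seg, topology.inlet_segs)

    def f(t, y):
        return _k.rhs(t, y, *args)

    sparsity = topology.jacobian_sparsity(n_extra=2)
    atol = np.full(NL + 2, settings.atol_diameter)
    atol[NL:] = settings.atol_volume

    y = np.concatenate([D0, [0.0, 0.0]])
    t0 = 0.0
    out_means, in_means = [], []
    times, diam = [], []
    converged = False
    n_cycles = 0
    for cycle in range(settings.max_cycles):
        y[NL:] = 0.0
        t_eval = np.linspace(t0, t0 + T, settings.samples_per_cycle + 1)
        sol = solve_ivp(f, (t0, t0 + T), y, method="BDF", rtol=settings.rtol,
                        atol=atol, t_eval=t_eval, jac_sparsity=sparsity)
        if not sol.success:
            raise SolverError(f"integration failed in cycle {cycle}: {sol.message}")
        y = sol.y[:, -1].copy()
        first = 1 if cycle > 0 else 0
        times.append(sol.t[first:])
        diam.append(sol.y[:NL, first:])
        if sol.y[:NL].min() <= 0:
            raise SolverError(f"non-positive diameter in cycle {cycle}")
        out_means.append(y[NL] / T * CM3S_TO_MLHR)
        in_means.append(y[NL + 1] / T * CM3S_TO_MLHR)
        n_cycles = cycle + 1
        if n_cycles >= settings.min_cycles:
            prev, cur = out_means[-2], out_means[-1]
            tol = max(settings.conv_rel * max(abs(prev), abs(cur)),
                      settings.conv_abs_ml_hr)
            if abs(cur - prev) <= tol:
                converged = True
                break
        t0 += T

    return SimulationResult(
        topology=topology, schedule=schedule, bc=bc, params=params,
        settings=settings, times=np.concatenate(times),
        diameters=np.concatenate(diam, axis=1),
        cycle_out_ml_hr=np.array(out_means), cycle_in_ml_hr=np.array(in_means),
        converged=converged, n_cycles=n_cycles, final_state=y)


def mean_outlet_flow(result: SimulationResult, periods: int = 1) -> float:
    """Time-averaged outlet-valve flow over the final ``periods`` cycles, ml/hr."""
    if periods < 1 or periods > result.n_cycles:
        raise ValueError("periods must be within the simulated cycle count")
    return float(np.mean(result.cycle_out_ml_hr[-periods:]))


def periodic_time_average(t: np.ndarray, q: np.ndarray, period: float) -> float:
    """Trapezoidal time-average of a series over its (integer-period) window.

    The window length must be an integer number of periods (to 1e-9 relative);
    returns the average in the units of ``q``.
    """
    t = np.asarray(t, dtype=float)
    span = t[-1] - t[0]
    n = span / period
    if abs(n - round(n)) > 1e-9 * max(1.0, n) or round(n) < 1:
        raise ValueError("averaging window must span an integer number of periods")
    return float(np.trapezoid(q, t) / span)
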