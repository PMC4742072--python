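"""Parameter-sweep drivers for the network pump-function studies.

Each driver varies one control — outlet pressure pb (pump function curve),
external pressure pe (transmural pressure), joint contraction-wave delay
dt = dtv = dtg, or diastolic period tr — holding everything else at the
baseline configuration, and records the converged cycle-mean outlet flow
Q-bar (ml/hr) per grid point.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .model_core import PhysicalParams
from .solver import (
    BoundaryConditions, SimulationResult, SolverError, SolverSettings,
    run_simulation,
)
from .topology import (
    build_bifurcating_network, contraction_schedule, propagation_direction,
)

__all__ = [
    "BaseCase", "SweepSpec", "SweepResult", "run_case", "pump_function_curve",
    "sweep_external_pressure", "sweep_time_delay", "sweep_diastolic_period",
    "find_peak", "FIGURE_SWEEPS", "reproduce",
]


@dataclass(frozen=True)
class BaseCase:
    """Baseline configuration (all values as in the reference parameter set)."""

    n_generations: int = 3
    nv: int = 4
    pa_cmH2O: float = 6.0
    pb_cmH2O: float = 9.0
    pe_cmH2O: float = 2.0
    dtv: float = 0.5
    dtg: float = 0.5
    params: PhysicalParams = field(default_factory=PhysicalParams)
    settings: SolverSettings = field(default_factory=SolverSettings)

    def with_(self, **kw) -> "BaseCase":
        pkw = {k[2:]: v for k, v in kw.items() if k.startswith("p_")}
        kw = {k: v for k, v in kw.items() if not k.startswith("p_")}
        case = replace(self, **kw)
        if pkw:
            case = replace(case, params=case.params.with_(**pkw))
        return case


def run_case(case: BaseCase) -> SimulationResult:
    """Build topology/schedule/boundary conditions from a case and simulate."""
    topo = build_bifurcating_network(case.n_generations, case.nv)
    sched = contraction_schedule(topo, case.dtv, case.dtg,
                                 case.params.Tc, case.params.tr)
    bc = BoundaryConditions.from_cmh2o(case.pa_cmH2O, case.pb_cmH2O,
                                       case.pe_cmH2O)
    return run_simulation(topo, sched, bc, case.params, case.settings)


@dataclass(frozen=True)
class SweepSpec:
    """One swept variable over a strictly monotone grid, on a fixed base case.

    ``var`` is one of pb | pe | tr | dt_joint | nv | Tc (pressures in cmH2O,
    times in s).
    """

    var: str
    grid: np.ndarray
    base: BaseCase = field(default_factory=BaseCase)

    _VARS = ("pb", "pe", "tr", "dt_joint", "nv", "Tc")

    def __post_init__(self):
        if self.var not in self._VARS:
            raise ValueError(f"unknown sweep variable {self.var!r}")
        g = np.asarray(self.grid, dtype=float)
        if g.size == 0 or (g.size > 1 and not (np.all(np.diff(g) > 0)
                                               or np.all(np.diff(g) < 0))):
            raise ValueError("grid must be nonempty and strictly monotone")
        object.__setattr__(self, "grid", g)

    def case_at(self, value: float) -> BaseCase:
        if self.var == "pb":
            return self.base.with_(pb_cmH2O=value)
        if self.var == "pe":
            return self.base.with_(pe_cmH2O=value)
        if self.var == "tr":
            return self.base.with_(p_tr=value)
        if self.var == "dt_joint":
            return self.base.with_(dtv=value, dtg=value)
        if self.var == "nv":
            return self.base.with_(nv=int(round(value)))
        return self.base.with_(p_f=1.0 / value)  # Tc = 1/f


@dataclass(frozen=True)
class SweepResult:
    """Q-bar per grid point, with per-point convergence flags."""

    spec: SweepSpec
    qbar_ml_hr: np.ndarray
    converged: np.ndarray
    extra: dict = field(default_factory=dict)

    @property
    def grid(self) -> np.ndarray:
        return self.spec.grid

    @property
    def peak(self) -> tuple:
        """(argmax grid value, peak Q-bar); ties break to the smaller value."""
        return find_peak(self)

    def to_frame(self):
        import pandas as pd
        base = self.spec.base
        df = pd.DataFrame({
            "swept_var": self.spec.var,
            "swept_value": self.grid,
            "Qbar_ml_hr": self.qbar_ml_hr,
            "converged": self.converged,
        })
        for k, v in (("n_generations", base.n_generations), ("nv", base.nv),
                     ("pa_cmH2O", base.pa_cmH2O), ("pb_cmH2O", base.pb_cmH2O),
                     ("pe_cmH2O", base.pe_cmH2O), ("dtv_s", base.dtv),
                     ("dtg_s", base.dtg), ("Tc_s", base.params.Tc),
                     ("tr_s", base.params.tr)):
            df[k] = v
        for k, v in self.extra.items():
            df[k] = v
        return df


def _run_sweep(spec: SweepSpec) -> SweepResult:
    qbar = np.empty(spec.grid.size)
    conv = np.zeros(spec.grid.size, dtype=bool)
    for i, v in enumerate(spec.grid):
        try:
            res = run_case(spec.case_at(v))
            qbar[i] = res.qbar_ml_hr
            conv[i] = res.converged
        except SolverError:
            qbar[i] = np.nan
    return SweepResult(spec, qbar, conv)


def pump_function_curve(nv: int, pb_values, base: BaseCase = BaseCase()) -> SweepResult:
    """Q-bar vs outlet pressure pb (the pump function curve) at fixed nv."""
    spec = SweepSpec("pb", np.asarray(pb_values, float), base.with_(nv=nv))
    out = _run_sweep(spec)
    dP = spec.grid - base.pa_cmH2O
    return SweepResult(spec, out.qbar_ml_hr, out.converged,
                       extra={"dP_cmH2O": dP})


def sweep_external_pressure(nv: int, pe_values, dP_cmH2O: float,
                            base: BaseCase = BaseCase()) -> SweepResult:
    """Q-bar vs external pressure pe at fixed axial pressure difference dP."""
    b = base.with_(nv=nv, pb_cmH2O=base.pa_cmH2O + dP_cmH2O)
    spec = SweepSpec("pe", np.asarray(pe_values, float), b)
    out = _run_sweep(spec)
    return SweepResult(spec, out.qbar_ml_hr, out.converged,
                       extra={"ptm_cmH2O": b.pa_cmH2O - spec.grid})


def sweep_time_delay(nv: int, dt_values, dP_cmH2O: float,
                     pe_cmH2O: Optional[float] = None,
                     base: BaseCase = BaseCase()) -> SweepResult:
    """Q-bar vs joint delay dt = dtv = dtg, with forward/reverse classification."""
    b = base.with_(nv=nv, pb_cmH2O=base.pa_cmH2O + dP_cmH2O)
    if pe_cmH2O is not None:
        b = b.with_(pe_cmH2O=pe_cmH2O)
    spec = SweepSpec("dt_joint", np.asarray(dt_values, float), b)
    out = _run_sweep(spec)
    direction = [propagation_direction(dt, b.params.Tc, b.params.tr)
                 for dt in spec.grid]
    return SweepResult(spec, out.qbar_ml_hr, out.converged,
                       extra={"direction": direction})


def sweep_diastolic_period(nv: int, tr_values,
                           base: BaseCase = BaseCase()) -> SweepResult:
    """Q-bar vs diastolic period tr (the cycle period T = Tc + tr varies too)."""
    spec = SweepSpec("tr", np.asarray(tr_values, float), base.with_(nv=nv))
    return _run_sweep(spec)


def find_peak(sweep: SweepResult) -> tuple:
    """Grid argmax of Q-bar, ties toward the smaller grid value; no interpolation."""
    q = sweep.qbar_ml_hr
    ok = sweep.converged & np.isfinite(q)
    if not ok.any():
        raise SolverError("no converged sweep point")
    masked = np.where(ok, q, -np.inf)
    order = np.argsort(sweep.grid)          # ascending grid; first max wins ties
    k = order[int(np.argmax(masked[order]))]
    return float(sweep.grid[k]), float(q[k])


#: Paper-family sweep grids (pressures cmH2O, times s).
FIGURE_SWEEPS = {
    "fig3": {"nv": list(range(1, 15)), "pb": np.arange(3.0, 41.0 + 0.5, 1.0)},
    "fig4": {"nv": [2, 4, 8], "dP": [3.0, 10.0, 16.0],
             "pe": np.arange(1.0, 5.0 + 0.1, 0.2)},
    "fig5": {"nv": [4], "tr": np.arange(0.0, 3.5 + 0.25, 0.5),
             "pb": np.arange(3.0, 36.0 + 0.5, 1.0)},
    "fig6": {"nv": [4], "dt_pairs": [(0.0, 0.0), (0.0, 0.5), (0.5, 0.5)],
             "pe": [2.0, 3.0], "pb": np.arange(3.0, 36.0 + 0.5, 1.0)},
    "fig7": {"nv": [4], "dt": np.arange(0.0, 3.5 + 0.025, 0.05),
             "dP": [-3.0, 0.0, 6.0, 12.0, 18.0, 24.0]},
}


def reproduce(figure: str, base: BaseCase = BaseCase(), **overrides) -> list:
    """Run the full sweep family behind one results figure.

    Returns a list of SweepResult. Grid overrides (e.g. ``nv=[2]`` or a
    coarser ``pb``) cut the run count; the defaults enumerate the complete
    published conditions and can take hours for fig3/fig6.
    """
    if figure not in FIGURE_SWEEPS:
        raise ValueError(f"unknown figure family {figure!r}")
    g = dict(FIGURE_SWEEPS[figure])
    g.update(overrides)
    out = []
    if figure == "fig3":
        for nv in g["nv"]:
            out.append(pump_function_curve(nv, g["pb"], base))
    elif figure == "fig4":
        for nv in g["nv"]:
            for dP in g["dP"]:
                out.append(sweep_external_pressure(nv, g["pe"], dP, base))
    elif figure == "fig5":
        for nv in g["nv"]:
            for tr in g["tr"]:
                out.append(pump_function_curve(nv, g["pb"], base.with_(p_tr=tr)))
    elif figure == "fig6":
        for nv in g["nv"]:
            for pe in g["pe"]:
                for dtv, dtg in g["dt_pairs"]:
                    out.append(pump_function_curve(
                        nv, g["pb"], base.with_(pe_cmH2O=pe, dtv=dtv, dtg=dtg)))
    elif figure == "fig7":
        for nv in g["nv"]:
            for dP in g["dP"]:
                out.append(sweep_time_delay(nv, g["dt"], dP, base=base))
    return out
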