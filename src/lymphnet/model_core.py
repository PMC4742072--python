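"""Constitutive relations for a single lymphangion and its valves.

A lymphangion is the contractile unit of a collecting lymphatic vessel,
bounded by one-way intraluminal valves. Its wall obeys a force balance

    p_im - p_e = fp(D) + fa(D, t),

where ``fp`` is the passive (experimentally fitted, strongly nonlinear)
pressure-diameter tube law and ``fa = 2 M0 Md(D) Mt(t) / D`` is the active
Laplace-law pressure generated by lymphatic muscle. Valves are modelled as a
smooth, pressure-difference-dependent resistance that is minimal for forward
flow, maximal shortly after the trans-valve pressure turns slightly negative,
and returns to minimal below a large negative "failure" (prolapse) pressure.

All quantities are in cgs units internally: dyn/cm^2 (pressure), cm
(diameter), cm^3/s (flow), g/(cm^4 s) (resistance), dyn/cm (tension).
Boundary values quoted in cmH2O convert with 980.665 dyn/cm^2 per cmH2O.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Union

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from . import _kernel as _k

ArrayLike = Union[float, np.ndarray]

#: dyn/cm^2 per cmH2O (standard water column at 4 degC, g = 980.665 cm/s^2)
CMH2O_TO_DYNCM2 = 980.665


def cmh2o_to_dyncm2(p: ArrayLike) -> ArrayLike:
    """Convert a pressure from cmH2O to dyn/cm^2."""
    return np.multiply(p, CMH2O_TO_DYNCM2)


def dyncm2_to_cmh2o(p: ArrayLike) -> ArrayLike:
    """Convert a pressure from dyn/cm^2 to cmH2O (inverse of cmh2o_to_dyncm2)."""
    return np.divide(p, CMH2O_TO_DYNCM2)


@dataclass(frozen=True)
class PhysicalParams:
    """All physical constants of the model, baseline values by default.

    Pressures are stored in cgs; ``dpf_cmH2O`` is the one constant quoted in
    cmH2O and is converted on access (``dpf``) so that the slope ``sf``
    (cm^2/dyn) applies. ``dpo_dyncm2`` is quoted - and used - in dyn/cm^2.

    The three model-form switches (``c9_mode``, ``md_form``, ``half_segment``)
    select between alternative readings of ambiguously printed constants; the
    defaults are the physiological ones (see docs/methods.md).
    """

    mu: float = 0.01          # fluid viscosity, g/(cm s)
    L: float = 0.3            # lymphangion length, cm
    Pd: float = 732.0         # tube-law pressure scale, dyn/cm^2
    Dd: float = 0.00845       # tube-law diameter constant, cm
    M0: float = 250.0         # active tension scale, dyn/cm
    f: float = 0.5            # contraction frequency, Hz
    tr: float = 1.5           # diastolic period, s
    RVn: float = 0.5e6        # minimum valve resistance, g/(cm^4 s)
    RVx: float = 9.9e9        # maximum valve resistance, g/(cm^4 s)
    sf: float = 0.049         # valve failure slope, cm^2/dyn
    so: float = 0.4           # valve closing slope, cm^2/dyn
    dpf_cmH2O: float = -18.4  # valve failure (prolapse) pressure, cmH2O
    dpo_dyncm2: float = -15.0  # valve closing threshold, dyn/cm^2
    c1: float = -2.34457751
    c2: float = 1.1262924
    c3: float = 3.76013762
    c4: float = 79.991135
    c5: float = 1.0028029
    c6: float = 1.59133174
    c7: float = 3.69692633
    c8: float = 0.20699868
    c10: float = -0.0180867408
    c11: float = 0.32538081
    c9_mode: str = "ratio"        # "ratio": c9 = Dd/c11 ; "product": Dd*c11
    md_form: str = "corrected"    # "corrected": second sigmoid at Db; "literal"
    half_segment: str = "full"    # each half-drop uses full-L ("full") or L/2

    def __post_init__(self) -> None:
        if min(self.mu, self.L, self.RVn, self.RVx, self.Pd, self.Dd) <= 0:
            raise ValueError("viscosity, lengths and resistances must be positive")
        if self.RVx <= 10 * self.RVn:
            raise ValueError("RVx must greatly exceed RVn")
        if self.f <= 0 or self.tr < 0:
            raise ValueError("require f > 0 and tr >= 0")
        if not (self.dpf < self.dpo < 0):
            raise ValueError("require dp_f < dp_o < 0 in dyn/cm^2")
        if self.c9_mode not in ("ratio", "product"):
            raise ValueError(f"unknown c9_mode {self.c9_mode!r}")
        if self.md_form not in ("corrected", "literal"):
            raise ValueError(f"unknown md_form {self.md_form!r}")
        if self.half_segment not in ("full", "half"):
            raise ValueError(f"unknown half_segment {self.half_segment!r}")

    # -- derived constants (never stored/serialized) --------------------------
    @property
    def Tc(self) -> float:
        """Contraction period 1/f, s."""
        return 1.0 / self.f

    @property
    def period(self) -> float:
        """Full cycle period T = 1/f + tr, s."""
        return 1.0 / self.f + self.tr

    @property
    def dpf(self) -> float:
        """Valve failure pressure in dyn/cm^2."""
        return float(cmh2o_to_dyncm2(self.dpf_cmH2O))

    @property
    def dpo(self) -> float:
        """Valve closing threshold in dyn/cm^2 (used as printed)."""
        return self.dpo_dyncm2

    @property
    def c9(self) -> float:
        """Characteristic diameter, cm."""
        if self.c9_mode == "ratio":
            return self.Dd / self.c11
        return self.Dd * self.c11

    @property
    def sd(self) -> float:
        """Muscle length-factor slope 3.25/Dd, 1/cm."""
        return 3.25 / self.Dd

    @property
    def Da(self) -> float:
        return 0.85 * self.c9

    @property
    def Db(self) -> float:
        return 2.0 * self.c9

    # -- serialization ---------------------------------------------------------
    _STORED = ("mu", "L", "Pd", "Dd", "M0", "f", "tr", "RVn", "RVx", "sf", "so",
               "dpf_cmH2O", "dpo_dyncm2", "c1", "c2", "c3", "c4", "c5", "c6",
               "c7", "c8", "c10", "c11", "c9_mode", "md_form", "half_segment")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self._STORED}

    @classmethod
    def from_dict(cls, d: dict) -> "PhysicalParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown physical parameter(s): {sorted(unknown)}")
        return cls(**d)

    def with_(self, **kw) -> "PhysicalParams":
        """Functional update (dataclasses.replace wrapper)."""
        return replace(self, **kw)

    def pack(self) -> np.ndarray:
        """Pack into the flat float vector consumed by the jitted kernels."""
        pk = np.empty(_k.NPK)
        pk[_k.MU] = self.mu
        pk[_k.LL] = self.L
        pk[_k.PD] = self.Pd
        pk[_k.DD] = self.Dd
        pk[_k.M0] = self.M0
        pk[_k.FREQ] = self.f
        pk[_k.TR] = self.tr
        pk[_k.RVN] = self.RVn
        pk[_k.RVX] = self.RVx
        pk[_k.SF] = self.sf
        pk[_k.SO] = self.so
        pk[_k.DPF] = self.dpf
        pk[_k.DPO] = self.dpo
        for i, name in enumerate(("c1", "c2", "c3", "c4", "c5", "c6", "c7", "c8")):
            pk[_k.C1 + i] = getattr(self, name)
        pk[_k.C10] = self.c10
        pk[_k.C11] = self.c11
        pk[_k.C9] = self.c9
        pk[_k.SD] = self.sd
        pk[_k.DA] = self.Da
        pk[_k.DB] = self.Db
        pk[_k.HALF] = 1.0 if self.half_segment == "full" else 0.5
        pk[_k.MDLIT] = 1.0 if self.md_form == "literal" else 0.0
        return pk


def _require_positive_diameter(D: ArrayLike) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if np.any(D <= 0):
        raise ValueError("diameter must be strictly positive")
    return D


def passive_pressure(D: ArrayLike, params: PhysicalParams) -> ArrayLike:
    """Passive tube-law pressure fp(D), dyn/cm^2.

    Strictly increasing in D over (0, inf): the -1/D^3 term drives fp to
    -infinity on collapse, the exponential term to +infinity on distension.
    """
    D = _require_positive_diameter(D)
    x = D / params.c9
    expo = np.minimum(params.c4 * (x - params.c5), _k._EXP_CLIP)
    out = params.Pd * (
        params.c1 * (x - params.c2) ** 2
        + params.c3 * np.exp(expo)
        + params.c6
        + params.c7 * (x - params.c8)
        + params.c10 / x ** 3
    )
    return out if out.ndim else float(out)


def muscle_time_course(t: ArrayLike, t_start: float, params: PhysicalParams) -> ArrayLike:
    """Normalized activation Mt(t) in [0, 1].

    Raised-cosine pulse of duration 1/f starting at ``t_start``, zero during
    the diastolic period tr, periodic with T = 1/f + tr.
    """
    tau = np.mod(np.asarray(t, dtype=float) - t_start, params.period)
    out = np.where(tau <= params.Tc,
                   0.5 * (1.0 - np.cos(2.0 * np.pi * params.f * tau)), 0.0)
    return out if out.ndim else float(out)


def muscle_length_factor(D: ArrayLike, params: PhysicalParams) -> ArrayLike:
    """Diameter-dependent tension modulation Md(D), a bump on [Da, Db]."""
    D = _require_positive_diameter(D)
    upper = params.Da if params.md_form == "literal" else params.Db
    out = (expit(params.sd * (D - params.Da))
           + expit(-params.sd * (D - upper)) - 1.0)
    return out if out.ndim else float(out)


def active_pressure(D: ArrayLike, Mt: ArrayLike, params: PhysicalParams) -> ArrayLike:
    """Active Laplace-law pressure fa = 2 M0 Md(D) Mt / D, dyn/cm^2."""
    D = _require_positive_diameter(D)
    out = 2.0 * params.M0 * muscle_length_factor(D, params) * np.asarray(Mt, float) / D
    return out if np.ndim(out) else float(out)


def midpoint_pressure(D: ArrayLike, t: ArrayLike, t_start: float, pe: float,
                      params: PhysicalParams) -> ArrayLike:
    """Lymphangion midpoint pressure p_im = pe + fp(D) + fa(D, t), dyn/cm^2."""
    Mt = muscle_time_course(t, t_start, params)
    return pe + passive_pressure(D, params) + active_pressure(D, Mt, params)


def valve_resistance(dp: ArrayLike, params: PhysicalParams) -> ArrayLike:
    """Valve resistance RV(dp), g/(cm^4 s); dp > 0 is forward.

    ~RVn for forward dp, ~RVn + RVx for moderately adverse dp (valve shut),
    and back to ~RVn below the failure pressure dp_f (prolapse, valve forced
    open). Smooth everywhere; bounded in [RVn - eps, RVn + RVx].
    """
    dp = np.asarray(dp, dtype=float)
    out = params.RVn + params.RVx * (
        expit(params.sf * (dp - params.dpf))
        + expit(-params.so * (dp - params.dpo)) - 1.0
    )
    return out if out.ndim else float(out)


def poiseuille_resistance(D: ArrayLike, params: PhysicalParams) -> ArrayLike:
    """Half-segment viscous resistance 64 mu L / (pi D^4), g/(cm^4 s).

    With ``half_segment="half"`` the length entering each half-drop is L/2.
    """
    D = _require_positive_diameter(D)
    factor = 1.0 if params.half_segment == "full" else 0.5
    out = factor * 64.0 * params.mu * params.L / (np.pi * D ** 4)
    return out if out.ndim else float(out)


def passive_equilibrium_diameter(ptm: float, params: PhysicalParams,
                                 bracket: tuple = (1e-4, 1.0)) -> float:
    """Invert the tube law: the D with fp(D) = ptm (muscle relaxed).

    fp is strictly increasing on (0, inf) with range (-inf, +inf), so the
    root is unique; solved by Brent's method to 1e-12 relative.
    """
    lo, hi = bracket
    f_lo = passive_pressure(lo, params) - ptm
    f_hi = passive_pressure(hi, params) - ptm
    if f_lo > 0 or f_hi < 0:
        raise ValueError(f"transmural pressure {ptm} outside bracket {bracket}")
    return brentq(lambda d: passive_pressure(d, params) - ptm, lo, hi,
                  xtol=1e-15, rtol=1e-12)
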