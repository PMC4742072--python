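"""Converging bifurcation tree of lymphatic vessels and contraction timing.

The network has ``n_generations`` generations of vessels: generation G (the
largest index) holds the 2^(G-1) inlet vessels, generation 1 the single
outlet vessel; every pair of sibling vessels converges into its parent at a
junction. Each vessel is a chain of ``nv`` lymphangions. Valves sit between
adjacent lymphangions within a vessel, at every vessel outlet (these double
as the parent's inflow valves at junctions) and at every inlet-generation
vessel entrance; the segment from a junction node into the parent's first
lymphangion carries no extra valve.

Vessels are labelled GGNN (generation, index), e.g. "0301" is the first
inlet vessel and "0101" the outlet vessel of a 3-generation tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "VesselId", "Lymphangion", "Segment", "Junction", "NetworkTopology",
    "ContractionSchedule", "build_bifurcating_network", "contraction_schedule",
    "reverse_equivalent_delay", "propagation_direction",
]


@dataclass(frozen=True, order=True)
class VesselId:
    """Vessel coordinates: generation (1 = outlet) and index within generation."""

    generation: int
    index: int

    def __post_init__(self):
        if self.generation < 1 or not (1 <= self.index <= 2 ** (self.generation - 1)):
            raise ValueError(f"invalid vessel coordinates ({self.generation}, {self.index})")

    @property
    def label(self) -> str:
        return f"{self.generation:02d}{self.index:02d}"

    @property
    def parent(self) -> Optional["VesselId"]:
        if self.generation == 1:
            return None
        return VesselId(self.generation - 1, (self.index + 1) // 2)

    def children(self, n_generations: int) -> tuple:
        if self.generation >= n_generations:
            return ()
        g = self.generation + 1
        return (VesselId(g, 2 * self.index - 1), VesselId(g, 2 * self.index))


@dataclass(frozen=True)
class Lymphangion:
    """One contractile unit: its vessel, 1-based position (1 = upstream end),
    and global index in the canonical ordering."""

    vessel: VesselId
    position: int
    global_index: int


@dataclass(frozen=True)
class Segment:
    """One directed flow unknown between two pressure points.

    ``up``/``down`` are global lymphangion indices; -1 stands for the pa / pb
    boundary (kinds "inlet"/"outlet") or for the junction node (kinds
    "junction_child"/"junction_parent", which carry ``junction`` >= 0).
    """

    kind: str
    up: int
    down: int
    has_valve: bool
    junction: int = -1


@dataclass(frozen=True)
class Junction:
    """A converging junction: the last lymphangions of the two child vessels
    and the first lymphangion of the parent vessel share one node."""

    index: int
    child_last: tuple
    parent_first: int


@dataclass(frozen=True)
class NetworkTopology:
    """The full network graph, built deterministically from (n_generations, nv).

    ``segments`` lists every flow unknown; the ``seg_up``/``seg_dn`` arrays
    view only the *simple* segments (both endpoint pressures explicit in the
    diameters) for the flow kernel, junction segments being resolved by the
    per-junction node solve.
    """

    n_generations: int
    nv: int
    vessels: tuple
    lymphangions: tuple
    segments: tuple
    junctions: tuple
    # kernel views over the simple segments
    seg_up: np.ndarray = field(repr=False, default=None)
    seg_dn: np.ndarray = field(repr=False, default=None)
    jn_c1: np.ndarray = field(repr=False, default=None)
    jn_c2: np.ndarray = field(repr=False, default=None)
    jn_p: np.ndarray = field(repr=False, default=None)
    outlet_seg: int = -1            # index into the simple-segment arrays
    inlet_segs: np.ndarray = field(repr=False, default=None)

    @property
    def n_vessels(self) -> int:
        return 2 ** self.n_generations - 1

    @property
    def n_lymphangions(self) -> int:
        return self.nv * self.n_vessels

    @property
    def n_junctions(self) -> int:
        return 2 ** (self.n_generations - 1) - 1

    @property
    def n_inlets(self) -> int:
        return 2 ** (self.n_generations - 1)

    @property
    def n_valves(self) -> int:
        return sum(1 for s in self.segments if s.has_valve)

    def vessel_first_index(self, vessel: VesselId) -> int:
        return self._first[vessel]

    @property
    def _first(self) -> dict:
        return {l.vessel: l.global_index for l in self.lymphangions if l.position == 1}

    def lymphangion_index(self, vessel: VesselId, position: int) -> int:
        if not 1 <= position <= self.nv:
            raise ValueError(f"position {position} outside 1..{self.nv}")
        return self._first[vessel] + position - 1

    def path_position(self, i: int) -> float:
        """Fractional position (0 = inlet boundary, 1 = outlet boundary) of
        lymphangion i along its root-to-leaf flow path."""
        lym = self.lymphangions[i]
        g = lym.vessel.generation
        upstream = (self.n_generations - g) * self.nv + (lym.position - 1)
        return (upstream + 0.5) / (self.n_generations * self.nv)

    def jacobian_sparsity(self, n_extra: int = 2) -> np.ndarray:
        """Boolean coupling pattern of the (NL + n_extra)-state ODE system."""
        NL = self.n_lymphangions
        n = NL + n_extra
        S = np.zeros((n, n), dtype=bool)
        np.fill_diagonal(S[:NL, :NL], True)
        for s in self.segments:
            if s.up >= 0 and s.down >= 0:
                S[s.up, s.down] = S[s.down, s.up] = True
        for j in self.junctions:
            for a in (*j.child_last, j.parent_first):
                for b in (*j.child_last, j.parent_first):
                    S[a, b] = True
        if n_extra >= 1:  # outlet volume rate depends on the outlet lymphangion
            S[NL, int(self.seg_up[self.outlet_seg])] = True
        if n_extra >= 2:  # inlet volume rate depends on the first inlet lymphangions
            for k in self.inlet_segs:
                S[NL + 1, int(self.seg_dn[k])] = True
        return S


def build_bifurcating_network(n_generations: int, nv: int) -> NetworkTopology:
    """Build the symmetric converging tree with ``nv`` lymphangions per vessel.

    Canonical ordering: inlet generation first, left to right within a
    generation, positions within a vessel from upstream to downstream.
    """
    if n_generations < 1 or nv < 1:
        raise ValueError("n_generations and nv must be >= 1")
    G = n_generations
    vessels = tuple(
        VesselId(g, i) for g in range(G, 0, -1) for i in range(1, 2 ** (g - 1) + 1)
    )
    lymphangions = []
    first = {}
    for v in vessels:
        first[v] = len(lymphangions)
        for pos in range(1, nv + 1):
            lymphangions.append(Lymphangion(v, pos, len(lymphangions)))

    segments = []
    simple_up, simple_dn, inlet_simple = [], [], []

    def add_simple(kind, up, down):
        segments.append(Segment(kind, up, down, True))
        simple_up.append(up)
        simple_dn.append(down)
        return len(simple_up) - 1

    for v in vessels:                       # inlet valves first
        if v.generation == G:
            inlet_simple.append(add_simple("inlet", -1, first[v]))
    for v in vessels:                       # intra-vessel valved segments
        for pos in range(1, nv):
            add_simple("intra", first[v] + pos - 1, first[v] + pos)
    junctions = []
    for v in vessels:                       # junctions feed every non-inlet vessel
        if v.generation < G:
            j = len(junctions)
            c1, c2 = v.children(G)
            last1, last2 = first[c1] + nv - 1, first[c2] + nv - 1
            junctions.append(Junction(j, (last1, last2), first[v]))
            segments.append(Segment("junction_child", last1, -1, True, j))
            segments.append(Segment("junction_child", last2, -1, True, j))
            segments.append(Segment("junction_parent", -1, first[v], False, j))
    outlet_simple = add_simple("outlet", first[VesselId(1, 1)] + nv - 1, -1)

    return NetworkTopology(
        n_generations=G, nv=nv, vessels=vessels,
        lymphangions=tuple(lymphangions), segments=tuple(segments),
        junctions=tuple(junctions),
        seg_up=np.array(simple_up, dtype=np.int64),
        seg_dn=np.array(simple_dn, dtype=np.int64),
        jn_c1=np.array([j.child_last[0] for j in junctions], dtype=np.int64),
        jn_c2=np.array([j.child_last[1] for j in junctions], dtype=np.int64),
        jn_p=np.array([j.parent_first for j in junctions], dtype=np.int64),
        outlet_seg=outlet_simple,
        inlet_segs=np.array(inlet_simple, dtype=np.int64),
    )


@dataclass(frozen=True)
class ContractionSchedule:
    """Per-lymphangion contraction start offsets within the period T = Tc + tr."""

    offsets: np.ndarray
    dtv: float
    dtg: float
    Tc: float
    tr: float

    @property
    def period(self) -> float:
        return self.Tc + self.tr

    def shifted(self, phase: float) -> "ContractionSchedule":
        """Rigid phase shift of every start time (mod T)."""
        return ContractionSchedule(
            np.mod(self.offsets + phase, self.period),
            self.dtv, self.dtg, self.Tc, self.tr,
        )


def contraction_schedule(topology: NetworkTopology, dtv: float, dtg: float,
                         Tc: float, tr: float) -> ContractionSchedule:
    """Assign start offsets for an orthograde contraction wave.

    The wave starts at the inlet generation at t = 0 and propagates toward
    the outlet: the lymphangion at position j of a generation-g vessel starts

        (G - g) * [(nv - 1) * dtv + dtg] + (j - 1) * dtv   (mod T),

    i.e. dtv between neighbours within a vessel and dtg once per junction
    crossing, accumulating across generations. Retrograde propagation is
    realized by large delays (see :func:`reverse_equivalent_delay`).
    """
    if dtv < 0 or dtg < 0:
        raise ValueError("time delays must be non-negative")
    T = Tc + tr
    G, nv = topology.n_generations, topology.nv
    offsets = np.empty(topology.n_lymphangions)
    for lym in topology.lymphangions:
        g = lym.vessel.generation
        off = (G - g) * ((nv - 1) * dtv + dtg) + (lym.position - 1) * dtv
        offsets[lym.global_index] = off % T
    return ContractionSchedule(offsets, dtv, dtg, Tc, tr)


def reverse_equivalent_delay(dt: float, Tc: float, tr: float) -> float:
    """Equivalent delay of the reverse-propagating wave: T - dt, T = Tc + tr."""
    T = Tc + tr
    if not 0 <= dt <= T:
        raise ValueError(f"delay {dt} outside [0, {T}]")
    return T - dt


def propagation_direction(dt: float, Tc: float, tr: float) -> str:
    """'forward' for dt < T/2 (orthograde wave), 'reverse' otherwise."""
    return "forward" if dt < 0.5 * (Tc + tr) else "reverse"
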