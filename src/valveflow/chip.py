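"""Lumped-element fluidic model of the two-layer microfluidic device.

The chip is a valve-gated flow graph: nodes are inlets, outlets, channels,
chambers and the plasma-separation membrane (PSM); edges carry a hydraulic
resistance (psi per nL/s) and may be gated by one of six on-chip membrane
microvalves.  A microvalve is *activated* (closed) when its control line is
pressurized above the closing threshold (~20 psig) and *deactivated*
(open) at atmosphere.

Flow is quasi-static plug flow: between two ports at different pressures
the volumetric rate along the open path of least resistance is
Q = dP / sum(R), and fluid advances node-to-node in first-in-first-out
order, so a chamber's resident air is displaced ahead of incoming liquid
and pressurizing air expels a liquid plug instead of passing through it.  The PSM edge passes plasma only and retains blood cells at the
membrane.  Degassing (pressurized removal of trapped bubbles through the
gas-permeable chip body) is a first-order decay of chamber air; active
mixing between the paired 50 nL sample/reagent chambers is a per-cycle
exchange fraction.

This is deliberately not hydrodynamics: channel geometry is unknown, so
fill *completeness*, species routing and isolation - not fill times - are
the contracts the model supports.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import networkx as nx

#: species considered liquid (conserved under flow)
LIQUIDS = ("plasma", "buffer", "reagent", "blood_cells")
#: species a plasma-only (membrane) edge will pass
MEMBRANE_PASS = ("plasma", "buffer")

DEFAULT_CLOSE_THRESHOLD = 20.0  # psig
DEFAULT_RESISTANCE = 0.01       # psi per (nL/s)
DEFAULT_DEGAS_TAU = 45.0        # s
DEFAULT_EXCHANGE_FRACTION = 0.02
CHAMBER_TRAPPED_FRACTION = 0.04

_VOL_TOL = 1e-9


class ChipError(ValueError):
    """Invalid chip topology, unknown node, or precondition failure."""


class ContaminationError(RuntimeError):
    """Raised when an operation would mix contents of sequestered units."""


@dataclass(frozen=True)
class MicrovalveState:
    """Control-line pressure of one membrane microvalve."""

    id: str
    control_pressure: float
    close_threshold: float = DEFAULT_CLOSE_THRESHOLD

    def __post_init__(self) -> None:
        if self.close_threshold <= 0:
            raise ChipError("close_threshold must be > 0")


def valve_is_closed(v: MicrovalveState) -> bool:
    """Closed (activated) iff the control line is at/above the threshold."""
    return v.control_pressure >= v.close_threshold


class FluidNode:
    """A lumped fluid compartment holding an ordered queue of parcels.

    Channels and chambers have spatial order that a lumped model would
    otherwise lose: the fluid that entered first leaves first.  Contents
    are therefore a FIFO of (species, nL) parcels - new fluid is appended
    at the tail, transfers pop from the head - which makes both directions
    of plug flow come out right (a chamber's initial air is displaced
    ahead of incoming liquid; air pushed in behind a liquid plug expels
    the liquid rather than tunnelling through it).  Parcels that cannot
    move (species blocked by the edge filter, trapped chamber air) are
    skipped in place, like fluid sliding past a retained cell cake or a
    pinned bubble.
    """

    def __init__(self, id: str, kind: str, capacity: float,
                 contents: dict[str, float] | None = None,
                 trapped_air_fraction: float = 0.0):
        if kind not in ("inlet", "outlet", "channel", "chamber", "membrane"):
            raise ChipError(f"unknown node kind {kind!r}")
        if capacity <= 0:
            raise ChipError("node capacity must be > 0")
        self.id = id
        self.kind = kind
        self.capacity = capacity
        self.trapped_air_fraction = trapped_air_fraction
        self.parcels: list[list] = []
        for sp, vol in (contents or {}).items():
            if vol < -_VOL_TOL:
                raise ChipError(f"negative volume of {sp} in {id}")
            if vol > _VOL_TOL:
                self.parcels.append([sp, float(vol)])

    @property
    def contents(self) -> dict[str, float]:
        """Aggregated per-species volumes (parcel order not exposed)."""
        out: dict[str, float] = {}
        for sp, vol in self.parcels:
            out[sp] = out.get(sp, 0.0) + vol
        return out

    @property
    def total(self) -> float:
        return sum(vol for _, vol in self.parcels)

    @property
    def free(self) -> float:
        return max(0.0, self.capacity - self.total)

    def volume(self, species: str) -> float:
        return sum(vol for sp, vol in self.parcels if sp == species)

    def liquid(self) -> float:
        return sum(vol for sp, vol in self.parcels if sp in LIQUIDS)

    def add(self, species: str, vol: float) -> None:
        if vol <= _VOL_TOL:
            return
        if self.parcels and self.parcels[-1][0] == species:
            self.parcels[-1][1] += vol
        else:
            self.parcels.append([species, float(vol)])

    def take(self, budget: float, allowed: tuple[str, ...] | frozenset
             ) -> list[tuple[str, float]]:
        """Pop up to ``budget`` nL of ``allowed`` species from the head.

        Blocked parcels are skipped in place; trapped chamber air (the
        ``trapped_air_fraction`` floor) never leaves by flow.
        """
        moves: list[tuple[str, float]] = []
        air_floor = (self.trapped_air_fraction * self.capacity
                     if self.kind == "chamber" else 0.0)
        air_left = self.volume("air")
        i = 0
        while i < len(self.parcels) and budget > _VOL_TOL:
            sp, vol = self.parcels[i]
            movable = vol
            if sp not in allowed:
                movable = 0.0
            elif sp == "air" and air_floor > 0.0:
                movable = min(vol, max(0.0, air_left - air_floor))
            amount = min(budget, movable)
            if amount > _VOL_TOL:
                self.parcels[i][1] -= amount
                budget -= amount
                if sp == "air":
                    air_left -= amount
                if moves and moves[-1][0] == sp:
                    moves[-1] = (sp, moves[-1][1] + amount)
                else:
                    moves.append((sp, amount))
            if self.parcels[i][1] <= _VOL_TOL:
                self.parcels.pop(i)
            else:
                i += 1
        return moves


class ChipModel:
    """Valve-gated flow graph plus analysis-unit bookkeeping.

    ``analysis_units`` maps a unit name to its (sample chamber, reagent
    chamber) node ids; ``mixing_state`` tracks per-unit homogeneity in
    [0, 1].
    """

    def __init__(self, *, degas_tau: float = DEFAULT_DEGAS_TAU,
                 exchange_fraction: float = DEFAULT_EXCHANGE_FRACTION,
                 close_threshold: float = DEFAULT_CLOSE_THRESHOLD):
        self.graph = nx.Graph()
        self.analysis_units: dict[str, tuple[str, str]] = {}
        self.mixing_state: dict[str, float] = {}
        self.degas_tau = degas_tau
        self.exchange_fraction = exchange_fraction
        self.close_threshold = close_threshold

    # -- construction -----------------------------------------------------
    def add_node(self, node: FluidNode) -> None:
        self.graph.add_node(node.id, node=node)

    def add_edge(self, a: str, b: str, *, valve: str | None = None,
                 resistance: float = DEFAULT_RESISTANCE,
                 species_filter: str | None = None) -> None:
        if resistance <= 0:
            raise ChipError("edge resistance must be > 0")
        if species_filter not in (None, "plasma_only"):
            raise ChipError(f"unknown species_filter {species_filter!r}")
        self.graph.add_edge(a, b, valve=valve, resistance=resistance,
                            species_filter=species_filter)

    def add_analysis_unit(self, name: str, sample: str, reagent: str) -> None:
        for nid in (sample, reagent):
            node = self.node(nid)
            if node.kind != "chamber":
                raise ChipError(f"analysis unit {name}: {nid} is not a chamber")
        self.analysis_units[name] = (sample, reagent)
        self.mixing_state[name] = 0.0

    # -- access -----------------------------------------------------------
    def node(self, node_id: str) -> FluidNode:
        try:
            return self.graph.nodes[node_id]["node"]
        except KeyError:
            raise ChipError(f"unknown node {node_id!r}") from None

    def nodes(self) -> list[FluidNode]:
        return [d["node"] for _, d in self.graph.nodes(data=True)]

    def valves(self) -> set[str]:
        return {d["valve"] for _, _, d in self.graph.edges(data=True)
                if d["valve"] is not None}

    def total_volume(self, species: str) -> float:
        return sum(n.volume(species) for n in self.nodes())

    def total_liquid(self) -> float:
        return sum(n.liquid() for n in self.nodes())

    def open_subgraph(self, valve_pressures: dict[str, float]) -> nx.Graph:
        """Subgraph of edges whose gating valve is open (or ungated)."""
        def is_open(d) -> bool:
            v = d["valve"]
            if v is None:
                return True
            p = valve_pressures.get(v, 0.0)
            return not valve_is_closed(
                MicrovalveState(v, p, self.close_threshold))
        return nx.subgraph_view(self.graph,
                                filter_edge=lambda a, b: is_open(
                                    self.graph.edges[a, b]))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "nodes": [{
                "id": n.id, "kind": n.kind, "capacity": n.capacity,
                "contents": dict(n.contents),
                "trapped_air_fraction": n.trapped_air_fraction,
            } for n in self.nodes()],
            "edges": [{
                "from": a, "to": b, "valve": d["valve"],
                "resistance": d["resistance"],
                "species_filter": d["species_filter"],
            } for a, b, d in self.graph.edges(data=True)],
            "analysis_units": {k: list(v)
                               for k, v in self.analysis_units.items()},
            "mixing_state": dict(self.mixing_state),
            "degas_tau": self.degas_tau,
            "exchange_fraction": self.exchange_fraction,
            "close_threshold": self.close_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChipModel":
        chip = cls(degas_tau=d.get("degas_tau", DEFAULT_DEGAS_TAU),
                   exchange_fraction=d.get("exchange_fraction",
                                           DEFAULT_EXCHANGE_FRACTION),
                   close_threshold=d.get("close_threshold",
                                         DEFAULT_CLOSE_THRESHOLD))
        for nd in d["nodes"]:
            chip.add_node(FluidNode(
                id=nd["id"], kind=nd["kind"], capacity=nd["capacity"],
                contents=dict(nd.get("contents", {})),
                trapped_air_fraction=nd.get("trapped_air_fraction", 0.0)))
        for ed in d["edges"]:
            chip.add_edge(ed["from"], ed["to"], valve=ed.get("valve"),
                          resistance=ed.get("resistance", DEFAULT_RESISTANCE),
                          species_filter=ed.get("species_filter"))
        for name, (s, r) in d.get("analysis_units", {}).items():
            chip.add_analysis_unit(name, s, r)
        for name, h in d.get("mixing_state", {}).items():
            chip.mixing_state[name] = h
        return chip

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "ChipModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def reachable(chip: ChipModel, valve_pressures: dict[str, float],
              a: str, b: str) -> bool:
    """True iff an undirected path of open edges joins ``a`` and ``b``."""
    chip.node(a), chip.node(b)  # raise on unknown ids
    return nx.has_path(chip.open_subgraph(valve_pressures), a, b)


def _edge_allowed(d: dict) -> tuple[str, ...]:
    """Species an edge will pass."""
    if d["species_filter"] == "plasma_only":
        return MEMBRANE_PASS
    return ("air",) + LIQUIDS


def _convey(chip: ChipModel, graph: nx.Graph, path: list[str],
            vol: float) -> None:
    """Advance up to ``vol`` nL along ``path`` (plug flow, sink last).

    Processed from the sink backwards so the same parcel cannot traverse
    more than one edge per call; each node releases its oldest movable
    parcels first (FIFO).
    """
    for i in range(len(path) - 2, -1, -1):
        src = chip.node(path[i])
        dst = chip.node(path[i + 1])
        edge = graph.edges[path[i], path[i + 1]]
        budget = min(vol, dst.free)
        if budget <= _VOL_TOL:
            continue
        for sp, amount in src.take(budget, _edge_allowed(edge)):
            dst.add(sp, amount)


def flow_update(chip: ChipModel, port_pressures: dict[str, float],
                valve_pressures: dict[str, float], dt: float) -> ChipModel:
    """Advance fluid along open paths between ports for ``dt`` seconds.

    For every pair of ports at different pressures connected through the
    open graph, a parcel Q*dt with Q = dP / sum(R) moves downstream,
    limited by upstream availability and downstream free capacity.
    Pressurized ports additionally dead-end-fill open chambers that still
    have free capacity (air escapes by compression/permeation, which is
    how degassing refills chambers).  Liquid volume is conserved exactly.
    """
    if dt <= 0:
        raise ChipError("dt must be > 0")
    if not port_pressures:
        return chip
    graph = chip.open_subgraph(valve_pressures)
    ports = sorted(port_pressures, key=lambda p: -port_pressures[p])
    for hi in ports:
        for lo in reversed(ports):
            dp = port_pressures[hi] - port_pressures[lo]
            if dp <= 0 or hi == lo:
                continue
            chip.node(hi), chip.node(lo)
            if not nx.has_path(graph, hi, lo):
                continue
            path = nx.shortest_path(graph, hi, lo, weight="resistance")
            rsum = sum(graph.edges[a, b]["resistance"]
                       for a, b in zip(path, path[1:]))
            _convey(chip, graph, path, dp / rsum * dt)
    # dead-end filling of chambers from pressurized ports
    for port in ports:
        p = port_pressures[port]
        if p <= 0:
            continue
        for node in chip.nodes():
            if node.kind != "chamber" or node.free <= _VOL_TOL:
                continue
            if not nx.has_path(graph, port, node.id):
                continue
            path = nx.shortest_path(graph, port, node.id, weight="resistance")
            rsum = sum(graph.edges[a, b]["resistance"]
                       for a, b in zip(path, path[1:]))
            _convey(chip, graph, path, p / rsum * dt)
    return chip


def degas_update(chip: ChipModel, pressure: float, dt: float) -> ChipModel:
    """First-order removal of trapped chamber air under positive pressure."""
    if pressure <= 0:
        raise ChipError("degas requires positive pressure")
    if dt < 0:
        raise ChipError("dt must be >= 0")
    if dt == 0:
        return chip
    decay = math.exp(-dt / chip.degas_tau)
    for node in chip.nodes():
        if node.kind != "chamber":
            continue
        for parcel in node.parcels:
            if parcel[0] == "air":
                parcel[1] *= decay
        node.parcels = [p for p in node.parcels if p[1] > _VOL_TOL]
    return chip


def mixing_update(chip: ChipModel, unit: str, cycles: int,
                  valve_pressures: dict[str, float] | None = None
                  ) -> ChipModel:
    """Apply ``cycles`` mixing cycles to one analysis unit.

    Homogeneity follows 1 - (1 - f)^cycles with per-cycle exchange
    fraction ``f``; batching is associative, so n1 + n2 cycles equal two
    consecutive updates.  When ``valve_pressures`` is supplied the unit
    must be sequestered from every other unit, otherwise a
    :class:`ContaminationError` is raised.
    """
    if unit not in chip.analysis_units:
        raise ChipError(f"unknown analysis unit {unit!r}")
    if cycles < 0:
        raise ChipError("cycles must be >= 0")
    if valve_pressures is not None:
        mine = chip.analysis_units[unit]
        for other, chambers in chip.analysis_units.items():
            if other == unit:
                continue
            for a in mine:
                for b in chambers:
                    if reachable(chip, valve_pressures, a, b):
                        raise ContaminationError(
                            f"unit {unit} reaches {other} ({a} - {b}); "
                            "sequester before mixing")
    h = chip.mixing_state[unit]
    f = chip.exchange_fraction
    chip.mixing_state[unit] = 1.0 - (1.0 - h) * (1.0 - f) ** cycles
    return chip


def load_blood(chip: ChipModel, volume_nl: float,
               hematocrit: float = 0.45, node: str = "psm") -> ChipModel:
    """Dispense whole blood onto the membrane node.

    The cellular fraction (``hematocrit``) stays at the membrane; only the
    plasma fraction can cross the plasma-only edge downstream.
    """
    if not 0.0 <= hematocrit < 1.0:
        raise ChipError("hematocrit must be in [0, 1)")
    n = chip.node(node)
    n.add("blood_cells", volume_nl * hematocrit)
    n.add("plasma", volume_nl * (1.0 - hematocrit))
    if n.total > n.capacity + _VOL_TOL:
        raise ChipError(f"blood volume exceeds {node} capacity")
    return chip


# ---------------------------------------------------------------------------
# Built-in topologies
# ---------------------------------------------------------------------------

def build_glucose_chip(*, n_units: int = 4, chamber_nl: float = 50.0,
                       collection_nl: float = 1000.0,
                       resistance: float = DEFAULT_RESISTANCE) -> ChipModel:
    """The two-module assay chip: PSM + collection channel feeding four
    analysis units (50 nL sample + 50 nL reagent chamber each).

    Valve convention (configurable; only V3/V4/V5 are fixed by the
    device's published roles):

    ======  =====================================================
    V1      PSM inlet and the collection->vacuum branch
    V2      all five outlets (four reagent outlets + chamber train)
    V3      collection -> sample-chamber train (mixing valve atop
            the sample chambers)
    V4      series links between neighbouring analysis units
    V5      sample/reagent separator within each unit
    V6      reagent and air inlets
    ======  =====================================================
    """
    chip = ChipModel()
    big = 1e6
    chip.add_node(FluidNode("psm", "membrane", 10000.0))
    chip.add_node(FluidNode("collection", "channel", collection_nl,
                            {"air": collection_nl}))
    chip.add_node(FluidNode("air_inlet", "inlet", big, {"air": big}))
    chip.add_node(FluidNode("reagent_inlet", "inlet", big,
                            {"reagent": 5000.0}))
    chip.add_node(FluidNode("vacuum_outlet", "outlet", big))
    chip.add_edge("psm", "collection", valve="V1", resistance=resistance,
                  species_filter="plasma_only")
    chip.add_edge("collection", "vacuum_outlet", valve="V1",
                  resistance=resistance)
    chip.add_edge("air_inlet", "collection", valve="V6",
                  resistance=resistance)
    prev = "collection"
    for i in range(1, n_units + 1):
        s, r, o = f"s{i}", f"r{i}", f"o{i}"
        chip.add_node(FluidNode(s, "chamber", chamber_nl,
                                {"air": chamber_nl},
                                trapped_air_fraction=CHAMBER_TRAPPED_FRACTION))
        chip.add_node(FluidNode(r, "chamber", chamber_nl,
                                {"air": chamber_nl},
                                trapped_air_fraction=CHAMBER_TRAPPED_FRACTION))
        chip.add_node(FluidNode(o, "outlet", big))
        chip.add_edge(prev, s, valve="V3" if i == 1 else "V4",
                      resistance=resistance)
        chip.add_edge(s, r, valve="V5", resistance=resistance)
        chip.add_edge("reagent_inlet", r, valve="V6", resistance=resistance)
        chip.add_edge(r, o, valve="V2", resistance=resistance)
        chip.add_analysis_unit(f"unit{i}", s, r)
        prev = s
    chip.add_edge(prev, "vacuum_outlet", valve="V2", resistance=resistance)
    return chip


def build_separation_chip(*, collection_nl: float = 1000.0,
                          resistance: float = DEFAULT_RESISTANCE
                          ) -> ChipModel:
    """The plasma-separation-only device: PSM, serpentine collection
    channel (holds up to 1 uL of plasma), an air inlet and one outlet.
    No microvalves; routing is purely by which port is pressurized."""
    chip = ChipModel()
    big = 1e6
    chip.add_node(FluidNode("psm", "membrane", 10000.0))
    chip.add_node(FluidNode("collection", "channel", collection_nl,
                            {"air": collection_nl}))
    chip.add_node(FluidNode("air_inlet", "inlet", big, {"air": big}))
    chip.add_node(FluidNode("vacuum_outlet", "outlet", big))
    chip.add_edge("psm", "collection", resistance=resistance,
                  species_filter="plasma_only")
    chip.add_edge("air_inlet", "collection", resistance=resistance)
    chip.add_edge("collection", "vacuum_outlet", resistance=resistance)
    return chip
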