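"""Synthetic coronary morphometry: diameter-defined Strahler networks.

Generates artery/capillary/vein networks ordered by the diameter-defined
Strahler convention (capillaries are order 0, arteries 1..11, veins -1..-12
with |order| increasing with diameter), with randomly placed Thebesian
shunts draining low-order nodes into a cardiac chamber, and registration
ports for equivalent microvascular networks.

The swine morphometric tables this surrogate stands in for are not publicly
deposited; the default :func:`default_order_table` is a reduced
equivalent-vessel calibration (see docs/methods.md), not anatomy.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .units import COMPL_TO_SI, MM_TO_M, UM_TO_M

GENERATOR_VERSION = "1.0"

ARTERY = "artery"
CAPILLARY = "capillary"
VEIN = "vein"
THEBESIAN = "thebesian"
SOURCE_LINE = "source_line"

#: vessel kinds with real geometry (diameter/length derived R and volume)
GEOMETRIC_KINDS = frozenset({ARTERY, CAPILLARY, VEIN, SOURCE_LINE})

MICRO_ORDER_MAX = 6  # embedded microvascular network spans orders -6..6


class MorphometryError(ValueError):
    """Invalid order table or network construction request."""


# ---------------------------------------------------------------------------
# order table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrderRow:
    """One Strahler order of the morphometric table.

    Parameters
    ----------
    order:
        Diameter-defined Strahler order; arteries 1..11, capillaries 0,
        veins -1..-12.
    count:
        Number of vessels of this order in the build.
    diameter_um, length_mm:
        Mean vessel dimensions.
    branching_ratio:
        Per-step count/compliance progression factor used by
        :func:`scale_rc` (dimensionless, > 0).
    """

    order: int
    count: int
    diameter_um: float
    length_mm: float
    branching_ratio: float = 1.6


def default_order_table() -> list[OrderRow]:
    """Reduced-scale default table spanning orders 11..-12.

    Counts sum to 296 geometric vessels; diameters are an equivalent-vessel
    compression of the anatomical range so that transit times through the
    reduced network fall on physiological washout timescales.
    """
    rows = [
        # arteries
        (11, 1, 600.0, 20.0), (10, 1, 480.0, 14.0), (9, 2, 380.0, 10.0),
        (8, 3, 300.0, 7.0), (7, 4, 230.0, 5.0), (6, 6, 170.0, 3.5),
        (5, 9, 120.0, 2.5), (4, 13, 90.0, 1.8), (3, 18, 65.0, 1.4),
        (2, 24, 45.0, 1.2), (1, 30, 30.0, 1.0),
        # capillaries
        (0, 64, 25.0, 0.5),
        # veins
        (-1, 36, 35.0, 1.0), (-2, 26, 50.0, 1.2), (-3, 18, 72.0, 1.4),
        (-4, 13, 100.0, 1.8), (-5, 9, 140.0, 2.5), (-6, 6, 190.0, 3.5),
        (-7, 4, 260.0, 5.0), (-8, 3, 330.0, 7.0), (-9, 2, 420.0, 10.0),
        (-10, 1, 520.0, 14.0), (-11, 1, 650.0, 18.0), (-12, 1, 800.0, 20.0),
    ]
    return [OrderRow(o, n, d, l) for o, n, d, l in rows]


def validate_order_table(table: Sequence[OrderRow]) -> dict[int, OrderRow]:
    """Check table invariants; return rows keyed by order.

    Raises :class:`MorphometryError` on duplicate orders, order-range gaps,
    a missing/empty capillary order, non-positive geometry, or diameters
    that fail to increase with |order| within arteries or within veins.
    """
    by_order: dict[int, OrderRow] = {}
    for row in table:
        if row.order in by_order:
            raise MorphometryError(f"duplicate order {row.order} in table")
        by_order[row.order] = row
    orders = sorted(by_order)
    lo, hi = orders[0], orders[-1]
    missing = [o for o in range(lo, hi + 1) if o not in by_order]
    if missing:
        raise MorphometryError(
            f"order table is not contiguous: missing order(s) {missing} "
            f"in range {lo}..{hi}"
        )
    if 0 not in by_order:
        raise MorphometryError("order table must include capillary order 0")
    if by_order[0].count < 1:
        raise MorphometryError("capillary order 0 has count 0 (no capillary bed)")
    for row in by_order.values():
        if row.count < 1:
            raise MorphometryError(f"order {row.order}: count must be >= 1")
        if row.diameter_um <= 0 or row.length_mm <= 0:
            raise MorphometryError(f"order {row.order}: non-positive geometry")
        if row.branching_ratio <= 0:
            raise MorphometryError(f"order {row.order}: branching_ratio must be > 0")
    for sign in (1, -1):
        seq = [by_order[o] for o in orders if o * sign >= 1]
        seq.sort(key=lambda r: abs(r.order))
        for a, b in zip(seq, seq[1:]):
            if b.diameter_um <= a.diameter_um:
                raise MorphometryError(
                    f"diameter must increase with |order|: order {b.order} "
                    f"({b.diameter_um} um) <= order {a.order} ({a.diameter_um} um)"
                )
    return by_order


def load_order_table(path) -> list[OrderRow]:
    """Read an order table from CSV (order,count,diameter_um,length_mm,branching_ratio)."""
    df = pd.read_csv(path)
    required = {"order", "count", "diameter_um", "length_mm", "branching_ratio"}
    missing = required - set(df.columns)
    if missing:
        raise MorphometryError(f"order table CSV missing columns {sorted(missing)}")
    rows = [
        OrderRow(int(r.order), int(r.count), float(r.diameter_um),
                 float(r.length_mm), float(r.branching_ratio))
        for r in df.itertuples()
    ]
    validate_order_table(rows)
    return rows


def save_order_table(table: Sequence[OrderRow], path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in table]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# resistance / compliance scaling
# ---------------------------------------------------------------------------

def poiseuille_resistance(diameter_um: float, length_mm: float,
                          viscosity: float) -> float:
    """Hagen-Poiseuille reference resistance 128*mu*L/(pi*D^4) in Pa.s/m3."""
    if diameter_um <= 0 or length_mm <= 0:
        raise MorphometryError("diameter and length must be positive")
    d = diameter_um * UM_TO_M
    length = length_mm * MM_TO_M
    return 128.0 * viscosity * length / (math.pi * d ** 4)


def scale_rc(order_table: Sequence[OrderRow], viscosity: float = 3.0e-3,
             c_total_order0_ml_per_mmhg: float = 5.0e-8,
             ) -> dict[int, tuple[float, float]]:
    """Per-order reference resistance and compliance assignments.

    Each vessel of an order gets the Poiseuille resistance of its mean
    geometry. Aggregate (parallel-combined) compliance per order follows the
    branching-ratio progression: anchored at the capillary order and
    multiplied by the row's branching ratio per order step away from it, so
    a ratio of 1 makes every order's aggregate compliance equal.

    Returns
    -------
    dict
        ``order -> (R0 [Pa.s/m3], C0 [m3/Pa])`` per vessel.
    """
    by_order = validate_order_table(order_table)
    c_anchor = c_total_order0_ml_per_mmhg * COMPL_TO_SI  # mL/mmHg -> m3/Pa

    out: dict[int, tuple[float, float]] = {}
    c_tot: dict[int, float] = {0: c_anchor}
    orders = sorted(by_order)
    for o in range(1, max(orders) + 1):
        c_tot[o] = c_tot[o - 1] * by_order[o].branching_ratio
    for o in range(-1, min(orders) - 1, -1):
        c_tot[o] = c_tot[o + 1] * by_order[o].branching_ratio
    for o, row in by_order.items():
        r0 = poiseuille_resistance(row.diameter_um, row.length_mm, viscosity)
        out[o] = (r0, c_tot[o] / row.count)
    return out


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Vessel:
    """One lumped vessel segment of the network graph."""

    id: str
    order: int | None
    diameter_um: float | None
    length_mm: float | None
    from_node: str
    to_node: str
    kind: str
    resistance: float | None = None  # Pa.s/m3; thebesian shunts only

    @property
    def area_m2(self) -> float:
        return math.pi * (self.diameter_um * UM_TO_M) ** 2 / 4.0

    @property
    def volume_m3(self) -> float:
        """Reference luminal volume (geometric kinds only)."""
        return self.area_m2 * self.length_mm * MM_TO_M


@dataclass(frozen=True)
class NetworkTopology:
    """Vessel graph with boundary ports, shunts and equivalent-network ports.

    ``nodes`` maps node id to role (interior, arterial_inlet, venous_outlet,
    chamber, equivalent_port_in, equivalent_port_out, femoral_source).
    ``tags`` records the scenario-relevant anatomy: the main (LAD-analog)
    artery, the distal great-cardiac-vein segment, the GCV junction node
    where the retroperfusion line attaches, and the chamber nodes.
    """

    nodes: dict[str, str]
    vessels: tuple[Vessel, ...]
    thebesian_shunts: tuple[str, ...]
    equivalent_port_pairs: tuple[tuple[str, str], ...]
    embedded_micro_region: frozenset[str]
    seed: int
    tags: dict[str, object] = field(default_factory=dict)

    # -- access helpers ----------------------------------------------------
    def vessel(self, vessel_id: str) -> Vessel:
        try:
            return self._by_id[vessel_id]
        except KeyError:
            raise KeyError(f"no vessel with id {vessel_id!r}") from None

    @property
    def _by_id(self) -> dict[str, Vessel]:
        cached = object.__getattribute__(self, "__dict__").get("_by_id_cache")
        if cached is None:
            cached = {v.id: v for v in self.vessels}
            object.__getattribute__(self, "__dict__")["_by_id_cache"] = cached
        return cached

    def incident(self) -> dict[str, list[Vessel]]:
        """node id -> incident vessels (all kinds)."""
        inc: dict[str, list[Vessel]] = {n: [] for n in self.nodes}
        for v in self.vessels:
            inc[v.from_node].append(v)
            inc[v.to_node].append(v)
        return inc

    def vessels_of_order(self, order: int) -> list[Vessel]:
        return [v for v in self.vessels if v.order == order]

    @property
    def n_vessels(self) -> int:
        return len(self.vessels)

    def ischemic_region(self) -> frozenset[str]:
        """Vessels of the embedded microvascular network (the territory
        distal to the occluded main artery in occlusion scenarios)."""
        return self.embedded_micro_region

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        roles = set(self.nodes.values())
        if "arterial_inlet" not in roles or "venous_outlet" not in roles:
            raise MorphometryError("network must have an arterial inlet and a venous outlet")
        for v in self.vessels:
            if v.from_node not in self.nodes or v.to_node not in self.nodes:
                raise MorphometryError(f"vessel {v.id}: endpoint not in node set")
            if v.kind in GEOMETRIC_KINDS:
                if not (v.diameter_um and v.diameter_um > 0 and v.length_mm
                        and v.length_mm > 0):
                    raise MorphometryError(f"vessel {v.id}: non-positive geometry")
            if v.kind == ARTERY and not (v.order is not None and v.order >= 1):
                raise MorphometryError(f"vessel {v.id}: artery must have order >= 1")
            if v.kind == CAPILLARY and v.order != 0:
                raise MorphometryError(f"vessel {v.id}: capillary must have order 0")
            if v.kind == VEIN and not (v.order is not None and v.order <= -1):
                raise MorphometryError(f"vessel {v.id}: vein must have order <= -1")
            if v.kind == THEBESIAN and (v.resistance is None or v.resistance <= 0):
                raise MorphometryError(f"vessel {v.id}: thebesian shunt needs resistance > 0")
        for vid in self.embedded_micro_region:
            o = self.vessel(vid).order
            if o is None or abs(o) > MICRO_ORDER_MAX:
                raise MorphometryError(
                    f"embedded micro region contains vessel {vid} of order {o}")
        self._check_connectivity()
        self._check_order_monotonicity()

    def _tree_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for v in self.vessels:
            if v.kind in (ARTERY, CAPILLARY, VEIN):
                g.add_edge(v.from_node, v.to_node, vessel=v.id)
        return g

    def _check_connectivity(self) -> None:
        g = self._tree_digraph()
        inlets = [n for n, r in self.nodes.items() if r == "arterial_inlet"]
        outlets = [n for n, r in self.nodes.items() if r == "venous_outlet"]
        reachable: set[str] = set()
        for n in inlets:
            reachable |= {n} | nx.descendants(g, n)
        co_reachable: set[str] = set()
        rg = g.reverse(copy=False)
        for n in outlets:
            co_reachable |= {n} | nx.descendants(rg, n)
        on_path = reachable & co_reachable
        for v in self.vessels:
            if v.kind in (ARTERY, CAPILLARY, VEIN):
                if v.from_node not in on_path or v.to_node not in on_path:
                    raise MorphometryError(
                        f"vessel {v.id} is not on any inlet->outlet path")

    def _check_order_monotonicity(self) -> None:
        # local check at every shared node of the tree; implies the path
        # property because arteries/veins form trees
        for v in self.vessels:
            if v.kind != ARTERY:
                continue
            for w in self.vessels:
                if w.kind == ARTERY and w.from_node == v.to_node and w.order > v.order:
                    raise MorphometryError(
                        f"arterial order increases downstream: {v.id} -> {w.id}")
        for v in self.vessels:
            if v.kind != VEIN:
                continue
            for w in self.vessels:
                if w.kind == VEIN and w.from_node == v.to_node and abs(w.order) < abs(v.order):
                    raise MorphometryError(
                        f"venous |order| decreases downstream: {v.id} -> {w.id}")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "meta": {"seed": self.seed, "generator_version": GENERATOR_VERSION},
            "nodes": [{"id": n, "role": r} for n, r in sorted(self.nodes.items())],
            "vessels": [
                {"id": v.id, "order": v.order, "diameter_um": v.diameter_um,
                 "length_mm": v.length_mm, "from": v.from_node, "to": v.to_node,
                 "kind": v.kind, "resistance": v.resistance}
                for v in sorted(self.vessels, key=lambda v: v.id)
            ],
            "shunts": sorted(self.thebesian_shunts),
            "equivalent_ports": [list(p) for p in self.equivalent_port_pairs],
            "embedded_micro_region": sorted(self.embedded_micro_region),
            "tags": self.tags,
        }

    def canonical_json(self) -> bytes:
        return json.dumps(self.to_dict(), sort_keys=True,
                          separators=(",", ":")).encode()

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkTopology":
        vessels = tuple(
            Vessel(id=v["id"], order=v["order"], diameter_um=v["diameter_um"],
                   length_mm=v["length_mm"], from_node=v["from"], to_node=v["to"],
                   kind=v["kind"], resistance=v.get("resistance"))
            for v in d["vessels"]
        )
        tags = dict(d.get("tags", {}))
        if "gcv_proximal" in tags:
            tags["gcv_proximal"] = list(tags["gcv_proximal"])
        return cls(
            nodes={n["id"]: n["role"] for n in d["nodes"]},
            vessels=vessels,
            thebesian_shunts=tuple(d.get("shunts", ())),
            equivalent_port_pairs=tuple(tuple(p) for p in d.get("equivalent_ports", ())),
            embedded_micro_region=frozenset(d.get("embedded_micro_region", ())),
            seed=int(d["meta"]["seed"]),
            tags=tags,
        )

    @classmethod
    def load(cls, path) -> "NetworkTopology":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_network(order_table: Sequence[OrderRow], seed: int,
                     *, with_source_line: bool = True) -> NetworkTopology:
    """Build the base artery-capillary-vein tree from an order table.

    Arteries branch from a single inlet down to order 1; each order-1
    arteriole feeds at least two capillaries; capillaries drain into order
    -1 venules which merge with non-decreasing |order| to the venous outlet
    (the coronary sinus). A retroperfusion source line is attached at the
    junction proximal to the largest vein (the GCV-analog), and chamber
    nodes are created for later Thebesian shunt placement.

    Identical ``(order_table, seed)`` give a byte-identical topology.
    """
    by_order = validate_order_table(order_table)
    orders = sorted(by_order)
    art_orders = [o for o in orders if o >= 1]
    vein_orders = [o for o in orders if o <= -1]
    if not art_orders or not vein_orders:
        raise MorphometryError("table must include at least one arterial and one venous order")
    # connectivity requires counts non-decreasing toward the capillaries
    for hi, lo in zip(sorted(art_orders, reverse=True),
                      sorted(art_orders, reverse=True)[1:]):
        if by_order[lo].count < by_order[hi].count:
            raise MorphometryError(
                f"count must not decrease toward order 1 (order {lo} < order {hi})")
    for hi, lo in zip(sorted(vein_orders), sorted(vein_orders)[1:]):
        if by_order[lo].count < by_order[hi].count:
            raise MorphometryError(
                f"count must not decrease toward order -1 (order {lo} < order {hi})")
    n1, n0, nm1 = by_order[art_orders[0]].count, by_order[0].count, by_order[vein_orders[-1]].count
    if n0 < 2 * n1:
        raise MorphometryError(
            f"capillary count ({n0}) must be >= 2 x order-1 count ({n1}) "
            "so each order-1 arteriole feeds at least two capillaries")
    if n0 < nm1:
        raise MorphometryError(
            f"capillary count ({n0}) must be >= order -1 count ({nm1})")

    rng = np.random.default_rng(seed)
    nodes: dict[str, str] = {"inlet": "arterial_inlet", "sinus": "venous_outlet",
                             "chamber_LA": "chamber", "chamber_LV": "chamber"}
    vessels: list[Vessel] = []

    def vid(kind_char: str, order: int, i: int) -> str:
        return f"{kind_char}{order:+03d}_{i:03d}"

    # arterial tree: top order from inlet, children round-robin on parents
    distal: dict[int, list[str]] = {}  # order -> distal node per vessel
    for k, o in enumerate(sorted(art_orders, reverse=True)):
        row = by_order[o]
        ids = [vid("A", o, i) for i in range(row.count)]
        if k == 0:
            parents = ["inlet"] * row.count
        else:
            pd_nodes = distal[sorted(art_orders, reverse=True)[k - 1]]
            perm = rng.permutation(row.count)
            parents = [pd_nodes[int(perm[i]) % len(pd_nodes)] for i in range(row.count)]
        distal[o] = []
        for i, v_id in enumerate(ids):
            to = f"n_{v_id}"
            nodes[to] = "interior"
            vessels.append(Vessel(v_id, o, row.diameter_um, row.length_mm,
                                  parents[i], to, ARTERY))
            distal[o].append(to)

    # venous tree mirrored: build from the outlet inward so parents exist
    vein_sorted = sorted(vein_orders)  # -12 .. -1
    proximal: dict[int, list[str]] = {}  # order -> from-node per vessel
    for k, o in enumerate(vein_sorted):
        row = by_order[o]
        ids = [vid("V", o, i) for i in range(row.count)]
        if k == 0:
            targets = ["sinus"] * row.count
        else:
            parent_nodes = proximal[vein_sorted[k - 1]]
            perm = rng.permutation(row.count)
            targets = [parent_nodes[int(perm[i]) % len(parent_nodes)]
                       for i in range(row.count)]
        proximal[o] = []
        for i, v_id in enumerate(ids):
            frm = f"n_{v_id}"
            nodes[frm] = "interior"
            vessels.append(Vessel(v_id, o, row.diameter_um, row.length_mm,
                                  frm, targets[i], VEIN))
            proximal[o].append(frm)

    # capillaries: each order-1 arteriole feeds >= 2; each -1 venule drains >= 1
    row0 = by_order[0]
    art1 = distal[art_orders[0]]
    ven1 = proximal[vein_orders[-1]]
    cap_parents = [art1[i % len(art1)] for i in range(row0.count)]
    perm = rng.permutation(row0.count)
    cap_targets = [ven1[int(perm[i]) % len(ven1)] for i in range(row0.count)]
    for i in range(row0.count):
        vessels.append(Vessel(vid("C", 0, i), 0, row0.diameter_um, row0.length_mm,
                              cap_parents[i], cap_targets[i], CAPILLARY))

    # anatomy tags
    lad_main = vid("A", art_orders[-1], 0)
    gcv_order = vein_sorted[0]
    gcv_distal = vid("V", gcv_order, 0)
    gcv_junction = proximal[gcv_order][0]
    gcv_proximal = [v.id for v in vessels
                    if v.kind == VEIN and v.to_node == gcv_junction]
    tags: dict[str, object] = {
        "lad_main": lad_main, "gcv_distal": gcv_distal,
        "gcv_junction": gcv_junction, "gcv_proximal": gcv_proximal,
        "chambers": {"LA": "chamber_LA", "LV": "chamber_LV"},
    }

    if with_source_line:
        # short terminal segment of the retroperfusion line: the prescribed
        # femoral pressure is defined directly proximal to the GCV, so the
        # line adds negligible resistance and volume
        nodes["femoral"] = "femoral_source"
        vessels.append(Vessel("SRC_000", None, 2000.0, 10.0,
                              "femoral", gcv_junction, SOURCE_LINE))
        tags["source_line"] = "SRC_000"
        tags["femoral_source"] = "femoral"

    micro = frozenset(v.id for v in vessels
                      if v.order is not None and abs(v.order) <= MICRO_ORDER_MAX)

    net = NetworkTopology(
        nodes=nodes, vessels=tuple(vessels), thebesian_shunts=(),
        equivalent_port_pairs=(), embedded_micro_region=micro,
        seed=int(seed), tags=tags,
    )
    net.validate()
    return net


def place_thebesian_shunts(network: NetworkTopology, n_shunts: int,
                           shunt_resistance: float, seed: int,
                           *, order_limit: int = 3,
                           chamber: str = "LA") -> NetworkTopology:
    """Add ``n_shunts`` Thebesian shunt vessels at random eligible nodes.

    Eligible nodes are interior nodes all of whose incident geometric
    vessels have |order| <= ``order_limit`` (the arteriole/venule
    neighbourhood). Each shunt connects one such node to the configured
    chamber node with the given lumped resistance (Pa.s/m3). Placement is
    reproducible under a fixed seed; nodes are drawn without replacement.
    """
    if n_shunts < 0:
        raise MorphometryError("n_shunts must be >= 0")
    if n_shunts == 0:
        return network
    chambers = network.tags.get("chambers", {})
    if chamber not in chambers:
        raise MorphometryError(f"no chamber node tagged {chamber!r}")
    chamber_node = chambers[chamber]
    eligible = eligible_thebesian_nodes(network, order_limit)
    if n_shunts > len(eligible):
        raise MorphometryError(
            f"n_shunts ({n_shunts}) exceeds eligible node count ({len(eligible)})")
    rng = np.random.default_rng(seed)
    chosen = [eligible[i] for i in rng.choice(len(eligible), size=n_shunts,
                                              replace=False)]
    shunts = [
        Vessel(f"T_{i:03d}", None, None, None, node, chamber_node, THEBESIAN,
               resistance=float(shunt_resistance))
        for i, node in enumerate(chosen)
    ]
    net = replace(
        network,
        vessels=network.vessels + tuple(shunts),
        thebesian_shunts=network.thebesian_shunts + tuple(s.id for s in shunts),
    )
    net.validate()
    return net


def eligible_thebesian_nodes(network: NetworkTopology,
                             order_limit: int = 3) -> list[str]:
    """Interior nodes whose incident geometric vessels all have |order| <= limit."""
    inc = network.incident()
    out = []
    for node, role in sorted(network.nodes.items()):
        if role != "interior":
            continue
        orders = [abs(v.order) for v in inc[node]
                  if v.kind in (ARTERY, CAPILLARY, VEIN)]
        if orders and max(orders) <= order_limit:
            out.append(node)
    return out


def attach_equivalent_networks(network: NetworkTopology,
                               n_equivalent: int) -> NetworkTopology:
    """Register ``n_equivalent`` equivalent microvascular network port pairs.

    Each pair (P_i, P_o) marks where one copy of the embedded microvascular
    network sees the embedded network's entry and exit pressures. Entry
    nodes are the feeding nodes of the highest-order micro arteries; exit
    nodes are the collecting nodes of the deepest micro veins; copies are
    distributed round-robin when several such nodes exist. The hemodynamic
    assembly realizes each pair as a lumped surrogate carrying the embedded
    network's aggregate resistance, compliance and volume, so identical
    copies multiply total microvascular flow by (1 + n_equivalent).
    """
    if n_equivalent < 0:
        raise MorphometryError("n_equivalent must be >= 0")
    if not network.embedded_micro_region:
        raise MorphometryError("embedded micro region is empty")
    if n_equivalent == 0:
        return network
    micro_orders = [network.vessel(v).order for v in network.embedded_micro_region]
    top_a = max(o for o in micro_orders if o >= 0)
    top_v = min(o for o in micro_orders if o <= 0)
    entries = sorted({v.from_node for v in network.vessels if v.order == top_a})
    exits = sorted({v.to_node for v in network.vessels if v.order == top_v})
    pairs = tuple((entries[i % len(entries)], exits[i % len(exits)])
                  for i in range(n_equivalent))
    nodes = dict(network.nodes)
    for p_i, p_o in pairs:
        if nodes[p_i] == "interior":
            nodes[p_i] = "equivalent_port_in"
        if nodes[p_o] == "interior":
            nodes[p_o] = "equivalent_port_out"
    return replace(network, nodes=nodes,
                   equivalent_port_pairs=network.equivalent_port_pairs + pairs)


def build_default_network(seed: int = 0, *,
                          order_table: Sequence[OrderRow] | None = None,
                          n_shunts: int = 10,
                          shunt_resistance: float | None = None,
                          n_equivalent: int = 15,
                          thebesian_order_limit: int = 3,
                          thebesian_chamber: str = "LA",
                          viscosity: float = 3.0e-3) -> NetworkTopology:
    """One-shot default build: tree + Thebesian shunts + equivalent ports.

    The default shunt resistance is 5x the reference resistance of an
    order -1 venule, per the package's surrogate parameterization.
    """
    table = list(order_table) if order_table is not None else default_order_table()
    net = generate_network(table, seed)
    if shunt_resistance is None:
        rc = scale_rc(table, viscosity)
        vein_orders = [o for o in rc if o <= -1]
        shunt_resistance = 5.0 * rc[max(vein_orders)][0]
    net = place_thebesian_shunts(net, n_shunts, shunt_resistance, seed + 1,
                                 order_limit=thebesian_order_limit,
                                 chamber=thebesian_chamber)
    net = attach_equivalent_networks(net, n_equivalent)
    return net
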