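"""Closed-loop nonlinear lumped-parameter coronary hemodynamics.

Every vessel is a 0D element: two resistive halves around a compliant
midpoint that stores volume. Resistance follows a pressure-distension law
(distension lowers resistance as D^-4), the stored volume maps back to
transmural pressure through a linear compliance with a stiff collapse
floor, and microvascular elements feel a fraction of left-ventricular
pressure as external (intramyocardial) pressure. The left ventricle and
atrium are time-varying elastance chambers; a linear two-compartment
periphery closes the loop aorta -> systemic bed -> venous return -> LA ->
LV -> aorta. Scenario boundary conditions (vessel occlusion, pulsatile
retroperfusion pressure at the great cardiac vein) are imposed without
changing the state dimension.

Internal computations are SI; the public surface is mmHg / mL / s.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.integrate import solve_ivp

from . import morphometry as mm
from .units import M3_TO_ML, MMHG_TO_PA, PA_TO_MMHG, RU_TO_SI

OCCLUSION_FACTOR = 1e-12  # conductance multiplier for occluded vessels
COLLAPSE_FLOOR_FRAC = 0.25  # volume floor as fraction of reference volume
COLLAPSE_SOFTNESS = 0.01  # compliance multiplier below the floor
DISTENSION_CLAMP = (0.5, 2.0)  # bounds on the diameter distension factor


class HemodynamicsError(ValueError):
    """Invalid model composition or scenario."""


class SolverError(RuntimeError):
    """Time integration failure."""


# ---------------------------------------------------------------------------
# elements
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VesselElement:
    """Lumped R/C description of one vessel.

    R0 is the reference resistance (Pa.s/m3) at reference transmural
    pressure ``pref_mmhg``; C0 the reference compliance (m3/Pa, 0 for a
    rigid element); ``beta`` the dimensionless distension exponent of the
    diameter law D = Dref*(1 + beta*(Ptm-Pref)/Pref); ``imp_weight`` the
    fraction of LV pressure applied as external pressure; ``vref_m3`` the
    luminal volume at reference pressure (used for state initialization
    and tracer transit).
    """

    vessel_id: str
    R0: float
    C0: float
    beta: float = 0.0
    imp_weight: float = 0.0
    pref_mmhg: float = 45.0
    vref_m3: float = 0.0

    def __post_init__(self):
        if self.R0 <= 0:
            raise HemodynamicsError(f"{self.vessel_id}: R0 must be > 0")
        if self.C0 < 0:
            raise HemodynamicsError(f"{self.vessel_id}: C0 must be >= 0")
        if not (0.0 <= self.imp_weight <= 1.0):
            raise HemodynamicsError(f"{self.vessel_id}: imp_weight must be in [0,1]")


def element_resistance(element: VesselElement,
                       transmural_pressure_mmhg: float) -> float:
    """Resistance (Pa.s/m3) at the given transmural pressure.

    Anchored at R0 for Ptm = Pref; distension (higher Ptm) lowers
    resistance via the fourth-power diameter law; the distension factor is
    clamped to avoid collapse singularities, so the result is always
    positive and monotonically non-increasing in Ptm.
    """
    pref = element.pref_mmhg
    fac = 1.0 + element.beta * (transmural_pressure_mmhg - pref) / pref
    fac = min(max(fac, DISTENSION_CLAMP[0]), DISTENSION_CLAMP[1])
    return element.R0 / fac ** 4


def imp_weight_for_order(order: int | None, peak: float = 0.75,
                         zero_at: int = 7) -> float:
    """Intramyocardial-pressure coupling: ``peak`` at the capillaries,
    tapering linearly to 0 at |order| >= ``zero_at``."""
    if order is None:
        return 0.0
    return peak * max(0.0, 1.0 - abs(order) / zero_at)


def build_elements(network: mm.NetworkTopology,
                   order_table: Sequence[mm.OrderRow] | None = None,
                   *, viscosity: float = 3.0e-3, beta: float = 0.2,
                   pref_mmhg: float = 45.0,
                   c_total_order0_ml_per_mmhg: float = 5.0e-8,
                   imp_peak: float = 0.75,
                   imp_zero_order: int = 7) -> dict[str, VesselElement]:
    """Element map for every vessel of a generated network.

    Geometric vessels get order-scaled R0/C0 from :func:`morphometry.scale_rc`;
    the source line gets its Poiseuille resistance and no compliance;
    Thebesian shunts carry their configured lumped resistance.
    """
    table = list(order_table) if order_table is not None else mm.default_order_table()
    rc = mm.scale_rc(table, viscosity, c_total_order0_ml_per_mmhg)
    out: dict[str, VesselElement] = {}
    for v in network.vessels:
        if v.kind == mm.THEBESIAN:
            out[v.id] = VesselElement(v.id, R0=v.resistance, C0=0.0)
        elif v.kind == mm.SOURCE_LINE:
            r0 = mm.poiseuille_resistance(v.diameter_um, v.length_mm, viscosity)
            out[v.id] = VesselElement(v.id, R0=r0, C0=0.0, vref_m3=v.volume_m3)
        else:
            r0, c0 = rc[v.order]
            out[v.id] = VesselElement(
                v.id, R0=r0, C0=c0, beta=beta,
                imp_weight=imp_weight_for_order(v.order, imp_peak, imp_zero_order),
                pref_mmhg=pref_mmhg, vref_m3=v.volume_m3)
    return out


def effective_region_resistance(network: mm.NetworkTopology,
                                elements: Mapping[str, VesselElement],
                                region: frozenset[str] | None = None,
                                ) -> tuple[float, float, float, float]:
    """Aggregate (R, C, V, imp_weight) of the embedded micro network.

    Effective resistance between the region's entry nodes (feeding the
    highest-order micro arteries) and exit nodes (collecting the deepest
    micro veins), computed at reference state by a sparse Laplacian solve
    with the entry set held at unit pressure and the exit set grounded.
    """
    region = region if region is not None else network.embedded_micro_region
    if not region:
        raise HemodynamicsError("embedded micro region is empty")
    vessels = [network.vessel(vid) for vid in sorted(region)]
    orders = [v.order for v in vessels]
    top_a = max(o for o in orders if o >= 0)
    top_v = min(o for o in orders if o <= 0)
    entries = {v.from_node for v in vessels if v.order == top_a}
    exits = {v.to_node for v in vessels if v.order == top_v}
    nodes = sorted({v.from_node for v in vessels} | {v.to_node for v in vessels})
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    lap = sp.lil_matrix((n, n))
    for v in vessels:
        g = 1.0 / elements[v.id].R0
        a, b = idx[v.from_node], idx[v.to_node]
        lap[a, a] += g
        lap[b, b] += g
        lap[a, b] -= g
        lap[b, a] -= g
    fixed = {idx[e]: 1.0 for e in entries}
    fixed.update({idx[e]: 0.0 for e in exits})
    free = [i for i in range(n) if i not in fixed]
    lap = lap.tocsr()
    rhs = np.zeros(n)
    for i, p in fixed.items():
        rhs -= lap[:, i].toarray().ravel() * p
    p_all = np.zeros(n)
    for i, p in fixed.items():
        p_all[i] = p
    if free:
        sub = lap[np.ix_(free, free)]
        p_all[free] = spla.spsolve(sp.csr_matrix(sub), rhs[free])
    # current out of the entry set
    q = 0.0
    for v in vessels:
        g = 1.0 / elements[v.id].R0
        if v.from_node in entries and v.to_node not in entries:
            q += g * (p_all[idx[v.from_node]] - p_all[idx[v.to_node]])
        elif v.to_node in entries and v.from_node not in entries:
            q -= g * (p_all[idx[v.to_node]] - p_all[idx[v.from_node]])
    if q <= 0:
        raise HemodynamicsError("embedded region has no entry->exit conductance")
    c_tot = sum(elements[v.id].C0 for v in vessels)
    v_tot = sum(elements[v.id].vref_m3 for v in vessels)
    if v_tot > 0:
        w = sum(elements[v.id].imp_weight * elements[v.id].vref_m3
                for v in vessels) / v_tot
    else:
        w = 0.0
    return 1.0 / q, c_tot, v_tot, w


# ---------------------------------------------------------------------------
# heart and periphery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChamberParams:
    """Time-varying elastance chamber: P = E(t) * (V - V0).

    ``onset`` and ``duration`` are fractions of the heart period; the
    activation shape is the raised cosine 0.5*(1 - cos(2*pi*phase/duration)),
    which is periodic with a continuous first derivative.
    """

    E_max: float  # mmHg/mL
    E_min: float  # mmHg/mL
    V0: float     # mL
    onset: float = 0.0
    duration: float = 0.45

    def __post_init__(self):
        if not (self.E_max >= self.E_min > 0):
            raise HemodynamicsError("need E_max >= E_min > 0")
        if not (0 < self.duration <= 1):
            raise HemodynamicsError("activation duration must be in (0, 1]")


@dataclass(frozen=True)
class HeartModel:
    period: float = 0.6  # s; ~100 bpm swine heart rate
    lv: ChamberParams = field(default_factory=lambda: ChamberParams(
        E_max=2.0, E_min=0.06, V0=10.0, onset=0.0, duration=0.45))
    la: ChamberParams = field(default_factory=lambda: ChamberParams(
        E_max=0.25, E_min=0.12, V0=5.0, onset=0.80, duration=0.35))

    def __post_init__(self):
        if self.period <= 0:
            raise HemodynamicsError("heart period must be > 0")


def elastance(t: float | np.ndarray, chamber: ChamberParams,
              period: float) -> float | np.ndarray:
    """Chamber elastance E(t) in mmHg/mL (periodic, smooth)."""
    if period <= 0:
        raise HemodynamicsError("period must be > 0")
    if np.any(np.asarray(t) < 0):
        raise HemodynamicsError("t must be >= 0")
    phase = np.mod(t / period - chamber.onset, 1.0)
    act = np.where(phase < chamber.duration,
                   0.5 * (1.0 - np.cos(2.0 * np.pi * phase /
                                       max(chamber.duration, 1e-12))),
                   0.0)
    out = chamber.E_min + (chamber.E_max - chamber.E_min) * act
    return float(out) if np.isscalar(t) else out


@dataclass(frozen=True)
class PeripheralModel:
    """Linear lumped periphery closing the loop (mmHg.s/mL, mL/mmHg, mL)."""

    R_av: float = 0.010   # aortic valve (open)
    R_mv: float = 0.008   # mitral valve (open)
    R_sys: float = 1.2    # systemic bed
    R_ven: float = 0.05   # venous return
    C_as: float = 1.5     # systemic arterial compliance
    C_vs: float = 60.0    # systemic venous compliance
    V_as0: float = 300.0  # unstressed volumes
    V_vs0: float = 2500.0
    valve_softness_mmhg: float = 0.25
    valve_leak: float = 1e-9  # closed/open conductance ratio

    def __post_init__(self):
        for name in ("R_av", "R_mv", "R_sys", "R_ven", "C_as", "C_vs"):
            if getattr(self, name) <= 0:
                raise HemodynamicsError(f"peripheral {name} must be > 0")


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GcvSource:
    """Prescribed pulsatile pressure proximal to the great cardiac vein."""

    mean_mmhg: float
    pulse_mmhg: float = 30.0
    waveform: str = "sin"
    period: float | None = None  # default: heart period

    def pressure_pa(self, t: np.ndarray | float, period: float) -> np.ndarray | float:
        T = self.period if self.period is not None else period
        if self.waveform == "sin":
            p = self.mean_mmhg + 0.5 * self.pulse_mmhg * np.sin(
                2.0 * np.pi * np.asarray(t) / T)
        elif self.waveform == "constant":
            p = self.mean_mmhg + 0.0 * np.asarray(t)
        else:
            raise HemodynamicsError(f"unknown waveform {self.waveform!r}")
        return p * MMHG_TO_PA


@dataclass(frozen=True)
class Scenario:
    """Boundary-condition bundle for one simulated condition.

    sarp_b: main artery and distal GCV occluded, pulsatile femoral pressure
    at the GCV-proximal node (balloon inflated). sarp_nb: same source but
    the distal GCV stays open. occlusion_only: arterial occlusion without
    retroperfusion. baseline: nothing occluded, no source.
    """

    name: str
    occluded_vessels: tuple[str, ...] = ()
    gcv_source: GcvSource | None = None
    distal_gcv_occluded: bool = False

    def __post_init__(self):
        if self.name in ("sarp_b", "sarp_nb") and self.gcv_source is None:
            raise HemodynamicsError(f"{self.name} requires a gcv_source")
        if self.name in ("baseline", "occlusion_only") and self.gcv_source is not None:
            raise HemodynamicsError(f"{self.name} must not have a gcv_source")
        if self.name == "sarp_b" and not self.distal_gcv_occluded:
            raise HemodynamicsError("sarp_b requires distal_gcv_occluded")
        if self.name == "sarp_nb" and self.distal_gcv_occluded:
            raise HemodynamicsError("sarp_nb requires the distal GCV open")

    @classmethod
    def baseline(cls) -> "Scenario":
        return cls("baseline")

    @classmethod
    def occlusion_only(cls) -> "Scenario":
        return cls("occlusion_only")

    @classmethod
    def sarp_b(cls, mean_mmhg: float = 63.9, pulse_mmhg: float = 30.0) -> "Scenario":
        return cls("sarp_b", gcv_source=GcvSource(mean_mmhg, pulse_mmhg),
                   distal_gcv_occluded=True)

    @classmethod
    def sarp_nb(cls, mean_mmhg: float = 39.2, pulse_mmhg: float = 30.0) -> "Scenario":
        return cls("sarp_nb", gcv_source=GcvSource(mean_mmhg, pulse_mmhg),
                   distal_gcv_occluded=False)

    @classmethod
    def by_name(cls, name: str, **kwargs) -> "Scenario":
        factories = {"baseline": cls.baseline, "occlusion_only": cls.occlusion_only,
                     "sarp_b": cls.sarp_b, "sarp_nb": cls.sarp_nb}
        if name not in factories:
            raise HemodynamicsError(f"unknown scenario {name!r}")
        return factories[name](**kwargs)


@dataclass(frozen=True)
class ScenarioBundle:
    """Scenario resolved against a concrete network."""

    scenario: Scenario
    occluded_ids: tuple[str, ...]
    source_pressure: Callable | None  # t [s] -> Pa at the femoral node


def apply_scenario(network: mm.NetworkTopology, scenario: Scenario,
                   heart_period: float = 0.6) -> ScenarioBundle:
    """Resolve a scenario to concrete occluded vessel ids and source waveform.

    In occlusion and SARP scenarios the main (largest-order, LAD-analog)
    artery is occluded; sarp_b additionally occludes the distal GCV. The
    retroperfusion line is itself treated as occluded whenever no source is
    prescribed, so the network keeps one state dimension across scenarios.
    """
    occluded = set(scenario.occluded_vessels)
    tags = network.tags
    if scenario.name in ("occlusion_only", "sarp_b", "sarp_nb"):
        if "lad_main" not in tags:
            raise HemodynamicsError("network has no tagged main artery (lad_main)")
        occluded.add(tags["lad_main"])
    if scenario.gcv_source is not None or scenario.distal_gcv_occluded:
        if "gcv_distal" not in tags or "source_line" not in tags:
            raise HemodynamicsError(
                "SARP scenario on a network lacking a tagged GCV path / source line")
    if scenario.distal_gcv_occluded:
        occluded.add(tags["gcv_distal"])
    source_fn = None
    if scenario.gcv_source is not None:
        src = scenario.gcv_source
        source_fn = lambda t, _s=src, _T=heart_period: _s.pressure_pa(t, _T)
    elif "source_line" in tags:
        occluded.add(tags["source_line"])
    for vid in occluded:
        network.vessel(vid)  # raises KeyError with the offending id
    return ScenarioBundle(scenario, tuple(sorted(occluded)), source_fn)


# ---------------------------------------------------------------------------
# system assembly
# ---------------------------------------------------------------------------

@dataclass
class SimVessel:
    """Vessel record as simulated (network vessels + equivalent-network lumps)."""

    id: str
    from_node: str
    to_node: str
    kind: str
    element: VesselElement


class System:
    """Assembled state-space system: d(volumes)/dt with algebraic junction
    pressures. Built by :func:`assemble_system`; integrated by :func:`solve`."""

    def __init__(self, network, sim_vessels, heart, periphery, bundle,
                 boundary_pressures, occlusion_factor):
        self.network = network
        self.sim_vessels: list[SimVessel] = sim_vessels
        self.heart = heart
        self.periphery = periphery
        self.bundle = bundle
        self.occlusion_factor = occlusion_factor
        self._build_index(boundary_pressures)

    # -- index construction -------------------------------------------------
    def _build_index(self, boundary_pressures):
        net = self.network
        bp = dict(boundary_pressures or {})
        known: dict[str, tuple[str, object]] = {}
        for node, role in net.nodes.items():
            if node in bp:
                val = bp[node]
                if callable(val):
                    known[node] = ("func", lambda t, _f=val: float(_f(t)) * MMHG_TO_PA)
                else:
                    known[node] = ("fixed", float(val) * MMHG_TO_PA)
            elif role == "arterial_inlet":
                if self.periphery is not None:
                    known[node] = ("as", None)
                else:
                    raise HemodynamicsError(
                        f"no pressure for arterial inlet {node!r}: provide a "
                        "periphery or a boundary_pressures entry")
            elif role == "venous_outlet":
                if self.periphery is not None:
                    known[node] = ("vs", None)
                else:
                    raise HemodynamicsError(
                        f"no pressure for venous outlet {node!r}")
            elif role == "chamber":
                if self.heart is not None:
                    which = "lv" if node.endswith("LV") else "la"
                    known[node] = (which, None)
                else:
                    known[node] = ("fixed", 0.0)
            elif role == "femoral_source":
                if self.bundle is not None and self.bundle.source_pressure is not None:
                    known[node] = ("func", self.bundle.source_pressure)
                else:
                    known[node] = ("fixed", 0.0)
        self.known_nodes = sorted(known)
        self.known_kinds = [known[n] for n in self.known_nodes]
        kidx = {n: i for i, n in enumerate(self.known_nodes)}
        self.unknown_nodes = sorted(n for n in net.nodes if n not in known)
        uidx = {n: i for i, n in enumerate(self.unknown_nodes)}
        self.nu, self.nk = len(self.unknown_nodes), len(self.known_nodes)

        occluded = set(self.bundle.occluded_ids) if self.bundle else set()
        missing = [sv.id for sv in self.sim_vessels if sv.element is None]
        if missing:
            raise HemodynamicsError(f"missing element for vessel(s) {missing}")

        def slot(node):
            # index into the concatenated [P_unknown, P_known] pressure vector
            return uidx[node] if node in uidx else self.nu + kidx[node]

        comp = [sv for sv in self.sim_vessels if sv.element.C0 > 0]
        rig = [sv for sv in self.sim_vessels if sv.element.C0 == 0]
        self.comp, self.rig = comp, rig
        self.nc = len(comp)

        def occ(svid):
            return self.occlusion_factor if svid in occluded else 1.0

        self.c_R0 = np.array([sv.element.R0 for sv in comp])
        self.c_C0 = np.array([sv.element.C0 for sv in comp])
        self.c_vref = np.array([sv.element.vref_m3 for sv in comp])
        self.c_pref = np.array([sv.element.pref_mmhg for sv in comp]) * MMHG_TO_PA
        self.c_beta = np.array([sv.element.beta for sv in comp])
        self.c_imp = np.array([sv.element.imp_weight for sv in comp])
        self.c_occ = np.array([occ(sv.id) for sv in comp])
        self.c_from = np.array([slot(sv.from_node) for sv in comp], dtype=int)
        self.c_to = np.array([slot(sv.to_node) for sv in comp], dtype=int)

        self.r_g0 = np.array([occ(sv.id) / sv.element.R0 for sv in rig])
        self.r_from = np.array([slot(sv.from_node) for sv in rig], dtype=int)
        self.r_to = np.array([slot(sv.to_node) for sv in rig], dtype=int)
        self.r_uu = np.flatnonzero((self.r_from < self.nu) & (self.r_to < self.nu)) \
            if len(rig) else np.array([], dtype=int)

        # state layout: compliant volumes, then chambers, then periphery
        self.i_lv = self.i_la = self.i_as = self.i_vs = None
        n = self.nc
        if self.heart is not None:
            self.i_lv, self.i_la = n, n + 1
            n += 2
        if self.periphery is not None:
            if self.heart is None:
                raise HemodynamicsError("periphery requires a heart model")
            self.i_as, self.i_vs = n, n + 1
            n += 2
        self.n_states = n

        # which slots of the known vector are state-derived
        self.k_state = {}
        for i, (kind, _) in enumerate(self.known_kinds):
            if kind in ("lv", "la", "as", "vs"):
                self.k_state[kind] = self.k_state.get(kind, []) + [i]

        # net-flow bookkeeping into known boundary nodes (m3/s, positive into node)
        self._kf_from = self.c_from - self.nu  # >=0 where from-end is known
        self._kf_to = self.c_to - self.nu
        self._rk_from = self.r_from - self.nu
        self._rk_to = self.r_to - self.nu

    # -- physics ------------------------------------------------------------
    def _known_pressures(self, t, y):
        p = np.zeros(self.nk)
        hp = self.heart
        for i, (kind, val) in enumerate(self.known_kinds):
            if kind == "fixed":
                p[i] = val
            elif kind == "func":
                p[i] = float(val(t))
            elif kind == "lv":
                e = elastance(t, hp.lv, hp.period)
                p[i] = e * (y[self.i_lv] * M3_TO_ML - hp.lv.V0) * MMHG_TO_PA
            elif kind == "la":
                e = elastance(t, hp.la, hp.period)
                p[i] = e * (y[self.i_la] * M3_TO_ML - hp.la.V0) * MMHG_TO_PA
            elif kind == "as":
                pm = self.periphery
                p[i] = (y[self.i_as] * M3_TO_ML - pm.V_as0) / pm.C_as * MMHG_TO_PA
            elif kind == "vs":
                pm = self.periphery
                p[i] = (y[self.i_vs] * M3_TO_ML - pm.V_vs0) / pm.C_vs * MMHG_TO_PA
        return p

    def _p_lv(self, t, y):
        if self.heart is None:
            return 0.0
        hp = self.heart
        e = elastance(t, hp.lv, hp.period)
        return e * (y[self.i_lv] * M3_TO_ML - hp.lv.V0) * MMHG_TO_PA

    def _ptm_from_volume(self, v):
        v_floor = COLLAPSE_FLOOR_FRAC * self.c_vref
        ptm_lin = self.c_pref + (v - self.c_vref) / self.c_C0
        ptm_floor = self.c_pref + (v_floor - self.c_vref) / self.c_C0
        return np.where(v >= v_floor, ptm_lin,
                        ptm_floor + (v - v_floor) / (self.c_C0 * COLLAPSE_SOFTNESS))

    def _volume_from_ptm(self, ptm):
        return self.c_vref + self.c_C0 * (ptm - self.c_pref)

    def _half_conductance(self, ptm):
        fac = 1.0 + self.c_beta * (ptm - self.c_pref) / self.c_pref
        np.clip(fac, DISTENSION_CLAMP[0], DISTENSION_CLAMP[1], out=fac)
        r = self.c_R0 / fac ** 4
        return self.c_occ * 2.0 / r

    def _node_solve(self, g_half, p_int, p_known):
        diag = np.zeros(self.nu)
        rhs = np.zeros(self.nu)
        for ends in (self.c_from, self.c_to):
            m = ends < self.nu
            if m.any():
                np.add.at(diag, ends[m], g_half[m])
                np.add.at(rhs, ends[m], g_half[m] * p_int[m])
        uu = self.r_uu
        r_from, r_to, r_g = self.r_from, self.r_to, self.r_g0
        for ends, other in ((r_from, r_to), (r_to, r_from)):
            m = (ends < self.nu) & (other >= self.nu)
            if m.any():
                np.add.at(diag, ends[m], r_g[m])
                np.add.at(rhs, ends[m], r_g[m] * p_known[other[m] - self.nu])
        if len(uu) == 0:
            with np.errstate(invalid="ignore", divide="ignore"):
                p_u = np.where(diag > 0, rhs / np.where(diag > 0, diag, 1.0), 0.0)
            return p_u
        # rigid vessels couple junction nodes: sparse symmetric solve
        a, b, g = r_from[uu], r_to[uu], r_g[uu]
        np.add.at(diag, a, g)
        np.add.at(diag, b, g)
        rows = np.concatenate([np.arange(self.nu), a, b])
        cols = np.concatenate([np.arange(self.nu), b, a])
        vals = np.concatenate([np.where(diag > 0, diag, 1.0), -g, -g])
        A = sp.csr_matrix((vals, (rows, cols)), shape=(self.nu, self.nu))
        return spla.spsolve(A, rhs)

    def _flows(self, t, y):
        """All per-vessel flows and node pressures at one state. Returns
        (p_all [Pa], q_in, q_out [m3/s] per compliant vessel, q_rigid)."""
        p_known = self._known_pressures(t, y)
        p_lv = self._p_lv(t, y)
        v = y[: self.nc]
        ptm = self._ptm_from_volume(v)
        p_ext = self.c_imp * p_lv
        p_int = ptm + p_ext
        g = self._half_conductance(ptm)
        p_u = self._node_solve(g, p_int, p_known)
        p_all = np.concatenate([p_u, p_known])
        q_in = g * (p_all[self.c_from] - p_int)
        q_out = g * (p_int - p_all[self.c_to])
        q_rig = self.r_g0 * (p_all[self.r_from] - p_all[self.r_to])
        return p_all, q_in, q_out, q_rig

    def _boundary_net_inflow(self, q_in, q_out, q_rig):
        """Net flow (m3/s) from the network into each known node."""
        net = np.zeros(self.nk)
        m = self._kf_from >= 0
        if m.any():
            np.add.at(net, self._kf_from[m], -q_in[m])
        m = self._kf_to >= 0
        if m.any():
            np.add.at(net, self._kf_to[m], q_out[m])
        if len(q_rig):
            m = self._rk_from >= 0
            if m.any():
                np.add.at(net, self._rk_from[m], -q_rig[m])
            m = self._rk_to >= 0
            if m.any():
                np.add.at(net, self._rk_to[m], q_rig[m])
        return net

    def _valve_flow(self, dp_pa, r_open_ru):
        pm = self.periphery
        g_open = 1.0 / (r_open_ru * RU_TO_SI)
        x = dp_pa / (pm.valve_softness_mmhg * MMHG_TO_PA)
        sig = 1.0 / (1.0 + np.exp(-np.clip(x, -50, 50)))
        g = g_open * (sig + pm.valve_leak)
        return g * dp_pa

    def rhs(self, t, y):
        p_all, q_in, q_out, q_rig = self._flows(t, y)
        dy = np.zeros_like(y)
        dy[: self.nc] = q_in - q_out
        if self.heart is None:
            return dy
        hp, pm = self.heart, self.periphery
        net_in = self._boundary_net_inflow(q_in, q_out, q_rig)
        p_lv = self._p_lv(t, y)
        e_la = elastance(t, hp.la, hp.period)
        p_la = e_la * (y[self.i_la] * M3_TO_ML - hp.la.V0) * MMHG_TO_PA
        if pm is not None:
            p_as = (y[self.i_as] * M3_TO_ML - pm.V_as0) / pm.C_as * MMHG_TO_PA
            p_vs = (y[self.i_vs] * M3_TO_ML - pm.V_vs0) / pm.C_vs * MMHG_TO_PA
            q_mv = self._valve_flow(p_la - p_lv, pm.R_mv)
            q_av = self._valve_flow(p_lv - p_as, pm.R_av)
            q_sys = (p_as - p_vs) / (pm.R_sys * RU_TO_SI)
            q_ven = (p_vs - p_la) / (pm.R_ven * RU_TO_SI)
            dy[self.i_lv] = q_mv - q_av
            dy[self.i_la] = q_ven - q_mv
            dy[self.i_as] = q_av - q_sys
            dy[self.i_vs] = q_sys - q_ven
        for kind, slots in self.k_state.items():
            target = {"lv": self.i_lv, "la": self.i_la,
                      "as": self.i_as, "vs": self.i_vs}[kind]
            if target is not None:
                dy[target] += sum(net_in[s] for s in slots)
        return dy

    # -- initial state ------------------------------------------------------
    def initial_state(self, pressures_mmhg: Mapping[str, float] | None = None) -> np.ndarray:
        """Reference initial condition: vessels at an order-typical pressure
        profile, chambers at end-diastolic volumes, periphery at nominal
        arterial/venous pressures."""
        p0 = {"artery": 80.0, "capillary": 35.0, "vein": 15.0,
              "equivalent": 35.0, "as": 90.0, "vs": 8.0,
              "lv_edp": 8.0, "la_p": 8.0}
        if pressures_mmhg:
            p0.update(pressures_mmhg)
        y = np.zeros(self.n_states)
        ptm0 = np.empty(self.nc)
        for j, sv in enumerate(self.comp):
            key = sv.kind if sv.kind in ("artery", "capillary", "vein") else "equivalent"
            ptm0[j] = p0[key] * MMHG_TO_PA
        y[: self.nc] = self._volume_from_ptm(ptm0)
        if self.heart is not None:
            hp = self.heart
            y[self.i_lv] = (hp.lv.V0 + p0["lv_edp"] / hp.lv.E_min) / M3_TO_ML
            y[self.i_la] = (hp.la.V0 + p0["la_p"] / hp.la.E_min) / M3_TO_ML
        if self.periphery is not None:
            pm = self.periphery
            y[self.i_as] = (pm.V_as0 + p0["as"] * pm.C_as) / M3_TO_ML
            y[self.i_vs] = (pm.V_vs0 + p0["vs"] * pm.C_vs) / M3_TO_ML
        return y

    # -- jacobian sparsity ---------------------------------------------------
    def jac_sparsity(self) -> sp.csr_matrix:
        n = self.n_states
        J = sp.lil_matrix((n, n), dtype=np.int8)
        # node clusters joined by rigid junction-junction edges
        parent = list(range(self.nu))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for k in self.r_uu:
            a, b = find(self.r_from[k]), find(self.r_to[k])
            if a != b:
                parent[a] = b
        cluster_members: dict[int, list[int]] = {}
        for j, sv in enumerate(self.comp):
            for end in (self.c_from[j], self.c_to[j]):
                if end < self.nu:
                    cluster_members.setdefault(find(end), []).append(j)
        for members in cluster_members.values():
            for a in members:
                for b in members:
                    J[a, b] = 1
        for j in range(self.nc):
            J[j, j] = 1
        aux = [i for i in (self.i_lv, self.i_la, self.i_as, self.i_vs)
               if i is not None]
        for i in aux:
            J[i, :] = 1
            J[:, i] = 1
        return J.tocsr()


def assemble_system(network: mm.NetworkTopology,
                    elements: Mapping[str, VesselElement],
                    heart: HeartModel | None,
                    periphery: PeripheralModel | None,
                    scenario: Scenario | ScenarioBundle | None = None,
                    *, boundary_pressures: Mapping[str, object] | None = None,
                    occlusion_factor: float = OCCLUSION_FACTOR) -> System:
    """Assemble the state-space system for a network under a scenario.

    ``boundary_pressures`` maps node ids to fixed pressures in mmHg (or
    callables t -> mmHg) and is intended for boundary-driven fixtures where
    no heart/periphery is attached; it also overrides the default boundary
    wiring on full networks. Occluded vessels keep their state but have
    conductance multiplied by ``occlusion_factor``.
    """
    missing = [v.id for v in network.vessels if v.id not in elements]
    if missing:
        raise HemodynamicsError(f"missing element for vessel(s): {missing[:5]}")
    period = heart.period if heart is not None else 0.6
    if isinstance(scenario, Scenario):
        bundle = apply_scenario(network, scenario, period)
    else:
        bundle = scenario
    sim: list[SimVessel] = [
        SimVessel(v.id, v.from_node, v.to_node, v.kind, elements[v.id])
        for v in network.vessels
    ]
    if network.equivalent_port_pairs:
        r_eq, c_eq, v_eq, w_eq = effective_region_resistance(network, elements)
        for i, (p_i, p_o) in enumerate(network.equivalent_port_pairs):
            el = VesselElement(f"EQ_{i:03d}", R0=r_eq, C0=c_eq, beta=0.0,
                               imp_weight=w_eq, vref_m3=v_eq)
            sim.append(SimVessel(el.vessel_id, p_i, p_o, "equivalent", el))
    return System(network, sim, heart, periphery, bundle,
                  boundary_pressures, occlusion_factor)


# ---------------------------------------------------------------------------
# solving
# ---------------------------------------------------------------------------

@dataclass
class HemoSolution:
    """Time series of the solved circulation, clinical units.

    Flows are signed positive in each vessel's from->to direction; ``q_in``
    and ``q_out`` are the proximal/distal half-element flows (equal for
    rigid vessels). ``period`` allows periodic extension of the final beat
    for long tracer-tracking windows.
    """

    t: np.ndarray                  # s
    node_ids: list[str]
    node_roles: dict
    node_pressures: np.ndarray     # (nt, nn) mmHg
    vessel_ids: list[str]
    vessel_from: list[str]
    vessel_to: list[str]
    vessel_kind: list[str]
    vessel_order: list  # int | None per vessel (None: shunts, source, lumps)
    vessel_volume_m3: np.ndarray   # reference luminal volumes (advection)
    q_in: np.ndarray               # (nt, nv) mL/s
    q_out: np.ndarray              # (nt, nv) mL/s
    vessel_volumes: np.ndarray     # (nt, nv) mL (states; reference for rigid)
    chambers: dict
    period: float | None
    occluded_ids: tuple[str, ...]
    mass_residual_max: float
    periodicity_residual: float
    beat_residuals: np.ndarray

    @property
    def q_mid(self) -> np.ndarray:
        return 0.5 * (self.q_in + self.q_out)

    def mean_flows(self, last_beat: bool = True) -> np.ndarray:
        """Beat-averaged (or whole-trace) mid-element flow per vessel, mL/s."""
        q = self.q_mid
        if last_beat and self.period is not None:
            m = self.t >= self.t[-1] - self.period + 1e-12
            return q[m].mean(axis=0)
        return q.mean(axis=0)

    def beat_flow_table(self, n_samples: int = 120) -> tuple[np.ndarray, np.ndarray]:
        """(times within one beat, (n_samples, nv) flows) from the last beat."""
        if self.period is None:
            raise HemodynamicsError("solution has no periodic beat structure")
        t0 = self.t[-1] - self.period
        ts = t0 + np.arange(n_samples) / n_samples * self.period
        q = np.empty((n_samples, len(self.vessel_ids)))
        for j in range(len(self.vessel_ids)):
            q[:, j] = np.interp(ts, self.t, self.q_mid[:, j])
        return ts - t0, q

    def vessel_index(self, vessel_id: str) -> int:
        return self.vessel_ids.index(vessel_id)


def solve(system: System, duration: float, output_dt: float = 1e-3,
          rtol: float = 1e-7, atol_rel: float = 1e-9,
          method: str = "BDF") -> HemoSolution:
    """Integrate the assembled system and post-process flows and residuals.

    ``atol_rel`` scales each state's absolute tolerance by its reference
    volume, which keeps the stiff solver honest across the several orders
    of magnitude separating capillary and trunk volumes. Reproducible
    bit-wise for fixed inputs and solver settings.
    """
    if duration <= 0:
        raise HemodynamicsError("duration must be > 0")
    t_eval = np.arange(0.0, duration + 0.5 * output_dt, output_dt)
    t_eval = np.minimum(t_eval[t_eval <= duration + 0.5 * output_dt], duration)
    sys_ = system
    if sys_.n_states == 0:
        return _postprocess(sys_, t_eval, np.zeros((0, len(t_eval))))
    y0 = sys_.initial_state()
    scale = np.abs(y0).copy()
    scale[scale == 0] = 1e-12
    atol = atol_rel * scale
    max_step = (sys_.heart.period / 8.0) if sys_.heart is not None else np.inf
    sol = solve_ivp(sys_.rhs, (0.0, duration), y0, method=method,
                    t_eval=t_eval, rtol=rtol, atol=atol,
                    jac_sparsity=sys_.jac_sparsity(), max_step=max_step)
    if not sol.success:
        t_fail = sol.t[-1] if len(sol.t) else 0.0
        dy = sys_.rhs(t_fail, sol.y[:, -1] if sol.y.size else y0)
        worst = int(np.argmax(np.abs(dy)))
        label = (sys_.comp[worst].id if worst < sys_.nc else f"aux[{worst - sys_.nc}]")
        raise SolverError(
            f"integration failed at t = {t_fail:.4f} s ({sol.message}); "
            f"fastest-moving state: {label}")
    return _postprocess(sys_, sol.t, sol.y)


def _postprocess(sys_: System, t: np.ndarray, y: np.ndarray) -> HemoSolution:
    nt = len(t)
    nv = len(sys_.sim_vessels)
    nn = sys_.nu + sys_.nk
    node_ids = sys_.unknown_nodes + sys_.known_nodes
    p_nodes = np.empty((nt, nn))
    q_in = np.empty((nt, nv))
    q_out = np.empty((nt, nv))
    vols = np.empty((nt, nv))
    comp_pos = {id(sv): j for j, sv in enumerate(sys_.comp)}
    c_cols = [i for i, sv in enumerate(sys_.sim_vessels) if sv.element.C0 > 0]
    r_cols = [i for i, sv in enumerate(sys_.sim_vessels) if sv.element.C0 == 0]
    vref = np.array([sv.element.vref_m3 for sv in sys_.sim_vessels])
    mass_res = 0.0
    for k in range(nt):
        yk = y[:, k] if y.size else np.zeros(sys_.n_states)
        p_all, qi, qo, qr = sys_._flows(t[k], yk)
        p_nodes[k] = p_all * PA_TO_MMHG
        q_in[k, c_cols] = qi * M3_TO_ML
        q_out[k, c_cols] = qo * M3_TO_ML
        q_in[k, r_cols] = qr * M3_TO_ML
        q_out[k, r_cols] = qr * M3_TO_ML
        vols[k, c_cols] = yk[: sys_.nc] * M3_TO_ML
        vols[k, r_cols] = vref[r_cols] * M3_TO_ML
        mass_res = max(mass_res, _junction_residual(sys_, p_all, qi, qo, qr))
    chambers = {}
    if sys_.heart is not None:
        hp = sys_.heart
        v_lv = y[sys_.i_lv] * M3_TO_ML
        v_la = y[sys_.i_la] * M3_TO_ML
        chambers["LV"] = {"volume_ml": v_lv,
                          "pressure_mmhg": elastance(t, hp.lv, hp.period) * (v_lv - hp.lv.V0)}
        chambers["LA"] = {"volume_ml": v_la,
                          "pressure_mmhg": elastance(t, hp.la, hp.period) * (v_la - hp.la.V0)}
        if sys_.periphery is not None:
            pm = sys_.periphery
            chambers["arterial"] = {"volume_ml": y[sys_.i_as] * M3_TO_ML,
                                    "pressure_mmhg": (y[sys_.i_as] * M3_TO_ML - pm.V_as0) / pm.C_as}
            chambers["venous"] = {"volume_ml": y[sys_.i_vs] * M3_TO_ML,
                                  "pressure_mmhg": (y[sys_.i_vs] * M3_TO_ML - pm.V_vs0) / pm.C_vs}
    period = sys_.heart.period if sys_.heart is not None else None
    beat_res, per_res = _beat_residuals(t, p_nodes, period)
    return HemoSolution(
        t=t, node_ids=node_ids, node_roles=dict(sys_.network.nodes),
        node_pressures=p_nodes,
        vessel_ids=[sv.id for sv in sys_.sim_vessels],
        vessel_from=[sv.from_node for sv in sys_.sim_vessels],
        vessel_to=[sv.to_node for sv in sys_.sim_vessels],
        vessel_kind=[sv.kind for sv in sys_.sim_vessels],
        vessel_order=[sys_.network.vessel(sv.id).order
                      if sv.kind != "equivalent" else None
                      for sv in sys_.sim_vessels],
        vessel_volume_m3=vref,
        q_in=q_in, q_out=q_out, vessel_volumes=vols, chambers=chambers,
        period=period,
        occluded_ids=sys_.bundle.occluded_ids if sys_.bundle else (),
        mass_residual_max=mass_res,
        periodicity_residual=per_res, beat_residuals=beat_res)


def _junction_residual(sys_, p_all, q_in, q_out, q_rig) -> float:
    """Max relative node mass-balance residual over junction nodes."""
    inflow = np.zeros(sys_.nu)
    scale = np.zeros(sys_.nu)
    for ends, q, sgn in ((sys_.c_from, q_in, -1.0), (sys_.c_to, q_out, 1.0)):
        m = ends < sys_.nu
        if m.any():
            np.add.at(inflow, ends[m], sgn * q[m])
            np.add.at(scale, ends[m], np.abs(q[m]))
    if len(q_rig):
        for ends, sgn in ((sys_.r_from, -1.0), (sys_.r_to, 1.0)):
            m = ends < sys_.nu
            if m.any():
                np.add.at(inflow, ends[m], sgn * q_rig[m])
                np.add.at(scale, ends[m], np.abs(q_rig[m]))
    if sys_.nu == 0:
        return 0.0
    # floor the per-node scale at a fraction of the network-wide flow scale
    # so roundoff dust at stagnant nodes does not register as imbalance
    global_q = max(np.max(np.abs(q_in), initial=0.0),
                   np.max(np.abs(q_rig), initial=0.0), 1e-30)
    floor = 1e-3 * global_q
    return float(np.max(np.abs(inflow) / np.maximum(scale, floor)))


def _beat_residuals(t, p_nodes, period):
    if period is None or t[-1] < 2 * period:
        return np.array([]), 0.0
    n_beats = int(np.floor(t[-1] / period + 1e-9))
    res = []
    prev = None
    ref_t = np.linspace(0, period, 64, endpoint=False)
    for b in range(n_beats):
        ts = b * period + ref_t
        pb = np.empty((len(ref_t), p_nodes.shape[1]))
        for j in range(p_nodes.shape[1]):
            pb[:, j] = np.interp(ts, t, p_nodes[:, j])
        if prev is not None:
            num = np.linalg.norm(pb - prev)
            den = max(np.linalg.norm(prev), 1e-30)
            res.append(num / den)
        prev = pb
    res = np.asarray(res)
    return res, float(res[-1]) if len(res) else 0.0
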