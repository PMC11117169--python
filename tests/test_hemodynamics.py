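"""Elastance heart, vessel elements, assembly, and the circuit solver."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sarpsim import hemodynamics as hd
from sarpsim import morphometry as mm
from sarpsim.units import MMHG_TO_PA, ML_TO_M3

from conftest import make_network


class TestElastance:
    CH = hd.ChamberParams(E_max=2.0, E_min=0.06, V0=10.0, onset=0.0,
                          duration=0.45)

    def test_end_diastole_is_minimal_elastance(self):
        # activation is zero outside the systolic window
        assert hd.elastance(0.55, self.CH, 1.0) == pytest.approx(0.06)

    def test_periodicity(self):
        for t in (0.1, 0.27, 0.8):
            assert hd.elastance(t + 1.0, self.CH, 1.0) == pytest.approx(
                hd.elastance(t, self.CH, 1.0), rel=1e-12)

    def test_peak_pressure_from_pv_relation(self):
        # P = E*(V - V0): 2.0 mmHg/mL * (70 - 10) mL = 120 mmHg
        t_peak = self.CH.duration / 2.0
        e = hd.elastance(t_peak, self.CH, 1.0)
        assert e == pytest.approx(2.0)
        assert e * (70.0 - 10.0) == pytest.approx(120.0)

    def test_negative_time_rejected(self):
        with pytest.raises(hd.HemodynamicsError):
            hd.elastance(-0.1, self.CH, 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(t=st.floats(0, 10))
    def test_bounded_by_emin_emax(self, t):
        e = hd.elastance(t, self.CH, 0.6)
        assert self.CH.E_min - 1e-12 <= e <= self.CH.E_max + 1e-12


class TestElementResistance:
    def el(self, beta):
        return hd.VesselElement("v", R0=1e12, C0=1e-15, beta=beta,
                                pref_mmhg=45.0)

    def test_beta_zero_is_constant(self):
        for p in (-50.0, 0.0, 45.0, 200.0):
            assert hd.element_resistance(self.el(0.0), p) == 1e12

    def test_reference_pressure_anchors_r0(self):
        assert hd.element_resistance(self.el(0.7), 45.0) == pytest.approx(1e12)

    def test_distension_law_hand_value(self):
        # beta=1 at Ptm = 2*Pref: D doubles, R drops 16-fold
        assert hd.element_resistance(self.el(1.0), 90.0) == pytest.approx(
            1e12 / 16.0, rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(p1=st.floats(-100, 300), p2=st.floats(-100, 300),
           beta=st.floats(0, 2))
    def test_monotone_nonincreasing_and_positive(self, p1, p2, beta):
        el = self.el(beta)
        r1, r2 = hd.element_resistance(el, p1), hd.element_resistance(el, p2)
        assert r1 > 0 and r2 > 0
        if p1 < p2:
            assert r1 >= r2


def _rigid_elements(network, r_by_id):
    return {vid: hd.VesselElement(vid, R0=r, C0=0.0)
            for vid, r in r_by_id.items()}


def _resistor_oracle(vessels, resistances, boundary_mmhg):
    """Independent steady resistor-network solve (dense Laplacian with
    Dirichlet elimination). Returns flow per vessel (mL/s, from->to)."""
    nodes = sorted({v[4] for v in vessels} | {v[5] for v in vessels})
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    G = np.zeros((n, n))
    for rec in vessels:
        vid, frm, to = rec[0], rec[4], rec[5]
        g = 1.0 / resistances[vid]
        a, b = idx[frm], idx[to]
        G[a, a] += g
        G[b, b] += g
        G[a, b] -= g
        G[b, a] -= g
    p = np.zeros(n)
    fixed = {idx[k]: v * MMHG_TO_PA for k, v in boundary_mmhg.items()}
    free = [i for i in range(n) if i not in fixed]
    rhs = -G[np.ix_(free, list(fixed))] @ np.array(list(fixed.values()))
    if free:
        p[free] = np.linalg.solve(G[np.ix_(free, free)], rhs)
    for i, v in fixed.items():
        p[i] = v
    return {rec[0]: (p[idx[rec[4]]] - p[idx[rec[5]]]) / resistances[rec[0]] / ML_TO_M3
            for rec in vessels}


def _random_rigid_network(rng):
    n_nodes = rng.integers(4, 10)
    nodes = [f"n{i}" for i in range(n_nodes)]
    vessels = []
    # random spanning tree plus extra edges, <= 20 vessels
    for i in range(1, n_nodes):
        j = int(rng.integers(0, i))
        vessels.append((f"v{len(vessels)}", 1, 50.0, 1.0, nodes[j], nodes[i],
                        "artery"))
    for _ in range(int(rng.integers(0, 8))):
        a, b = rng.choice(n_nodes, size=2, replace=False)
        vessels.append((f"v{len(vessels)}", 1, 50.0, 1.0, nodes[int(a)],
                        nodes[int(b)], "artery"))
    vessels = vessels[:20]
    resistances = {v[0]: float(10 ** rng.uniform(9, 13)) for v in vessels}
    n_bnd = int(rng.integers(2, min(4, n_nodes) + 1))
    bnd_nodes = rng.choice(n_nodes, size=n_bnd, replace=False)
    boundary = {nodes[int(i)]: float(rng.uniform(5, 120)) for i in bnd_nodes}
    roles = {n: "interior" for n in nodes}
    return vessels, resistances, boundary, roles


def solve_rigid(vessels, resistances, boundary, roles):
    net = make_network(vessels, roles)
    els = _rigid_elements(net, resistances)
    sys_ = hd.assemble_system(net, els, heart=None, periphery=None,
                              boundary_pressures=boundary)
    sol = hd.solve(sys_, duration=1.0, output_dt=1.0)
    return {vid: sol.q_in[0, sol.vessel_index(vid)] for vid in resistances}


class TestRigidCircuits:
    def test_series_resistors_closed_form(self):
        vessels = [("v0", 1, 50, 1, "a", "b", "artery"),
                   ("v1", 1, 50, 1, "b", "c", "artery"),
                   ("v2", 1, 50, 1, "c", "d", "artery")]
        R = {"v0": 1e10, "v1": 3e10, "v2": 6e10}
        q = solve_rigid(vessels, R, {"a": 100.0, "d": 10.0},
                        {n: "interior" for n in "abcd"})
        expected = (90.0 * MMHG_TO_PA) / 1e11 / ML_TO_M3
        for vid in R:
            assert q[vid] == pytest.approx(expected, rel=1e-10)

    def test_matches_sparse_oracle_on_randomized_networks(self):
        """Steady flows equal an independent resistor-network solve to 1e-8
        relative error on >= 25 randomized rigid networks."""
        rng = np.random.default_rng(12345)
        for _ in range(25):
            vessels, resistances, boundary, roles = _random_rigid_network(rng)
            got = solve_rigid(vessels, resistances, boundary, roles)
            want = _resistor_oracle(vessels, resistances, boundary)
            scale = max(max(abs(v) for v in want.values()), 1e-30)
            for vid in resistances:
                assert abs(got[vid] - want[vid]) <= 1e-8 * scale


class TestCompliantDynamics:
    def test_step_response_relaxes_with_rc_time_constant(self):
        # both ends held at P: dV/dt = (4/R)(P - Pint) -> tau = R*C/4
        R, C, vref = 1e10, 1e-13, 1e-6
        pref = 80.0
        vessels = [("v0", 1, 50, 1, "a", "b", "artery")]
        net = make_network(vessels, {"a": "interior", "b": "interior"})
        els = {"v0": hd.VesselElement("v0", R0=R, C0=C, pref_mmhg=pref,
                                      vref_m3=vref)}
        sys_ = hd.assemble_system(net, els, None, None,
                                  boundary_pressures={"a": 30.0, "b": 30.0})
        tau = R * C / 4.0
        sol = hd.solve(sys_, duration=6 * tau, output_dt=tau / 10,
                       rtol=1e-10, atol_rel=1e-12)
        v = sol.vessel_volumes[:, 0] * ML_TO_M3  # mL -> m3
        v_eq = vref + C * (30.0 - pref) * MMHG_TO_PA
        expected = v_eq + (vref - v_eq) * np.exp(-sol.t / tau)
        assert np.allclose(v, expected, rtol=0, atol=2e-4 * abs(vref - v_eq))

    def test_constant_pressure_equilibrium(self):
        # equal constant boundary pressures, no activation: flows decay to
        # zero and every node settles at the boundary pressure
        vessels = [("v0", 1, 50, 1, "a", "m", "artery"),
                   ("v1", 1, 50, 1, "m", "b", "artery")]
        net = make_network(vessels, {"a": "interior", "m": "interior",
                                     "b": "interior"})
        els = {v[0]: hd.VesselElement(v[0], R0=1e10, C0=1e-14, pref_mmhg=50.0,
                                      vref_m3=1e-7) for v in vessels}
        sys_ = hd.assemble_system(net, els, None, None,
                                  boundary_pressures={"a": 40.0, "b": 40.0})
        sol = hd.solve(sys_, duration=0.01, output_dt=5e-4)
        assert abs(sol.q_in[-1]).max() < 1e-9
        m = sol.node_ids.index("m")
        assert sol.node_pressures[-1, m] == pytest.approx(40.0, abs=1e-6)


class TestEquivalentNetworkCoupling:
    def test_identical_copies_multiply_micro_inflow(self):
        # 3 identical copies -> total micro inflow = 4 x embedded inflow
        rows = [mm.OrderRow(1, 1, 30.0, 1.0), mm.OrderRow(0, 2, 25.0, 0.5),
                mm.OrderRow(-1, 1, 35.0, 1.0)]
        net = mm.generate_network(rows, seed=0, with_source_line=False)
        net = mm.attach_equivalent_networks(net, 3)
        els = {v.id: hd.VesselElement(v.id, R0=1e12 * (1 + i), C0=0.0)
               for i, v in enumerate(net.vessels)}
        sys_ = hd.assemble_system(net, els, None, None,
                                  boundary_pressures={"inlet": 60.0, "sinus": 10.0})
        sol = hd.solve(sys_, duration=1.0, output_dt=1.0)
        q_emb = sol.q_in[0, sol.vessel_index("A+01_000")]
        q_eq = sum(sol.q_in[0, i] for i, k in enumerate(sol.vessel_kind)
                   if k == "equivalent")
        assert q_eq == pytest.approx(3.0 * q_emb, rel=1e-8)
        total = q_emb + q_eq
        assert total == pytest.approx(4.0 * q_emb, rel=1e-8)


class TestScenarios:
    def test_baseline_has_empty_occlusion_set(self):
        assert hd.Scenario.baseline().occluded_vessels == ()

    def test_scenario_invariants(self):
        with pytest.raises(hd.HemodynamicsError):
            hd.Scenario("sarp_b", distal_gcv_occluded=True)  # missing source
        with pytest.raises(hd.HemodynamicsError):
            hd.Scenario("baseline", gcv_source=hd.GcvSource(60.0))

    def test_apply_resolves_occluded_ids(self, default_network):
        b = hd.apply_scenario(default_network, hd.Scenario.sarp_b())
        tags = default_network.tags
        assert tags["lad_main"] in b.occluded_ids
        assert tags["gcv_distal"] in b.occluded_ids
        nb = hd.apply_scenario(default_network, hd.Scenario.sarp_nb())
        assert tags["gcv_distal"] not in nb.occluded_ids

    def test_source_waveform_means(self):
        t = np.linspace(0, 0.6, 2001)[:-1]
        for mean in (63.9, 39.2):
            src = hd.GcvSource(mean, 30.0)
            p = np.asarray(src.pressure_pa(t, 0.6)) / MMHG_TO_PA
            assert p.mean() == pytest.approx(mean, abs=1e-6)

    def test_unknown_occluded_id_is_named(self, default_network):
        sc = hd.Scenario("occlusion_only", occluded_vessels=("NOPE",))
        with pytest.raises(KeyError, match="NOPE"):
            hd.apply_scenario(default_network, sc)

    def test_missing_element_is_named(self, default_network, default_elements):
        els = dict(default_elements)
        els.pop("C+00_000")
        with pytest.raises(hd.HemodynamicsError, match="C\\+00_000"):
            hd.assemble_system(default_network, els, hd.HeartModel(),
                               hd.PeripheralModel(), hd.Scenario.baseline())

    def test_sarp_on_untagged_network_rejected(self):
        rows = [mm.OrderRow(1, 1, 30.0, 1.0), mm.OrderRow(0, 2, 25.0, 0.5),
                mm.OrderRow(-1, 1, 35.0, 1.0)]
        net = mm.generate_network(rows, seed=0, with_source_line=False)
        with pytest.raises(hd.HemodynamicsError, match="GCV|source"):
            hd.apply_scenario(net, hd.Scenario.sarp_b())


class TestSolvedScenarioPhysiology:
    """Checks on the shared default-network comparison run."""

    def test_pressures_physiological(self, comparison):
        sol = comparison.scenarios["baseline"].solution
        p_lv = sol.chambers["LV"]["pressure_mmhg"]
        p_as = sol.chambers["arterial"]["pressure_mmhg"]
        assert 80 < p_lv.max() < 180
        assert 50 < p_as.min() < p_as.max() < 180

    def test_mass_balance_all_scenarios(self, comparison):
        for r in comparison.scenarios.values():
            assert r.mass_residual_max < 1e-8

    def test_periodicity_residual_decreases(self, comparison):
        res = comparison.scenarios["baseline"].solution.beat_residuals
        assert len(res) >= 3
        assert all(b <= a * 1.001 for a, b in zip(res, res[1:]))

    def test_prescribed_gcv_pressure_is_honored(self, comparison, default_network):
        sol = comparison.scenarios["sarp_b"].solution
        j = sol.node_ids.index(default_network.tags["gcv_junction"])
        m = sol.t >= sol.t[-1] - 0.6
        assert sol.node_pressures[m, j].mean() == pytest.approx(63.9, abs=2.0)
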