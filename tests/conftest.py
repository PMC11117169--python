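"""Shared fixtures: the default network, solved scenario bundle, toy builders."""
from __future__ import annotations

import numpy as np
import pytest

from sarpsim import (
    PipelineConfig, build_default_network, build_elements, compare_scenarios,
)
from sarpsim.hemodynamics import HemoSolution
from sarpsim.morphometry import NetworkTopology, Vessel


@pytest.fixture(scope="session")
def default_network():
    return build_default_network(seed=0)


@pytest.fixture(scope="session")
def default_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def default_elements(default_network):
    return build_elements(default_network)


@pytest.fixture(scope="session")
def comparison(default_network, default_config):
    """Full default comparison (4 scenarios x 5 replicates), solutions kept.

    The expensive shared computation behind the scenario-level checks:
    occlusion efficacy, flow reversal, washout ordering, retro-reach,
    and indicator conservation all read from this one run.
    """
    return compare_scenarios(default_network, default_config,
                             keep_solutions=True)


# ---------------------------------------------------------------------------
# toy builders
# ---------------------------------------------------------------------------

def make_network(vessels: list[tuple], roles: dict[str, str],
                 tags: dict | None = None,
                 micro: tuple[str, ...] = (),
                 shunts: tuple[str, ...] = (),
                 seed: int = 0) -> NetworkTopology:
    """Toy topology from (id, order, D_um, L_mm, from, to, kind[, R]) tuples."""
    vs = []
    for rec in vessels:
        vid, order, d, length, frm, to, kind = rec[:7]
        resistance = rec[7] if len(rec) > 7 else None
        vs.append(Vessel(vid, order, d, length, frm, to, kind, resistance))
    return NetworkTopology(nodes=dict(roles), vessels=tuple(vs),
                           thebesian_shunts=tuple(shunts),
                           equivalent_port_pairs=(),
                           embedded_micro_region=frozenset(micro),
                           seed=seed, tags=tags or {})


def make_solution(network: NetworkTopology, flows_ml_s: dict[str, float],
                  volumes_m3: dict[str, float] | None = None,
                  occluded: tuple[str, ...] = (),
                  period: float | None = None) -> HemoSolution:
    """Hand-built steady HemoSolution for tracking tests.

    ``flows_ml_s`` are signed mid-element flows; geometry volumes default to
    each vessel's luminal volume.
    """
    ids = [v.id for v in network.vessels]
    q = np.array([[flows_ml_s.get(v, 0.0) for v in ids]] * 2)
    vols = np.array([
        (volumes_m3 or {}).get(v.id,
                               v.volume_m3 if v.kind in ("artery", "capillary",
                                                         "vein", "source_line")
                               else 0.0)
        for v in network.vessels])
    t = np.array([0.0, 1.0])
    nn = len(network.nodes)
    return HemoSolution(
        t=t, node_ids=list(network.nodes), node_roles=dict(network.nodes),
        node_pressures=np.zeros((2, nn)),
        vessel_ids=ids,
        vessel_from=[v.from_node for v in network.vessels],
        vessel_to=[v.to_node for v in network.vessels],
        vessel_kind=[v.kind for v in network.vessels],
        vessel_order=[v.order for v in network.vessels],
        vessel_volume_m3=vols,
        q_in=q.copy(), q_out=q.copy(),
        vessel_volumes=np.tile(vols * 1e6, (2, 1)),
        chambers={}, period=period, occluded_ids=tuple(occluded),
        mass_residual_max=0.0, periodicity_residual=0.0,
        beat_residuals=np.array([]))
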