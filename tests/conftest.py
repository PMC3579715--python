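import pytest

from emsurv.curves import HazardCurves, N_BINS
from emsurv.region import (AMBULANCE, Home, RegionConfig, RegionScenario,
                           RoadEdge, RoadNetwork, RoadNode, Station,
                           generate_region)


def build_region(node_xy, edges, homes, stations):
    """Hand-build a region from terse tuples.

    node_xy: [(x, y), ...] (node ids are positional)
    edges:   [(a, b, length_km, speed_kmh, in_locality), ...]
    homes:   [(node_id, inhabitants), ...]
    stations:[(node_id, kind, reaction_minutes), ...]
    """
    network = RoadNetwork(
        nodes=tuple(RoadNode(i, float(x), float(y)) for i, (x, y) in enumerate(node_xy)),
        edges=tuple(RoadEdge(a, b, float(l), float(s), bool(loc))
                    for a, b, l, s, loc in edges),
    )
    home_tuple = tuple(Home(i, nid, inh) for i, (nid, inh) in enumerate(homes))
    station_tuple = tuple(Station(i, nid, kind, float(r))
                          for i, (nid, kind, r) in enumerate(stations))
    return RegionScenario(network=network, homes=home_tuple, stations=station_tuple,
                          pop=sum(h.inhabitants for h in home_tuple), seed=0)


def constant_curves(vf=0.3, surv=0.2):
    return HazardCurves(vf=(vf,) * N_BINS, surv=(surv,) * N_BINS)


@pytest.fixture
def tiny_config():
    """Small region: fast to generate, still has both resource kinds."""
    return RegionConfig(n_nodes=40, side_km=10.0, n_homes=60,
                        population_total=5000, n_ambulance_stations=2,
                        n_fire_stations=3)


@pytest.fixture
def tiny_region(tiny_config):
    return generate_region(tiny_config, seed=7)


@pytest.fixture
def single_node_region():
    """Degenerate one-node region: one home of 100 people, one ambulance
    station on the same node, so drive time is exactly zero."""
    return build_region(
        node_xy=[(0.0, 0.0)],
        edges=[],
        homes=[(0, 100)],
        stations=[(0, AMBULANCE, 1.5)],
    )
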