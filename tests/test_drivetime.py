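"""Drive-time fields and reach curves: unit arithmetic, min-over-stations,
binning convention, conservation and structural properties."""

import dataclasses
import math

import numpy as np
import pytest

from emsurv.drivetime import (ReachCurve, ResponseTimeField, build_reach_curve,
                              edge_traversal_minutes, minutes_to_bin,
                              response_time_field)
from emsurv.region import AMBULANCE, FIRE, Station

from conftest import build_region
from _oracles import exhaustive_response_minutes


@pytest.mark.parametrize("length,speed,loc,expected", [
    (1.0, 60.0, False, 1.0),
    (1.0, 60.0, True, 1.25),     # 20% slowdown in built-up areas
    (0.8, 48.0, False, 1.0),
    (2.0, 120.0, True, 1.25),
])
def test_edge_traversal_minutes(length, speed, loc, expected):
    assert edge_traversal_minutes(length, speed, loc) == pytest.approx(expected)


@pytest.mark.parametrize("length,speed", [(0.0, 50.0), (-1.0, 50.0), (1.0, 0.0), (1.0, -5.0)])
def test_edge_traversal_rejects_nonphysical(length, speed):
    with pytest.raises(ValueError):
        edge_traversal_minutes(length, speed, False)


def test_station_on_home_node_gives_pure_reaction_time(single_node_region):
    field = response_time_field(single_node_region, {AMBULANCE})
    assert field.minutes == (1.5,)


def test_min_over_stations_trades_reaction_against_drive():
    """A slow-to-depart station nearby (3 + 1 min) beats a fast one far away
    (1.5 + 4 min)."""
    region = build_region(
        node_xy=[(0, 0), (5, 0), (4, 0)],
        edges=[(0, 2, 4.0, 60.0, False),   # 4 min drive
               (1, 2, 1.0, 60.0, False)],  # 1 min drive
        homes=[(2, 10)],
        stations=[(0, AMBULANCE, 1.5), (1, AMBULANCE, 3.0)],
    )
    field = response_time_field(region, {AMBULANCE})
    assert field.minutes == (4.0,)


def test_dual_dispatch_is_per_home_min_of_single_kind_fields(tiny_region):
    amb = response_time_field(tiny_region, {AMBULANCE})
    fire = response_time_field(tiny_region, {FIRE})
    dual = response_time_field(tiny_region, {AMBULANCE, FIRE})
    assert dual.minutes == tuple(min(a, f) for a, f in zip(amb.minutes, fire.minutes))


def test_unreachable_home_flagged_but_kept():
    """Home in a component with no station carries inf and counts as
    unreached (still in the POP denominator)."""
    region = build_region(
        node_xy=[(0, 0), (1, 0), (10, 10), (11, 10)],
        edges=[(0, 1, 1.0, 60.0, False), (2, 3, 1.0, 60.0, False)],
        homes=[(1, 40), (3, 60)],
        stations=[(0, AMBULANCE, 1.5)],
    )
    field = response_time_field(region, {AMBULANCE})
    assert field.minutes[0] == pytest.approx(2.5)
    assert math.isinf(field.minutes[1])
    curve = build_reach_curve(field, region, n_bins=31)
    assert curve.unreached == 60
    assert sum(curve.b) + curve.unreached == region.pop == 100


def test_empty_or_unstaffed_kinds_rejected(tiny_region, single_node_region):
    with pytest.raises(ValueError):
        response_time_field(tiny_region, set())
    with pytest.raises(ValueError, match="no station"):
        response_time_field(single_node_region, {FIRE})


def test_all_locality_multiplies_pure_drive_times_by_1_25(tiny_region):
    def with_locality(region, flag):
        edges = tuple(e._replace(in_locality=flag) for e in region.network.edges)
        network = dataclasses.replace(region.network, edges=edges)
        stations = tuple(s._replace(reaction_minutes=0.0) for s in region.stations)
        return dataclasses.replace(region, network=network, stations=stations)

    fast = response_time_field(with_locality(tiny_region, False), {AMBULANCE})
    slow = response_time_field(with_locality(tiny_region, True), {AMBULANCE})
    assert np.allclose(np.asarray(slow.minutes), 1.25 * np.asarray(fast.minutes))


def test_adding_a_station_never_slows_any_home(tiny_region):
    base = response_time_field(tiny_region, {AMBULANCE})
    extra_station = Station(999, tiny_region.network.nodes[0].node_id, AMBULANCE, 1.5)
    bigger = dataclasses.replace(tiny_region, stations=tiny_region.stations + (extra_station,))
    more = response_time_field(bigger, {AMBULANCE})
    assert all(m2 <= m1 for m1, m2 in zip(base.minutes, more.minutes))


@pytest.mark.parametrize("seed", range(30))
def test_shortest_path_matches_exhaustive_enumeration_small(seed):
    """Cross-check the Dijkstra field against full simple-path enumeration on
    small random regions (the wide sweep lives in the acceptance suite)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 9))
    xy = rng.uniform(0, 5, size=(n, 2))
    edges = []
    for a in range(n):
        for b in range(a + 1, n):
            if rng.random() < 2.5 / n:
                edges.append((a, b, float(rng.uniform(0.2, 4.0)),
                              float(rng.choice([50, 70, 90])), bool(rng.random() < 0.4)))
    if not edges:
        edges = [(0, min(1, n - 1) or 0, 1.0, 50.0, False)] if n > 1 else []
    if n == 1 or not edges:
        return
    homes = [(i, 1) for i in range(n)]
    stations = [(int(rng.integers(n)), AMBULANCE, float(rng.uniform(0, 3)))
                for _ in range(int(rng.integers(1, 3)))]
    region = build_region(xy.tolist(), edges, homes, stations)
    field = response_time_field(region, {AMBULANCE})
    oracle = exhaustive_response_minutes(region, {AMBULANCE})
    for home_id, minutes in zip(field.home_ids, field.minutes):
        expect = oracle[home_id]
        if math.isinf(expect):
            assert math.isinf(minutes)
        else:
            assert minutes == pytest.approx(expect, rel=1e-9)


# -- binning -----------------------------------------------------------------

@pytest.mark.parametrize("minutes,expected", [
    (0.0, 1), (0.5, 1), (1.0, 1), (1.0001, 2), (2.0, 2), (2.01, 3),
    (31.0, 31), (31.5, 31), (400.0, 31),
])
def test_ceil_binning_on_half_open_intervals(minutes, expected):
    assert minutes_to_bin(minutes, 31) == expected


def test_reach_curve_single_bin_mass():
    region = build_region([(0, 0)], [], homes=[(0, 100)],
                          stations=[(0, AMBULANCE, 0.5)])
    field = response_time_field(region, {AMBULANCE})
    curve = build_reach_curve(field, region, n_bins=31)
    assert curve.b[0] == 100
    assert sum(curve.b) == 100 and curve.unreached == 0


def test_reach_curve_hand_enumerated_three_masses():
    """Times {0.5, 1.5, 40} with inhabitants {10, 20, 5}: bins 1, 2 and the
    terminal bin."""
    region = build_region([(0, 0)], [], homes=[(0, 10), (0, 20), (0, 5)],
                          stations=[(0, AMBULANCE, 0.0)])
    field = ResponseTimeField(kinds=frozenset({AMBULANCE}),
                              home_ids=(0, 1, 2), minutes=(0.5, 1.5, 40.0))
    curve = build_reach_curve(field, region, n_bins=31)
    assert curve.b[0] == 10
    assert curve.b[1] == 20
    assert curve.b[30] == 5
    assert sum(curve.b) + curve.unreached == region.pop == 35


def test_reach_curve_offset_shifts_before_binning():
    region = build_region([(0, 0)], [], homes=[(0, 7)],
                          stations=[(0, AMBULANCE, 1.5)])
    field = response_time_field(region, {AMBULANCE})
    curve = build_reach_curve(field, region, n_bins=31, offset_minutes=5.0)
    assert curve.b[6] == 7  # 1.5 + 5.0 = 6.5 -> bin 7


def test_reach_curve_rejects_inconsistent_totals():
    with pytest.raises(ValueError, match="conserve"):
        ReachCurve(b=(10, 20), pop=100, unreached=5)
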