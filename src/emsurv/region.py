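"""Synthetic region generation: road network, localities, homes and stations.

The survival model needs a regional geography — a drivable road network with
speed limits, the population's homes attached to it (homes are used as the
locations of out-of-hospital cardiac arrests), and ambulance / fire stations
with per-station reaction times.  Real platforms of this kind (national road
databases joined to census population grids) are not redistributable, so this
module generates seeded synthetic regions with the same statistical structure:

* a planar random geometric graph on a square, augmented to connectivity so
  that reachability is a modelling choice rather than an accident of sampling;
* contiguous "locality" clusters of nodes standing in for the census
  settlement concept (built-up areas where emergency vehicles drive ~20%
  slower);
* homes placed preferentially inside localities, with the regional population
  distributed over them (every home has at least one inhabitant);
* stations placed preferentially inside localities; ambulance stations share a
  single reaction time (default 90 s), fire stations are a mixture of
  full-time (90 s) and part-time stations with longer, variable reaction
  times.

Everything is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple
import json
import pathlib

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

AMBULANCE = "ambulance"
FIRE = "fire"
RESOURCE_KINDS = (AMBULANCE, FIRE)


class RoadNode(NamedTuple):
    node_id: int
    x_km: float
    y_km: float


class RoadEdge(NamedTuple):
    node_a: int
    node_b: int
    length_km: float
    speed_kmh: float
    in_locality: bool


class Home(NamedTuple):
    home_id: int
    node_id: int
    inhabitants: int


class Station(NamedTuple):
    station_id: int
    node_id: int
    resource_kind: str
    reaction_minutes: float


@dataclass(frozen=True)
class RoadNetwork:
    """Undirected road network with per-edge speed limits and locality flags."""

    nodes: tuple[RoadNode, ...]
    edges: tuple[RoadEdge, ...]

    def __post_init__(self) -> None:
        ids = {n.node_id for n in self.nodes}
        for e in self.edges:
            if e.length_km <= 0:
                raise ValueError(f"edge ({e.node_a},{e.node_b}) has non-positive length")
            if e.speed_kmh <= 0:
                raise ValueError(f"edge ({e.node_a},{e.node_b}) has non-positive speed limit")
            if e.node_a not in ids or e.node_b not in ids:
                raise ValueError(f"edge ({e.node_a},{e.node_b}) references unknown node")

    @property
    def node_ids(self) -> frozenset[int]:
        return frozenset(n.node_id for n in self.nodes)


@dataclass(frozen=True)
class RegionScenario:
    """A complete synthetic region: geography, population and stations."""

    network: RoadNetwork
    homes: tuple[Home, ...]
    stations: tuple[Station, ...]
    pop: int
    seed: int

    def __post_init__(self) -> None:
        if self.pop != sum(h.inhabitants for h in self.homes):
            raise ValueError("POP must equal the sum of home inhabitants")
        ids = self.network.node_ids
        for h in self.homes:
            if h.inhabitants < 1:
                raise ValueError(f"home {h.home_id} has fewer than 1 inhabitant")
            if h.node_id not in ids:
                raise ValueError(f"home {h.home_id} attached to unknown node {h.node_id}")
        for s in self.stations:
            if s.reaction_minutes < 0:
                raise ValueError(f"station {s.station_id} has negative reaction time")
            if s.node_id not in ids:
                raise ValueError(f"station {s.station_id} attached to unknown node {s.node_id}")
            if s.resource_kind not in RESOURCE_KINDS:
                raise ValueError(f"station {s.station_id} has unknown kind {s.resource_kind!r}")

    def stations_of(self, kind: str) -> tuple[Station, ...]:
        return tuple(s for s in self.stations if s.resource_kind == kind)


@dataclass(frozen=True)
class RegionConfig:
    """Parameters of the synthetic-region generator.

    ``side_km`` and ``target_degree`` control the geometric graph (nodes are
    uniform on a ``side_km`` x ``side_km`` square; pairs closer than a radius
    chosen to give the target mean degree are joined).  ``locality_fraction``
    of the nodes is flagged as built-up localities, grown as contiguous
    clusters.  Home and station placement favour locality nodes by the given
    multiplicative weights, emulating urban population concentration.
    """

    n_nodes: int = 900
    side_km: float = 80.0
    target_degree: float = 3.5
    locality_fraction: float = 0.35
    n_homes: int = 3000
    population_total: int = 1_949_516
    n_ambulance_stations: int = 30
    n_fire_stations: int = 43
    ambulance_reaction_minutes: float = 1.5
    fire_fulltime_fraction: float = 0.5
    fire_fulltime_reaction_minutes: float = 1.5
    fire_parttime_reaction_range: tuple[float, float] = (3.0, 7.0)
    locality_speeds_kmh: tuple[float, ...] = (50.0, 70.0)
    locality_speed_weights: tuple[float, ...] = (0.8, 0.2)
    rural_speeds_kmh: tuple[float, ...] = (70.0, 90.0, 110.0)
    rural_speed_weights: tuple[float, ...] = (0.5, 0.35, 0.15)
    locality_home_weight: float = 4.0
    locality_station_weight: float = 4.0

    def validate(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("config needs at least one network node")
        if self.n_homes < 1:
            raise ValueError("config needs at least one home")
        if self.population_total < self.n_homes:
            raise ValueError("population_total must be >= n_homes (every home houses >= 1 person)")
        if self.n_ambulance_stations < 0 or self.n_fire_stations < 0:
            raise ValueError("station counts must be non-negative")
        if self.n_ambulance_stations + self.n_fire_stations < 1:
            raise ValueError("config needs at least one station of some kind")
        if not 0 <= self.locality_fraction <= 1:
            raise ValueError("locality_fraction must lie in [0, 1]")
        lo, hi = self.fire_parttime_reaction_range
        if lo < 0 or hi < lo:
            raise ValueError("fire_parttime_reaction_range must be 0 <= lo <= hi")
        if not 0 <= self.fire_fulltime_fraction <= 1:
            raise ValueError("fire_fulltime_fraction must lie in [0, 1]")


def stockholm_like_config() -> RegionConfig:
    """Default configuration emulating the County of Stockholm study region.

    Population total (1 949 516 on 31 Dec 2007), the 43 fire stations and the
    90 s ambulance reaction time are the study-region values; the ambulance
    station count (30) and the synthetic network size are generator choices,
    since no public station-level dataset accompanies them.
    """
    return RegionConfig()


def _connection_radius(cfg: RegionConfig) -> float:
    # mean degree of a geometric graph ~ n * pi * r^2 / side^2
    return float(np.sqrt(cfg.target_degree * cfg.side_km**2 / (np.pi * max(cfg.n_nodes, 1))))


def _grow_localities(n: int, adjacency: list[list[int]], n_locality: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Flag ``n_locality`` nodes as locality members, grown as contiguous BFS
    clusters from random seed nodes (approximating census built-up areas)."""
    flag = np.zeros(n, dtype=bool)
    if n_locality <= 0:
        return flag
    n_clusters = max(1, round(n_locality / 60))
    seeds = rng.choice(n, size=min(n_clusters, n), replace=False)
    frontier = list(seeds)
    flagged = 0
    idx = 0
    while flagged < n_locality:
        if idx >= len(frontier):
            # graph exhausted (disconnected leftovers): seed a fresh node
            remaining = np.flatnonzero(~flag)
            frontier.append(int(rng.choice(remaining)))
        node = frontier[idx]
        idx += 1
        if flag[node]:
            continue
        flag[node] = True
        flagged += 1
        for nb in adjacency[node]:
            if not flag[nb]:
                frontier.append(nb)
    return flag


def generate_region(config: RegionConfig, seed: int) -> RegionScenario:
    """Generate a synthetic region; deterministic in ``(config, seed)``."""
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n_nodes

    xy = rng.uniform(0.0, config.side_km, size=(n, 2))
    nodes = tuple(RoadNode(i, float(xy[i, 0]), float(xy[i, 1])) for i in range(n))

    pairs: list[tuple[int, int]] = []
    if n > 1:
        tree = cKDTree(xy)
        pairs = sorted((int(a), int(b)) for a, b in tree.query_pairs(_connection_radius(config)))

    # union-find to bridge disconnected components with their nearest outside node
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(a: int, b: int) -> None:
        parent[find(a)] = find(b)

    for a, b in pairs:
        union(a, b)
    roots = {find(i) for i in range(n)}
    while len(roots) > 1:
        comp_of = np.array([find(i) for i in range(n)])
        smallest = min(roots, key=lambda r: (int(np.sum(comp_of == r)), r))
        inside = np.flatnonzero(comp_of == smallest)
        outside = np.flatnonzero(comp_of != smallest)
        d = np.linalg.norm(xy[inside][:, None, :] - xy[outside][None, :, :], axis=2)
        i, j = np.unravel_index(int(np.argmin(d)), d.shape)
        a, b = int(inside[i]), int(outside[j])
        pairs.append((min(a, b), max(a, b)))
        union(a, b)
        roots = {find(i) for i in range(n)}

    adjacency: list[list[int]] = [[] for _ in range(n)]
    for a, b in pairs:
        adjacency[a].append(b)
        adjacency[b].append(a)

    in_locality = _grow_localities(n, adjacency, round(config.locality_fraction * n), rng)

    edges = []
    for a, b in pairs:
        length = float(max(np.linalg.norm(xy[a] - xy[b]), 0.05))
        loc = bool(in_locality[a] and in_locality[b])
        if loc:
            speed = float(rng.choice(config.locality_speeds_kmh,
                                     p=np.asarray(config.locality_speed_weights)
                                     / np.sum(config.locality_speed_weights)))
        else:
            speed = float(rng.choice(config.rural_speeds_kmh,
                                     p=np.asarray(config.rural_speed_weights)
                                     / np.sum(config.rural_speed_weights)))
        edges.append(RoadEdge(a, b, length, speed, loc))

    node_weight = np.where(in_locality, config.locality_home_weight, 1.0)
    home_nodes = rng.choice(n, size=config.n_homes, p=node_weight / node_weight.sum())
    extra = rng.multinomial(config.population_total - config.n_homes,
                            np.full(config.n_homes, 1.0 / config.n_homes))
    homes = tuple(Home(i, int(home_nodes[i]), int(1 + extra[i]))
                  for i in range(config.n_homes))

    station_weight = np.where(in_locality, config.locality_station_weight, 1.0)
    n_stations = config.n_ambulance_stations + config.n_fire_stations
    if n_stations <= n:
        station_nodes = rng.choice(n, size=n_stations, replace=False,
                                   p=station_weight / station_weight.sum())
    else:
        station_nodes = rng.choice(n, size=n_stations, replace=True,
                                   p=station_weight / station_weight.sum())
    stations = []
    sid = 0
    for _ in range(config.n_ambulance_stations):
        stations.append(Station(sid, int(station_nodes[sid]), AMBULANCE,
                                config.ambulance_reaction_minutes))
        sid += 1
    n_fulltime = round(config.fire_fulltime_fraction * config.n_fire_stations)
    lo, hi = config.fire_parttime_reaction_range
    for k in range(config.n_fire_stations):
        if k < n_fulltime:
            reaction = config.fire_fulltime_reaction_minutes
        else:
            reaction = float(rng.uniform(lo, hi))
        stations.append(Station(sid, int(station_nodes[sid]), FIRE, reaction))
        sid += 1

    return RegionScenario(
        network=RoadNetwork(nodes=nodes, edges=tuple(edges)),
        homes=homes,
        stations=tuple(stations),
        pop=config.population_total,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# On-disk representation: one CSV per entity plus a JSON manifest.

REGION_FILES = ("nodes.csv", "edges.csv", "homes.csv", "stations.csv")


def write_region(scenario: RegionScenario, outdir: str | pathlib.Path) -> list[pathlib.Path]:
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    frames = {
        "nodes.csv": pd.DataFrame(scenario.network.nodes,
                                  columns=["node_id", "x_km", "y_km"]),
        "edges.csv": pd.DataFrame(scenario.network.edges,
                                  columns=["node_a", "node_b", "length_km",
                                           "speed_kmh", "in_locality"]),
        "homes.csv": pd.DataFrame(scenario.homes,
                                  columns=["home_id", "node_id", "inhabitants"]),
        "stations.csv": pd.DataFrame(scenario.stations,
                                     columns=["station_id", "node_id",
                                              "resource_kind", "reaction_minutes"]),
    }
    for name, frame in frames.items():
        path = outdir / name
        frame.to_csv(path, index=False, float_format="%.17g")  # exact round-trip
        written.append(path)
    manifest = {"seed": scenario.seed, "pop": scenario.pop, "files": list(frames)}
    mpath = outdir / "region_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2) + "\n")
    written.append(mpath)
    return written


def read_region(indir: str | pathlib.Path) -> RegionScenario:
    indir = pathlib.Path(indir)
    nodes = pd.read_csv(indir / "nodes.csv", float_precision="round_trip")
    edges = pd.read_csv(indir / "edges.csv", float_precision="round_trip")
    homes = pd.read_csv(indir / "homes.csv")
    stations = pd.read_csv(indir / "stations.csv", float_precision="round_trip")
    manifest = json.loads((indir / "region_manifest.json").read_text())
    network = RoadNetwork(
        nodes=tuple(RoadNode(int(r.node_id), float(r.x_km), float(r.y_km))
                    for r in nodes.itertuples()),
        edges=tuple(RoadEdge(int(r.node_a), int(r.node_b), float(r.length_km),
                             float(r.speed_kmh), bool(r.in_locality))
                    for r in edges.itertuples()),
    )
    return RegionScenario(
        network=network,
        homes=tuple(Home(int(r.home_id), int(r.node_id), int(r.inhabitants))
                    for r in homes.itertuples()),
        stations=tuple(Station(int(r.station_id), int(r.node_id), str(r.resource_kind),
                               float(r.reaction_minutes))
                       for r in stations.itertuples()),
        pop=int(manifest["pop"]),
        seed=int(manifest["seed"]),
    )
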