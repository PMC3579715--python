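"""Independent brute-force oracles used by the test suite.

The shortest-path oracle enumerates every simple path between a station node
and a home node and sums edge traversal times itself, so it shares no code
path with the Dijkstra-based implementation it checks (only the path listing
comes from networkx).
"""

import math

import networkx as nx

from emsurv.drivetime import edge_traversal_minutes


def edge_minutes_graph(region):
    """Plain adjacency with per-edge traversal minutes (parallel edges keep
    the fastest)."""
    g = nx.Graph()
    g.add_nodes_from(n.node_id for n in region.network.nodes)
    for e in region.network.edges:
        m = edge_traversal_minutes(e.length_km, e.speed_kmh, e.in_locality)
        if g.has_edge(e.node_a, e.node_b):
            m = min(m, g[e.node_a][e.node_b]["m"])
        g.add_edge(e.node_a, e.node_b, m=m)
    return g


def exhaustive_drive_minutes(g, source, target):
    """Min total traversal minutes over all simple paths; inf if unconnected."""
    if source == target:
        return 0.0
    best = math.inf
    for path in nx.all_simple_paths(g, source, target):
        total = sum(g[a][b]["m"] for a, b in zip(path, path[1:]))
        best = min(best, total)
    return best


def exhaustive_response_minutes(region, kinds):
    """Per-home best (reaction + drive) minutes by full path enumeration."""
    g = edge_minutes_graph(region)
    stations = [s for s in region.stations if s.resource_kind in kinds]
    out = {}
    for home in region.homes:
        best = math.inf
        for s in stations:
            drive = exhaustive_drive_minutes(g, s.node_id, home.node_id)
            best = min(best, s.reaction_minutes + drive)
        out[home.home_id] = best
    return out
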