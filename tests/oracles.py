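"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: plain loops, an
explicit Dijkstra over an augmented graph, and a hand-rolled BFS.
"""

import heapq
import math


def brute_force_euclidean(origin, providers, category):
    cands = [
        (math.hypot(p.x - origin[0], p.y - origin[1]), p.provider_id)
        for p in providers
        if p.category == category
    ]
    return min(cands)[1]


def brute_force_radius(origin, providers, category, radius_m):
    return {
        p.provider_id
        for p in providers
        if p.category == category
        and math.hypot(p.x - origin[0], p.y - origin[1]) <= radius_m
    }


def dijkstra_travel_time(origin, dest, network, speeds):
    """Shortest travel time via an augmented graph: origin and destination
    are temporary nodes connected to their nearest network node by an
    off-road walk edge and to each other by a direct walk edge."""

    def walk_minutes(meters):
        return meters / 1000.0 / speeds.offroad_walk_kmh * 60.0

    adj = {n: [] for n in network.nodes}
    for a, b, length_m, cls_ in network.edges:
        minutes = length_m / 1000.0 / speeds.speeds_kmh[cls_] * 60.0
        adj[a].append((b, minutes))
        adj[b].append((a, minutes))
    adj["__o__"], adj["__d__"] = [], []

    def nearest_node(pt):
        return min(network.nodes, key=lambda n: math.dist(network.nodes[n], pt))

    o_snap, d_snap = nearest_node(origin), nearest_node(dest)
    adj["__o__"].append((o_snap, walk_minutes(math.dist(origin, network.nodes[o_snap]))))
    adj[d_snap].append(("__d__", walk_minutes(math.dist(dest, network.nodes[d_snap]))))
    adj["__o__"].append(("__d__", walk_minutes(math.dist(origin, dest))))

    dist = {"__o__": 0.0}
    heap = [(0.0, "__o__")]
    while heap:
        d, u = heapq.heappop(heap)
        if u == "__d__":
            return d
        if d > dist.get(u, math.inf):
            continue
        for v, w in adj[u]:
            nd = d + w
            if nd < dist.get(v, math.inf):
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    return math.inf


def brute_force_travel_time_link(origin, providers, category, network, speeds):
    cands = []
    for p in providers:
        if p.category != category:
            continue
        t = dijkstra_travel_time(origin, (p.x, p.y), network, speeds)
        d = math.hypot(p.x - origin[0], p.y - origin[1])
        cands.append((t, d, p.provider_id))
    return min(cands)[2]


def bfs_connected(network):
    adj = {n: set() for n in network.nodes}
    for a, b, _, _ in network.edges:
        adj[a].add(b)
        adj[b].add(a)
    start = next(iter(network.nodes))
    seen = {start}
    frontier = [start]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    nxt.append(v)
        frontier = nxt
    return len(seen) == len(network.nodes)
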