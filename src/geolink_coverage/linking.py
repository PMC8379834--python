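"""Ecological linking of sick children to providers by geographic proximity.

Three linking methods, each restricted to the reported provider category:

* ``euclidean`` — the single closest provider by planar distance;
* ``travel_time`` — the single closest by road-network travel time, with
  off-road walking to/from the nearest network node;
* ``radius_5km`` — all category providers within a fixed radius
  (an isotropic ~1-hour-walk buffer), possibly none.

Neither single-closest method caps the link distance, so they always link;
the radius method may leave a child unlinked. Origins can be household
locations, cluster central points, or displaced central points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Optional, Sequence

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .config import SpeedTable

if TYPE_CHECKING:  # pragma: no cover
    from .clusters import ClusterPoint
    from .landscape import CareSeekingEvent, Landscape, ProviderAssessment, RoadNetwork

METHODS = ("euclidean", "travel_time", "radius_5km")

LOCATION_SOURCES = ("household", "central_point")  # plus displaced_A..E


@dataclass(frozen=True)
class LinkAssignment:
    """Linking outcome for one event from one origin with one method.

    ``linked_ids`` is aligned with the event's reported sources: each
    entry holds the provider ids that source was linked to (a singleton
    for the single-closest methods, possibly empty for the radius
    method). ``linked_true`` is None when no reported source has a known
    true provider.
    """

    event_id: str
    location_source: str
    method: str
    source_categories: tuple[str, ...]
    linked_ids: tuple[tuple[str, ...], ...]
    linked_any: bool
    linked_true: Optional[bool]
    fallback_used: bool = False


def _euclid(a: tuple[float, float], b: tuple[float, float]) -> float:
    return math.dist(a, b)


def euclidean_link(
    origin: tuple[float, float],
    providers: Iterable["ProviderAssessment"],
    category: str,
) -> str:
    """Closest provider of the category by planar distance; distance ties
    broken by smallest provider id."""
    best = None
    for p in providers:
        if p.category != category:
            continue
        key = (_euclid(origin, (p.x, p.y)), p.provider_id)
        if best is None or key < best:
            best = key
    if best is None:
        raise ValueError(f"no provider of category {category!r}")
    return best[1]


def radius_link(
    origin: tuple[float, float],
    providers: Iterable["ProviderAssessment"],
    category: str,
    radius_m: float = 5000.0,
) -> set[str]:
    """All category providers within radius_m (boundary inclusive)."""
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    return {
        p.provider_id
        for p in providers
        if p.category == category and _euclid(origin, (p.x, p.y)) <= radius_m
    }


class TravelTimeEngine:
    """Shortest-path travel times over a road network.

    Origins and destinations snap to their single nearest network node
    (walking off-road at a constant speed); travel time is the walk to
    the snap node, the shortest path over the network with per-class
    speeds, and the walk from the destination's snap node. Shortest-path
    trees are cached per snap node, so repeated queries from the same
    neighbourhood are cheap.
    """

    def __init__(self, network: "RoadNetwork", speeds: SpeedTable):
        speeds.validate()
        self.network = network
        self.speeds = speeds
        self.graph = nx.Graph()
        for nid, (x, y) in network.nodes.items():
            self.graph.add_node(nid, x=x, y=y)
        for a, b, length_m, cls_ in network.edges:
            minutes = (length_m / 1000.0) / speeds.speeds_kmh[cls_] * 60.0
            # Keep the faster edge if duplicates occur.
            if self.graph.has_edge(a, b):
                minutes = min(minutes, self.graph[a][b]["minutes"])
            self.graph.add_edge(a, b, minutes=minutes, length_m=length_m, road_class=cls_)
        self._node_ids = list(network.nodes)
        coords = np.array([network.nodes[n] for n in self._node_ids])
        self._tree = cKDTree(coords)
        self._sp_cache: dict[str, dict[str, float]] = {}

    def _walk_minutes(self, meters: float) -> float:
        return (meters / 1000.0) / self.speeds.offroad_walk_kmh * 60.0

    def snap(self, point: tuple[float, float]) -> tuple[str, float]:
        """Nearest network node and the walk time to it (minutes)."""
        dist, idx = self._tree.query(point)
        return self._node_ids[int(idx)], self._walk_minutes(float(dist))

    def _times_from(self, node: str) -> dict[str, float]:
        if node not in self._sp_cache:
            self._sp_cache[node] = nx.single_source_dijkstra_path_length(
                self.graph, node, weight="minutes"
            )
        return self._sp_cache[node]

    def travel_time(self, origin: tuple[float, float], dest: tuple[float, float]) -> float:
        """Door-to-door travel time in minutes.

        The route is the faster of (a) walking off-road straight to the
        destination and (b) walking to the origin's snap node, taking the
        network shortest path, and walking from the destination's snap
        node — without (a), sub-grid-scale trips would absurdly detour
        via the network. Infinite only if the snap nodes lie in different
        components and the walk is infinite (never, for finite points).
        """
        direct = self._walk_minutes(_euclid(origin, dest))
        if direct == 0.0:
            return 0.0
        o_node, o_walk = self.snap(origin)
        d_node, d_walk = self.snap(dest)
        times = self._times_from(o_node)
        if d_node not in times:
            return direct
        return min(direct, o_walk + times[d_node] + d_walk)


def travel_time(
    origin: tuple[float, float],
    dest: tuple[float, float],
    network: "RoadNetwork",
    speeds: SpeedTable,
) -> float:
    """Functional form of :meth:`TravelTimeEngine.travel_time`."""
    return TravelTimeEngine(network, speeds).travel_time(origin, dest)


def travel_time_link(
    origin: tuple[float, float],
    providers: Iterable["ProviderAssessment"],
    category: str,
    network: "RoadNetwork" = None,
    speeds: SpeedTable | None = None,
    engine: TravelTimeEngine | None = None,
) -> str:
    """Closest provider of the category by travel time; ties broken by
    smaller Euclidean distance, then provider id. Falls back to Euclidean
    linking if every provider is unreachable."""
    pid, _ = _travel_time_link_ex(origin, providers, category, network, speeds, engine)
    return pid


def _travel_time_link_ex(
    origin, providers, category, network=None, speeds=None, engine=None
) -> tuple[str, bool]:
    if engine is None:
        if network is None:
            raise ValueError("either a network or an engine is required")
        engine = TravelTimeEngine(network, speeds or SpeedTable())
    best = None
    for p in providers:
        if p.category != category:
            continue
        t = engine.travel_time(origin, (p.x, p.y))
        key = (t, _euclid(origin, (p.x, p.y)), p.provider_id)
        if best is None or key < best:
            best = key
    if best is None:
        raise ValueError(f"no provider of category {category!r}")
    if math.isinf(best[0]):
        return euclidean_link(origin, providers, category), True
    return best[2], False


# ---------------------------------------------------------------------------
# Event-level linking


def _origin_for_event(
    event: "CareSeekingEvent",
    landscape: "Landscape",
    hh_to_cluster: dict[str, "ClusterPoint"] | None,
    location_source: str,
) -> tuple[float, float]:
    if location_source == "household":
        hh = landscape.household_by_id(event.household_id)
        return (hh.x, hh.y)
    if hh_to_cluster is None or event.household_id not in hh_to_cluster:
        raise ValueError(
            f"no cluster mapping for household {event.household_id!r} "
            f"(location source {location_source!r})"
        )
    cl = hh_to_cluster[event.household_id]
    if location_source == "central_point":
        return (cl.x, cl.y)
    if location_source.startswith("displaced_"):
        label = location_source.split("_", 1)[1]
        if label not in cl.displaced:
            raise ValueError(f"cluster {cl.cluster_id} has no displaced replicate {label!r}")
        return cl.displaced[label]
    raise ValueError(f"unknown location source {location_source!r}")


def link_events(
    events: Sequence["CareSeekingEvent"],
    landscape: "Landscape",
    clusters: Sequence["ClusterPoint"] | None,
    location_source: str,
    method: str,
    speeds: SpeedTable | None = None,
    radius_m: float = 5000.0,
    engine: TravelTimeEngine | None = None,
) -> list[LinkAssignment]:
    """Link every care-seeking event from one location source with one
    method; events where no care was sought produce no assignment.

    Multi-source events are linked independently per reported source from
    the same origin. ``linked_true`` requires every source with a known
    true provider to be linked to exactly that provider (single-closest
    methods) or to a set containing it (radius).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    hh_to_cluster = None
    if location_source != "household":
        if clusters is None:
            raise ValueError("cluster points are required for non-household location sources")
        hh_to_cluster = {}
        for cl in clusters:
            for hid in cl.member_household_ids:
                hh_to_cluster[hid] = cl
    if method == "travel_time" and engine is None:
        engine = TravelTimeEngine(landscape.roads, speeds or SpeedTable())

    out: list[LinkAssignment] = []
    for event in events:
        if not event.care_sought:
            continue
        origin = _origin_for_event(event, landscape, hh_to_cluster, location_source)
        linked: list[tuple[str, ...]] = []
        fallback = False
        for src in event.sources:
            if method == "euclidean":
                linked.append((euclidean_link(origin, landscape.providers, src.category),))
            elif method == "travel_time":
                pid, fb = _travel_time_link_ex(
                    origin, landscape.providers, src.category, engine=engine
                )
                fallback = fallback or fb
                linked.append((pid,))
            else:
                ids = radius_link(origin, landscape.providers, src.category, radius_m)
                linked.append(tuple(sorted(ids)))
        known = [
            (src.true_provider_id, ids)
            for src, ids in zip(event.sources, linked)
            if src.true_provider_id is not None
        ]
        linked_true: Optional[bool]
        if not known:
            linked_true = None
        elif method == "radius_5km":
            linked_true = all(pid in ids for pid, ids in known)
        else:
            linked_true = all(ids == (pid,) for pid, ids in known)
        out.append(
            LinkAssignment(
                event_id=event.event_id,
                location_source=location_source,
                method=method,
                source_categories=tuple(s.category for s in event.sources),
                linked_ids=tuple(linked),
                linked_any=any(len(ids) > 0 for ids in linked),
                linked_true=linked_true,
                fallback_used=fallback,
            )
        )
    return out
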