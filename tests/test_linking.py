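import math

import numpy as np
import pytest

from geolink_coverage.clusters import displace_replicates, form_clusters
from geolink_coverage.config import DisplacementConfig, SpeedTable
from geolink_coverage.landscape import ProviderAssessment, RoadNetwork
from geolink_coverage.linking import (
    TravelTimeEngine,
    euclidean_link,
    link_events,
    radius_link,
    travel_time,
    travel_time_link,
)
from geolink_coverage.quality import BINARY_DOMAINS

from .oracles import (
    brute_force_euclidean,
    brute_force_radius,
    brute_force_travel_time_link,
    dijkstra_travel_time,
)


def provider(pid, x, y, category="pharmacy"):
    return ProviderAssessment(
        provider_id=pid, x=x, y=y, category=category,
        indicators={d: [1] * n for d, n in BINARY_DOMAINS.items()},
        knowledge_score=1.0,
    )


def random_providers(rng, n=50, extent=20000.0, categories=("pharmacy", "shop_market")):
    return [
        provider(f"P{i:03d}", float(rng.uniform(0, extent)), float(rng.uniform(0, extent)),
                 categories[i % len(categories)])
        for i in range(n)
    ]


SPEEDS = SpeedTable()


def line_network(length_m=6000.0, cls_="paved"):
    return RoadNetwork(
        nodes={"A": (0.0, 0.0), "B": (length_m, 0.0)},
        edges=[("A", "B", length_m, cls_)],
    )


# -- euclidean -------------------------------------------------------------


def test_euclidean_link_exact_location_and_hand_distances():
    ps = [provider("P1", 3, 4), provider("P2", 6, 8)]
    assert euclidean_link((3, 4), ps, "pharmacy") == "P1"
    assert euclidean_link((0, 0), ps, "pharmacy") == "P1"  # 5 < 10
    with pytest.raises(ValueError, match="traditional_faith"):
        euclidean_link((0, 0), ps, "traditional_faith")


def test_euclidean_tie_breaks_by_provider_id():
    ps = [provider("P9", 10, 0), provider("P1", -10, 0)]
    assert euclidean_link((0, 0), ps, "pharmacy") == "P1"


def test_euclidean_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(0)
    ps = random_providers(rng)
    for _ in range(100):
        origin = tuple(rng.uniform(0, 20000, 2))
        cat = "pharmacy" if rng.random() < 0.5 else "shop_market"
        assert euclidean_link(origin, ps, cat) == brute_force_euclidean(origin, ps, cat)


# -- travel time -----------------------------------------------------------


def test_travel_time_zero_for_same_point():
    assert travel_time((5.0, 5.0), (5.0, 5.0), line_network(), SPEEDS) == 0.0


def test_travel_time_paved_edge_is_length_over_speed():
    # 6 km at 60 km/h -> 6 minutes, faster than the 90-minute direct walk
    t = travel_time((0.0, 0.0), (6000.0, 0.0), line_network(), SPEEDS)
    assert t == pytest.approx(6.0)


def test_travel_time_symmetric():
    net = line_network()
    a, b = (100.0, 300.0), (5800.0, -200.0)
    assert travel_time(a, b, net, SPEEDS) == pytest.approx(travel_time(b, a, net, SPEEDS))


def test_travel_time_matches_augmented_graph_dijkstra(default_landscape):
    net = default_landscape.roads
    engine = TravelTimeEngine(net, SPEEDS)
    rng = np.random.default_rng(1)
    for _ in range(50):
        o = tuple(rng.uniform(0, 24000, 2))
        d = tuple(rng.uniform(0, 16000, 2))
        assert engine.travel_time(o, d) == pytest.approx(
            dijkstra_travel_time(o, d, net, SPEEDS), abs=1e-9
        )


def test_road_quality_beats_distance():
    # A: 2 km footpath (24 min); B: 10 km paved (10 min) -> B wins
    net = RoadNetwork(
        nodes={"O": (0.0, 0.0), "A": (2000.0, 0.0), "B": (-10000.0, 0.0)},
        edges=[("O", "A", 2000.0, "footpath"), ("O", "B", 10000.0, "paved")],
    )
    ps = [provider("PA", 2000.0, 0.0), provider("PB", -10000.0, 0.0)]
    assert travel_time_link((0.0, 0.0), ps, "pharmacy", network=net, speeds=SPEEDS) == "PB"


def test_far_network_reduces_travel_time_link_to_euclidean():
    # network so remote that every trip is a direct off-road walk
    net = RoadNetwork(
        nodes={"X": (1e7, 1e7), "Y": (1e7 + 1000.0, 1e7)},
        edges=[("X", "Y", 1000.0, "footpath")],
    )
    rng = np.random.default_rng(2)
    ps = random_providers(rng, n=20)
    for _ in range(20):
        origin = tuple(rng.uniform(0, 20000, 2))
        assert travel_time_link(origin, ps, "pharmacy", network=net, speeds=SPEEDS) == \
            euclidean_link(origin, ps, "pharmacy")


def test_travel_time_link_matches_brute_force(default_landscape):
    net = default_landscape.roads
    engine = TravelTimeEngine(net, SPEEDS)
    rng = np.random.default_rng(3)
    ps = random_providers(rng, n=30, extent=16000.0)
    for _ in range(100):
        origin = tuple(rng.uniform(0, 16000, 2))
        cat = "pharmacy" if rng.random() < 0.5 else "shop_market"
        assert travel_time_link(origin, ps, cat, engine=engine) == \
            brute_force_travel_time_link(origin, ps, cat, net, SPEEDS)


# -- radius ----------------------------------------------------------------


def test_radius_boundary_inclusive():
    ps = [provider("IN", 4999.0, 0.0), provider("OUT", 5001.0, 0.0)]
    assert radius_link((0, 0), ps, "pharmacy", 5000.0) == {"IN"}
    assert radius_link((0, 0), [provider("FAR", 9000.0, 0.0)], "pharmacy", 5000.0) == set()


def test_radius_matches_brute_force_and_is_monotone():
    rng = np.random.default_rng(4)
    ps = random_providers(rng)
    for _ in range(100):
        origin = tuple(rng.uniform(0, 20000, 2))
        cat = "pharmacy" if rng.random() < 0.5 else "shop_market"
        r = float(rng.uniform(1000, 10000))
        got = radius_link(origin, ps, cat, r)
        assert got == brute_force_radius(origin, ps, cat, r)
        assert got <= radius_link(origin, ps, cat, r + 2000.0)


# -- event-level linking ---------------------------------------------------


@pytest.fixture(scope="module")
def linked_setup(small_landscape, small_events):
    clusters = form_clusters(small_landscape.households, cluster_size=50, seed=1)
    clusters = displace_replicates(
        clusters, DisplacementConfig(), small_landscape.admin_polygon, seed=2
    )
    return small_landscape, small_events, clusters


@pytest.mark.parametrize("method", ["euclidean", "travel_time", "radius_5km"])
@pytest.mark.parametrize("source", ["household", "central_point", "displaced_C"])
def test_linked_providers_always_match_reported_category(linked_setup, method, source):
    land, events, clusters = linked_setup
    cat_of = {p.provider_id: p.category for p in land.providers}
    links = link_events(events, land, clusters, source, method)
    n_care = sum(e.care_sought for e in events)
    assert len(links) == n_care  # no rows for children who sought no care
    ev = {e.event_id: e for e in events}
    for l in links:
        for src, ids in zip(ev[l.event_id].sources, l.linked_ids):
            for pid in ids:
                assert cat_of[pid] == src.category
        if method in ("euclidean", "travel_time"):
            assert l.linked_any and all(len(ids) == 1 for ids in l.linked_ids)


def test_single_closest_methods_link_every_child(linked_setup):
    land, events, clusters = linked_setup
    for method in ("euclidean", "travel_time"):
        links = link_events(events, land, clusters, "household", method)
        assert all(l.linked_any for l in links)


def test_missing_cluster_mapping_is_an_error(linked_setup):
    land, events, _ = linked_setup
    with pytest.raises(ValueError, match="cluster"):
        link_events(events, land, [], "central_point", "euclidean")
    with pytest.raises(ValueError, match="cluster"):
        link_events(events, land, None, "central_point", "euclidean")


def test_linked_true_from_household_with_deterministic_nearest(small_landscape):
    from geolink_coverage.config import CATEGORIES, BehaviorConfig
    from geolink_coverage.landscape import simulate_careseeking

    beh = BehaviorConfig(
        p_nearest=1.0,
        p_multi_source_by_stratum={"rural": 0.0, "urban": 0.0},
        p_unrecalled_by_category={c: 0.0 for c in CATEGORIES},
    )
    events = simulate_careseeking(small_landscape, beh, seed=31)
    links = link_events(events, small_landscape, None, "household", "euclidean")
    assert links and all(l.linked_true for l in links)


def test_origin_perturbation_changes_link_distance_lipschitzly():
    rng = np.random.default_rng(5)
    ps = random_providers(rng, n=10)
    origin = (5000.0, 5000.0)
    pid = euclidean_link(origin, ps, "pharmacy")
    p = next(q for q in ps if q.provider_id == pid)
    d0 = math.dist(origin, (p.x, p.y))
    for _ in range(20):
        delta = rng.uniform(-500, 500, 2)
        moved = (origin[0] + delta[0], origin[1] + delta[1])
        d1 = math.dist(moved, (p.x, p.y))
        assert abs(d1 - d0) <= np.linalg.norm(delta) + 1e-9
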