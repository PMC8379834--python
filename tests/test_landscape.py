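import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point

from geolink_coverage.config import (
    CATEGORIES,
    BehaviorConfig,
    LandscapeConfig,
    QualityProfile,
)
from geolink_coverage.io import events_to_frame, households_to_frame, providers_to_frame
from geolink_coverage.landscape import (
    generate_landscape,
    generate_provider_indicators,
    generate_road_network,
    simulate_careseeking,
)
from geolink_coverage.linking import euclidean_link

from .conftest import small_landscape_config
from .oracles import bfs_connected


def test_zero_households_yields_valid_empty_landscape():
    cfg = small_landscape_config(n_households_by_stratum={"rural": 0, "urban": 0})
    land = generate_landscape(cfg, seed=0)
    assert land.households == []
    assert len(land.providers) > 0
    assert bfs_connected(land.roads)


def test_default_config_reproduces_enrolled_household_counts(default_landscape):
    by_stratum = {"rural": 0, "urban": 0}
    for h in default_landscape.households:
        by_stratum[h.stratum] += 1
    assert by_stratum == {"rural": 335, "urban": 469}
    assert len(default_landscape.households) == 804


def test_generation_is_deterministic_and_seed_sensitive():
    cfg = small_landscape_config()
    a = generate_landscape(cfg, seed=3)
    b = generate_landscape(cfg, seed=3)
    pd.testing.assert_frame_equal(households_to_frame(a.households), households_to_frame(b.households))
    pd.testing.assert_frame_equal(providers_to_frame(a.providers), providers_to_frame(b.providers))
    assert a.roads.nodes == b.roads.nodes and a.roads.edges == b.roads.edges
    c = generate_landscape(cfg, seed=4)
    assert households_to_frame(a.households)["x"].tolist() != households_to_frame(c.households)["x"].tolist()


def test_all_points_inside_admin_and_rural_sparser_than_urban(default_landscape):
    land = default_landscape
    for h in land.households:
        assert land.admin_polygon.covers(Point(h.x, h.y))
    for p in land.providers:
        assert land.admin_polygon.covers(Point(p.x, p.y))
    dens = {}
    for stratum in ("rural", "urban"):
        n = sum(h.stratum == stratum for h in land.households)
        dens[stratum] = n / land.strata_extents[stratum].area
    assert dens["rural"] < dens["urban"]


def test_children_per_household_between_one_and_three(default_landscape):
    kids = [h.n_children_u5 for h in default_landscape.households]
    assert min(kids) >= 1 and max(kids) <= 3


def test_missing_provider_category_is_a_configuration_error():
    cfg = small_landscape_config(
        n_providers={
            cat: ({"rural": 0, "urban": 0} if cat == "govt_health_center_post"
                  else {"rural": 2, "urban": 2})
            for cat in CATEGORIES
        }
    )
    with pytest.raises(ValueError, match="govt_health_center_post"):
        cfg.validate()


# -- road network ----------------------------------------------------------


def test_degenerate_extents_rejected():
    cfg = LandscapeConfig()
    cfg.width_m = 0.0
    with pytest.raises(ValueError, match="degenerate|positive"):
        generate_road_network(cfg, seed=0)


def test_road_network_is_connected_with_all_three_classes(default_landscape):
    roads = default_landscape.roads
    assert bfs_connected(roads)
    classes = {cls_ for _, _, _, cls_ in roads.edges}
    assert classes == {"paved", "graded", "footpath"}
    roads.validate()  # edge lengths consistent with node coordinates


def test_every_point_within_offroad_cap_of_a_node():
    cfg = LandscapeConfig()
    roads = generate_road_network(cfg, seed=1)
    nodes = np.array(list(roads.nodes.values()))
    rng = np.random.default_rng(2)
    pts = rng.uniform((0, 0), (cfg.width_m, cfg.height_m), size=(500, 2))
    for pt in pts:
        assert np.min(np.linalg.norm(nodes - pt, axis=1)) <= cfg.max_offroad_m


def test_single_segment_degenerate_grid():
    cfg = LandscapeConfig()
    cfg.width_m, cfg.height_m = 6000.0, 1.0
    cfg.road_grid_spacing_m, cfg.road_jitter_m = 6000.0, 0.0
    net = generate_road_network(cfg, seed=0)
    assert len(net.nodes) == 2 and len(net.edges) == 1
    a, b, length, cls_ = net.edges[0]
    assert cls_ == "paved"
    assert length == pytest.approx(np.hypot(*(np.array(net.nodes[a]) - net.nodes[b])))


def test_road_network_deterministic():
    cfg = LandscapeConfig()
    n1 = generate_road_network(cfg, seed=9)
    n2 = generate_road_network(cfg, seed=9)
    assert n1.nodes == n2.nodes and n1.edges == n2.edges


# -- provider indicators ---------------------------------------------------


def test_saturated_profile_gives_full_checklist():
    profile = QualityProfile.from_scalars({c: 1.0 for c in CATEGORIES})
    ind, knowledge = generate_provider_indicators(
        "pharmacy", profile, np.random.default_rng(0)
    )
    assert all(all(v == 1 for v in vals) for vals in ind.values())
    assert knowledge == 1.0


def test_homogeneous_profile_has_no_within_category_variance():
    profile = QualityProfile.homogeneous()
    rng = np.random.default_rng(1)
    draws = [generate_provider_indicators("govt_health_center_post", profile, rng) for _ in range(20)]
    assert all(d == draws[0] for d in draws)


def test_indicator_frequencies_match_profile_within_3_binomial_sd():
    p = 0.65
    profile = QualityProfile.from_scalars({c: p for c in CATEGORIES})
    rng = np.random.default_rng(42)
    n = 200
    values = []
    for _ in range(n):
        ind, _ = generate_provider_indicators("govt_cba_fieldworker", profile, rng)
        values.append(ind["diagnostics"][0])
    freq = np.mean(values)
    sd = np.sqrt(p * (1 - p) / n)
    assert abs(freq - p) <= 3 * sd


def test_invalid_probability_rejected():
    profile = QualityProfile.from_scalars({c: 0.5 for c in CATEGORIES})
    profile.indicator_p["pharmacy"]["diagnostics"][0] = 1.5
    with pytest.raises(ValueError):
        generate_provider_indicators("pharmacy", profile, np.random.default_rng(0))


# -- care-seeking ----------------------------------------------------------


def test_no_illness_means_no_events(small_landscape):
    beh = BehaviorConfig(p_illness_by_stratum={"rural": 0.0, "urban": 0.0})
    assert simulate_careseeking(small_landscape, beh, seed=0) == []


def test_illness_careseeking_and_mix_calibration(default_landscape, default_events):
    events = default_events
    n_children = {s: sum(h.n_children_u5 for h in default_landscape.households if h.stratum == s)
                  for s in ("rural", "urban")}
    beh = BehaviorConfig()
    for stratum in ("rural", "urban"):
        evs = [e for e in events if e.stratum == stratum]
        p = beh.p_illness_by_stratum[stratum]
        sd = np.sqrt(p * (1 - p) / n_children[stratum])
        assert abs(len(evs) / n_children[stratum] - p) <= 3 * sd
        pc = beh.p_careseek_by_stratum[stratum]
        sdc = np.sqrt(pc * (1 - pc) / len(evs))
        assert abs(np.mean([e.care_sought for e in evs]) - pc) <= 3 * sdc
        # dominant category share among reported sources
        mix = beh.normalized_mix(stratum)
        srcs = [s.category for e in evs for s in e.sources]
        share = np.mean([c == "govt_health_center_post" for c in srcs])
        pm = mix["govt_health_center_post"]
        sdm = np.sqrt(pm * (1 - pm) / len(srcs))
        assert abs(share - pm) <= 3 * sdm


def test_true_sources_reference_existing_providers_of_stated_category(
    default_landscape, default_events
):
    providers = {p.provider_id: p for p in default_landscape.providers}
    for e in default_events:
        if not e.care_sought:
            assert e.sources == ()
        for s in e.sources:
            if s.true_provider_id is not None:
                assert providers[s.true_provider_id].category == s.category


def test_deterministic_nearest_choice_is_recovered_by_euclidean_linking(small_landscape):
    beh = BehaviorConfig(
        p_nearest=1.0,
        p_multi_source_by_stratum={"rural": 0.0, "urban": 0.0},
        p_unrecalled_by_category={c: 0.0 for c in CATEGORIES},
    )
    events = simulate_careseeking(small_landscape, beh, seed=21)
    hh = {h.household_id: h for h in small_landscape.households}
    checked = 0
    for e in events:
        if not e.care_sought:
            continue
        (src,) = e.sources
        origin = (hh[e.household_id].x, hh[e.household_id].y)
        assert euclidean_link(origin, small_landscape.providers, src.category) == src.true_provider_id
        checked += 1
    assert checked > 20


def test_careseeking_deterministic_given_seed(small_landscape):
    beh = BehaviorConfig()
    a = simulate_careseeking(small_landscape, beh, seed=8)
    b = simulate_careseeking(small_landscape, beh, seed=8)
    pd.testing.assert_frame_equal(events_to_frame(a), events_to_frame(b))
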