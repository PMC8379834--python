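import random

import numpy as np
import pytest

from geolink_coverage.clusters import displace_replicates, form_clusters
from geolink_coverage.config import DisplacementConfig
from geolink_coverage.coverage import (
    assign_child_score,
    assign_scores,
    bootstrap_ci,
    compare_estimates,
    effective_coverage,
    linkage_accuracy,
)
from geolink_coverage.landscape import CareSeekingEvent, SourceOfCare
from geolink_coverage.linking import LinkAssignment, link_events
from geolink_coverage.quality import category_means, score_all


def event(eid="E0", care=True, sources=(), stratum="rural"):
    return CareSeekingEvent(
        event_id=eid, household_id="H0", stratum=stratum,
        care_sought=care, sources=tuple(sources),
    )


def record(eid, score, stratum="rural"):
    from geolink_coverage.coverage import ChildScoreRecord

    return ChildScoreRecord(eid, stratum, "m", "s", score, "geolink")


CAT_MEANS = {"pharmacy": 0.55, "shop_market": 0.3}


def test_no_care_scores_zero():
    r = assign_child_score(event(care=False), None, {}, CAT_MEANS)
    assert r.assigned_score == 0.0 and r.assignment_path == "no_care_zero"


def test_multi_source_scores_average():
    ev = event(sources=[SourceOfCare("pharmacy", "P1"), SourceOfCare("shop_market", "P2")])
    link = LinkAssignment(
        event_id="E0", location_source="household", method="euclidean",
        source_categories=("pharmacy", "shop_market"),
        linked_ids=(("P1",), ("P2",)), linked_any=True, linked_true=True,
    )
    r = assign_child_score(ev, link, {"P1": 0.6, "P2": 0.8}, CAT_MEANS)
    assert r.assigned_score == pytest.approx(0.7)
    assert r.assignment_path == "multi_source_mean"


def test_empty_radius_set_falls_back_to_category_mean():
    ev = event(sources=[SourceOfCare("pharmacy", "P1")])
    link = LinkAssignment(
        event_id="E0", location_source="household", method="radius_5km",
        source_categories=("pharmacy",), linked_ids=((),),
        linked_any=False, linked_true=False,
    )
    r = assign_child_score(ev, link, {"P1": 0.9}, CAT_MEANS)
    assert r.assigned_score == pytest.approx(0.55)
    assert r.assignment_path == "category_mean_fallback"


def test_exact_match_uses_true_provider_and_category_mean_for_unknown():
    known = assign_child_score(
        event(sources=[SourceOfCare("pharmacy", "P1")]), None, {"P1": 0.9}, CAT_MEANS
    )
    assert known.assigned_score == pytest.approx(0.9)
    unknown = assign_child_score(
        event(sources=[SourceOfCare("shop_market", None)]), None, {}, CAT_MEANS
    )
    assert unknown.assigned_score == pytest.approx(0.3)
    assert unknown.assignment_path == "category_mean_fallback"


def test_unknown_category_is_an_error():
    ev = event(sources=[SourceOfCare("traditional_faith", None)])
    with pytest.raises(ValueError, match="traditional_faith"):
        assign_child_score(ev, None, {}, CAT_MEANS)


def test_effective_coverage_simple_means():
    recs = [record(f"E{i}", 0.8) for i in range(10)]
    assert effective_coverage(recs, "rural") == pytest.approx(0.8)
    recs = [record(f"E{i}", 0.0) for i in range(5)] + [record(f"F{i}", 1.0) for i in range(5)]
    assert effective_coverage(recs, "rural") == pytest.approx(0.5)
    with pytest.raises(ValueError):
        effective_coverage(recs, "urban")


def test_coverage_invariant_to_event_order():
    rng = np.random.default_rng(0)
    recs = [record(f"E{i}", float(rng.random())) for i in range(101)]
    shuffled = recs.copy()
    random.Random(1).shuffle(shuffled)
    assert effective_coverage(recs, "rural") == pytest.approx(
        effective_coverage(shuffled, "rural"), abs=1e-12
    )


def test_exact_match_coverage_equals_direct_oracle(small_landscape, small_events):
    scores = score_all(small_landscape.providers)
    means = category_means(scores, small_landscape.providers)
    recs = assign_scores(small_events, None, scores, means, "exact_match")
    for stratum in ("rural", "urban"):
        # independent one-line recomputation from raw events
        vals = []
        for e in small_events:
            if e.stratum != stratum:
                continue
            if not e.care_sought:
                vals.append(0.0)
            else:
                vals.append(
                    np.mean([
                        scores[s.true_provider_id].score
                        if s.true_provider_id is not None
                        else means[s.category]
                        for s in e.sources
                    ])
                )
        assert effective_coverage(recs, stratum) == pytest.approx(np.mean(vals), abs=1e-12)


def test_bootstrap_degenerate_and_determinism():
    recs = [record(f"E{i}", 0.4) for i in range(50)]
    lo, hi = bootstrap_ci(recs, "rural", seed=1)
    assert lo == hi == pytest.approx(0.4)
    rng = np.random.default_rng(2)
    recs = [record(f"E{i}", float(rng.integers(0, 2))) for i in range(400)]
    assert bootstrap_ci(recs, "rural", seed=3) == bootstrap_ci(recs, "rural", seed=3)
    with pytest.raises(ValueError):
        bootstrap_ci(recs, "rural", n_boot=50)


def test_bootstrap_width_near_analytic_se():
    rng = np.random.default_rng(4)
    vals = rng.integers(0, 2, size=400).astype(float)
    recs = [record(f"E{i}", v) for i, v in enumerate(vals)]
    lo, hi = bootstrap_ci(recs, "rural", n_boot=2000, seed=5)
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    expected_width = 2 * 1.96 * se
    assert abs((hi - lo) - expected_width) <= 0.2 * expected_width


def test_compare_identical_arms_not_significant():
    recs = [record(f"E{i}", 0.1 * (i % 10)) for i in range(100)]
    res = compare_estimates(recs, recs, seed=6)
    assert res.difference == 0.0 and not res.significant


def test_compare_detects_constant_shift():
    rng = np.random.default_rng(7)
    base = [record(f"E{i}", float(rng.random()) * 0.5) for i in range(400)]
    shifted = [record(r.event_id, r.assigned_score + 0.2) for r in base]
    res = compare_estimates(shifted, base, seed=8)
    assert res.significant
    assert res.difference == pytest.approx(0.2, abs=1e-12)
    assert res.ci_low <= 0.2 <= res.ci_high


def test_compare_rejects_mismatched_event_sets():
    a = [record("E1", 0.5), record("E2", 0.5)]
    b = [record("E1", 0.5), record("E3", 0.5)]
    with pytest.raises(ValueError):
        compare_estimates(a, b)


def test_linkage_accuracy_empty_and_full(small_landscape):
    assert linkage_accuracy([], []).empty
    from geolink_coverage.config import CATEGORIES, BehaviorConfig
    from geolink_coverage.landscape import simulate_careseeking

    beh = BehaviorConfig(
        p_nearest=1.0,
        p_multi_source_by_stratum={"rural": 0.0, "urban": 0.0},
        p_unrecalled_by_category={c: 0.0 for c in CATEGORIES},
    )
    events = simulate_careseeking(small_landscape, beh, seed=41)
    links = link_events(events, small_landscape, None, "household", "euclidean")
    acc = linkage_accuracy(links, events)
    assert (acc["pct_linked_any"] == 100.0).all()
    assert (acc["pct_linked_true"] == 100.0).all()


def test_homogeneous_quality_makes_every_arm_equal_exact_match():
    """With zero within-category score variance, mislinking is harmless:
    every linking arm reproduces the exact-match estimate exactly."""
    from geolink_coverage.config import BehaviorConfig, QualityProfile
    from geolink_coverage.landscape import generate_landscape, simulate_careseeking

    from .conftest import small_landscape_config

    cfg = small_landscape_config(quality_profile=QualityProfile.homogeneous())
    land = generate_landscape(cfg, seed=17)
    events = simulate_careseeking(land, BehaviorConfig(), seed=18)
    scores = score_all(land.providers)
    means = category_means(scores, land.providers)
    clusters = form_clusters(land.households, cluster_size=50, seed=19)
    clusters = displace_replicates(clusters, DisplacementConfig(), land.admin_polygon, seed=20)
    exact = assign_scores(events, None, scores, means, "exact_match")
    for method in ("euclidean", "travel_time", "radius_5km"):
        for source in ("household", "central_point", "displaced_A", "displaced_E"):
            links = link_events(events, land, clusters, source, method)
            recs = assign_scores(events, links, scores, means, method, source)
            for stratum in ("rural", "urban"):
                assert effective_coverage(recs, stratum) == pytest.approx(
                    effective_coverage(exact, stratum), abs=1e-12
                )
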