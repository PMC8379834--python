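"""Synthetic study landscape: households, providers, roads, care-seeking.

The generator emulates the structure of a household-and-provider census in
a small district: a dense urban core inside a sparse rural area, seven
categories of curative-care providers, a road network with paved, graded
and footpath classes, and simulated illness/care-seeking episodes for
children under five. It exists so that the downstream linking analysis is
fully testable without any confidential field data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from shapely.geometry import Point, Polygon, box

from .config import (
    CATEGORIES,
    STRATA,
    BehaviorConfig,
    LandscapeConfig,
    QualityProfile,
    SpeedTable,
)
from .quality import BINARY_DOMAINS

# ---------------------------------------------------------------------------
# Domain types


@dataclass(frozen=True)
class HouseholdRecord:
    household_id: str
    x: float
    y: float
    stratum: str
    n_children_u5: int


@dataclass(frozen=True)
class ProviderAssessment:
    """A provider's location, category and readiness checklist."""

    provider_id: str
    x: float
    y: float
    category: str
    indicators: dict[str, list[int]]
    knowledge_score: float


@dataclass(frozen=True)
class SourceOfCare:
    """One reported source of care: the category is always reported; the
    specific provider is known only when the caregiver could name it."""

    category: str
    true_provider_id: Optional[str]


@dataclass(frozen=True)
class CareSeekingEvent:
    """One sick child's illness episode."""

    event_id: str
    household_id: str
    stratum: str
    care_sought: bool
    sources: tuple[SourceOfCare, ...]


@dataclass
class RoadNetwork:
    """Undirected road graph in planar meters.

    ``edges`` are (node_a, node_b, length_m, road_class); lengths agree
    with node coordinates.
    """

    nodes: dict[str, tuple[float, float]]
    edges: list[tuple[str, str, float, str]]

    def validate(self) -> None:
        for a, b, length, cls_ in self.edges:
            d = math.dist(self.nodes[a], self.nodes[b])
            if length <= 0:
                raise ValueError(f"edge {a}-{b} has non-positive length")
            if d > 0 and abs(length - d) / d > 0.01:
                raise ValueError(f"edge {a}-{b} length inconsistent with node coordinates")


@dataclass
class Landscape:
    households: list[HouseholdRecord]
    providers: list[ProviderAssessment]
    roads: RoadNetwork
    admin_polygon: Polygon
    strata_extents: dict[str, Polygon] = field(default_factory=dict)

    def provider_by_id(self, pid: str) -> ProviderAssessment:
        return self._pindex()[pid]

    def providers_in_category(self, category: str) -> list[ProviderAssessment]:
        return [p for p in self.providers if p.category == category]

    def household_by_id(self, hid: str) -> HouseholdRecord:
        if not hasattr(self, "_hidx"):
            self._hidx = {h.household_id: h for h in self.households}
        return self._hidx[hid]

    def _pindex(self) -> dict[str, ProviderAssessment]:
        if not hasattr(self, "_pidx"):
            self._pidx = {p.provider_id: p for p in self.providers}
        return self._pidx

    def validate(self) -> None:
        ids = [h.household_id for h in self.households]
        if len(set(ids)) != len(ids):
            raise ValueError("household ids are not unique")
        pids = [p.provider_id for p in self.providers]
        if len(set(pids)) != len(pids):
            raise ValueError("provider ids are not unique")
        for h in self.households:
            if h.stratum not in STRATA:
                raise ValueError(f"household {h.household_id} has unknown stratum")
            if not self.admin_polygon.covers(Point(h.x, h.y)):
                raise ValueError(f"household {h.household_id} outside admin polygon")
        for p in self.providers:
            if p.category not in CATEGORIES:
                raise ValueError(f"provider {p.provider_id} has unknown category")
            if not self.admin_polygon.covers(Point(p.x, p.y)):
                raise ValueError(f"provider {p.provider_id} outside admin polygon")
        self.roads.validate()


# ---------------------------------------------------------------------------
# Road network


def generate_road_network(config: LandscapeConfig, seed: int) -> RoadNetwork:
    """Lay a grid road network over the study area.

    A paved trunk runs across the middle of the area, graded branches run
    perpendicular at regular intervals, and the remaining grid cells are
    footpaths, so that every point of the area is within
    ``config.max_offroad_m`` of some node. Nodes off the trunk and
    branches are jittered so the network is not perfectly rectilinear.
    """
    if config.width_m <= 0 or config.height_m <= 0:
        raise ValueError("degenerate extents: area must have positive width and height")
    rng = np.random.default_rng(seed)
    s = config.road_grid_spacing_m
    ncols = max(2, round(config.width_m / s) + 1)
    nrows = max(1, round(config.height_m / s) + 1)
    xs = np.linspace(0.0, config.width_m, ncols)
    ys = np.linspace(0.0, config.height_m, nrows)
    trunk_row = int(np.argmin(np.abs(ys - config.road_trunk_frac * config.height_m)))
    branch_cols = set(range(0, ncols, max(1, config.road_branch_spacing_cells)))

    nodes: dict[str, tuple[float, float]] = {}
    for iy in range(nrows):
        for ix in range(ncols):
            x, y = float(xs[ix]), float(ys[iy])
            if iy != trunk_row and ix not in branch_cols and config.road_jitter_m > 0:
                x = float(np.clip(x + rng.uniform(-1, 1) * config.road_jitter_m, 0, config.width_m))
                y = float(np.clip(y + rng.uniform(-1, 1) * config.road_jitter_m, 0, config.height_m))
            nodes[f"N{ix}_{iy}"] = (x, y)

    edges: list[tuple[str, str, float, str]] = []

    def add_edge(a: str, b: str, cls_: str) -> None:
        length = math.dist(nodes[a], nodes[b])
        edges.append((a, b, length, cls_))

    for iy in range(nrows):
        for ix in range(ncols - 1):
            cls_ = "paved" if iy == trunk_row else "footpath"
            add_edge(f"N{ix}_{iy}", f"N{ix + 1}_{iy}", cls_)
    for ix in range(ncols):
        for iy in range(nrows - 1):
            cls_ = "graded" if ix in branch_cols else "footpath"
            add_edge(f"N{ix}_{iy}", f"N{ix}_{iy + 1}", cls_)
    # Diagonal footpaths: walking routes are near-isotropic rather than
    # rectilinear, so network distance approximates straight-line
    # distance away from the fast roads.
    for ix in range(ncols - 1):
        for iy in range(nrows - 1):
            add_edge(f"N{ix}_{iy}", f"N{ix + 1}_{iy + 1}", "footpath")
            add_edge(f"N{ix + 1}_{iy}", f"N{ix}_{iy + 1}", "footpath")

    return RoadNetwork(nodes=nodes, edges=edges)


# ---------------------------------------------------------------------------
# Households and providers


def _rural_region(config: LandscapeConfig):
    admin = box(0, 0, config.width_m, config.height_m)
    return admin.difference(box(*config.urban_box))


def _sample_in_region(region, rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform rejection sampling of n points inside a shapely region."""
    minx, miny, maxx, maxy = region.bounds
    out = np.empty((n, 2))
    got = 0
    while got < n:
        cand = rng.uniform((minx, miny), (maxx, maxy), size=(max(64, 2 * (n - got)), 2))
        for x, y in cand:
            if region.covers(Point(x, y)):
                out[got] = (x, y)
                got += 1
                if got == n:
                    break
    return out


def _neyman_scott(
    region, rng: np.random.Generator, n: int, per_parent: float, sigma: float
) -> np.ndarray:
    """Clustered point process: uniform parents, Gaussian offspring
    rejected back into the region."""
    if n == 0:
        return np.empty((0, 2))
    n_parents = max(1, int(math.ceil(n / per_parent)))
    parents = _sample_in_region(region, rng, n_parents)
    pts = np.empty((n, 2))
    for i in range(n):
        parent = parents[rng.integers(n_parents)]
        while True:
            p = parent + rng.normal(0.0, sigma, size=2)
            if region.covers(Point(p[0], p[1])):
                pts[i] = p
                break
    return pts


def _truncated_poisson_children(
    rng: np.random.Generator, lam: float, n: int, kmax: int = 3
) -> np.ndarray:
    """Children per household on {1..kmax}, Poisson-shaped and renormalised."""
    ks = np.arange(1, kmax + 1)
    pmf = np.array([lam**k / math.factorial(k) for k in ks])
    pmf = pmf / pmf.sum()
    return rng.choice(ks, size=n, p=pmf)


def generate_provider_indicators(
    category: str, quality_profile: QualityProfile, rng: np.random.Generator
) -> tuple[dict[str, list[int]], float]:
    """Draw a provider's binary checklist and knowledge score.

    Each binary indicator is an independent Bernoulli draw at the
    category's profiled probability; the knowledge score is the mean of
    four simulated case-scenario performances, each Bernoulli at the
    category's knowledge mean.
    """
    profile = quality_profile.indicator_p[category]
    indicators: dict[str, list[int]] = {}
    for domain, n in BINARY_DOMAINS.items():
        ps = profile[domain]
        if len(ps) != n:
            raise ValueError(f"profile for {category!r}/{domain!r} needs {n} probabilities")
        for p in ps:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"indicator probability {p} outside [0, 1]")
        indicators[domain] = [int(rng.random() < p) for p in ps]
    kmean = quality_profile.knowledge_mean[category]
    if not 0.0 <= kmean <= 1.0:
        raise ValueError(f"knowledge mean {kmean} outside [0, 1]")
    scenarios = [int(rng.random() < kmean) for _ in range(4)]
    return indicators, sum(scenarios) / 4.0


def generate_landscape(config: LandscapeConfig, seed: int) -> Landscape:
    """Generate a full synthetic landscape; identical (config, seed) pairs
    reproduce identical output."""
    config.validate()
    ss = np.random.SeedSequence(seed)
    hh_ss, prov_ss, road_ss = ss.spawn(3)
    hh_rng = np.random.default_rng(hh_ss)
    prov_rng = np.random.default_rng(prov_ss)
    road_seed = int(road_ss.generate_state(1)[0] % 2**31)

    admin = box(0, 0, config.width_m, config.height_m)
    urban = box(*config.urban_box)
    rural = _rural_region(config)
    regions = {"rural": rural, "urban": urban}

    households: list[HouseholdRecord] = []
    idx = 0
    for stratum in STRATA:
        n = config.n_households_by_stratum.get(stratum, 0)
        pts = _neyman_scott(
            regions[stratum],
            hh_rng,
            n,
            config.households_per_parent[stratum],
            config.household_cluster_sigma_m[stratum],
        )
        if n:
            kids = _truncated_poisson_children(
                hh_rng, config.children_lambda_by_stratum[stratum], n
            )
        for i in range(n):
            households.append(
                HouseholdRecord(
                    household_id=f"H{idx:04d}",
                    x=float(pts[i, 0]),
                    y=float(pts[i, 1]),
                    stratum=stratum,
                    n_children_u5=int(kids[i]),
                )
            )
            idx += 1

    providers: list[ProviderAssessment] = []
    pidx = 0
    for category in CATEGORIES:
        for stratum in STRATA:
            n = config.n_providers.get(category, {}).get(stratum, 0)
            if n == 0:
                continue
            pts = _sample_in_region(regions[stratum], prov_rng, n)
            for i in range(n):
                indicators, knowledge = generate_provider_indicators(
                    category, config.quality_profile, prov_rng
                )
                providers.append(
                    ProviderAssessment(
                        provider_id=f"P{pidx:03d}",
                        x=float(pts[i, 0]),
                        y=float(pts[i, 1]),
                        category=category,
                        indicators=indicators,
                        knowledge_score=knowledge,
                    )
                )
                pidx += 1

    roads = generate_road_network(config, road_seed)
    land = Landscape(
        households=households,
        providers=providers,
        roads=roads,
        admin_polygon=admin,
        strata_extents={"rural": rural, "urban": urban},
    )
    land.validate()
    return land


# ---------------------------------------------------------------------------
# Care-seeking simulation


def simulate_careseeking(
    landscape: Landscape,
    behavior: BehaviorConfig,
    seed: int,
    speeds: SpeedTable | None = None,
    scores: dict[str, float] | None = None,
) -> list[CareSeekingEvent]:
    """Simulate one illness episode per sick child.

    Illness is drawn per child at the stratum's prevalence; care-seeking
    per episode at the stratum's rate; the provider category comes from
    the stratum's reported mix. Under the ``nearest`` choice model the
    child uses the travel-time-nearest provider of the category with
    probability ``p_nearest`` and otherwise one of the next
    ``n_alternatives`` nearest, uniformly — so most children use the
    nearest provider but not all. The ``gravity`` model samples providers
    with probability proportional to exp(-d/lambda) * exp(beta*quality).
    A second, independently drawn source is added with the stratum's
    multi-source probability. With category-specific probability the
    specific provider goes unrecalled and is recorded as unknown.
    """
    from .linking import TravelTimeEngine

    behavior.validate()
    for stratum in STRATA:
        for cat in behavior.normalized_mix(stratum):
            if not landscape.providers_in_category(cat):
                raise ValueError(
                    f"category {cat!r} in the {stratum} care-seeking mix has no providers"
                )
    if behavior.choice_model == "gravity" and behavior.quality_preference_beta != 0 and scores is None:
        raise ValueError("gravity choice with quality preference requires provider scores")

    speeds = speeds or SpeedTable()
    engine = TravelTimeEngine(landscape.roads, speeds)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    # Ranked provider lists are deterministic geometry; cache per
    # (household, category).
    rank_cache: dict[tuple[str, str], list[ProviderAssessment]] = {}

    def ranked(hh: HouseholdRecord, category: str) -> list[ProviderAssessment]:
        key = (hh.household_id, category)
        if key not in rank_cache:
            provs = landscape.providers_in_category(category)
            origin = (hh.x, hh.y)
            keyed = []
            for p in provs:
                d = math.dist(origin, (p.x, p.y))
                if behavior.choice_metric == "walk":
                    keyed.append((d, d, p.provider_id, p))
                else:
                    t = engine.travel_time(origin, (p.x, p.y))
                    keyed.append((t, d, p.provider_id, p))
            keyed.sort(key=lambda k: k[:3])
            rank_cache[key] = [k[3] for k in keyed]
        return rank_cache[key]

    def choose_provider(hh: HouseholdRecord, category: str) -> ProviderAssessment:
        provs = ranked(hh, category)
        if behavior.choice_model == "nearest":
            if len(provs) == 1 or rng.random() < behavior.p_nearest:
                return provs[0]
            alts = provs[1 : 1 + behavior.n_alternatives]
            return alts[rng.integers(len(alts))]
        # gravity
        origin = (hh.x, hh.y)
        d = np.array([math.dist(origin, (p.x, p.y)) for p in provs])
        w = np.exp(-d / behavior.gravity_decay_lambda_m)
        if behavior.quality_preference_beta != 0:
            q = np.array([scores[p.provider_id] for p in provs])
            w = w * np.exp(behavior.quality_preference_beta * q)
        w = w / w.sum()
        return provs[rng.choice(len(provs), p=w)]

    def draw_source(hh: HouseholdRecord, stratum: str) -> SourceOfCare:
        mix = behavior.normalized_mix(stratum)
        cats = sorted(mix)
        probs = np.array([mix[c] for c in cats])
        category = cats[rng.choice(len(cats), p=probs)]
        provider = choose_provider(hh, category)
        p_unrec = behavior.p_unrecalled_by_category.get(category, 0.005)
        true_pid = None if rng.random() < p_unrec else provider.provider_id
        return SourceOfCare(category=category, true_provider_id=true_pid)

    events: list[CareSeekingEvent] = []
    eidx = 0
    for hh in landscape.households:
        stratum = hh.stratum
        p_ill = behavior.p_illness_by_stratum[stratum]
        for _child in range(hh.n_children_u5):
            if rng.random() >= p_ill:
                continue
            care = rng.random() < behavior.p_careseek_by_stratum[stratum]
            sources: tuple[SourceOfCare, ...] = ()
            if care:
                first = draw_source(hh, stratum)
                sources = (first,)
                if rng.random() < behavior.p_multi_source_by_stratum[stratum]:
                    second = draw_source(hh, stratum)
                    if second.true_provider_id is None or (
                        second.true_provider_id != first.true_provider_id
                    ):
                        sources = (first, second)
            events.append(
                CareSeekingEvent(
                    event_id=f"E{eidx:05d}",
                    household_id=hh.household_id,
                    stratum=stratum,
                    care_sought=care,
                    sources=sources,
                )
            )
            eidx += 1
    return events
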