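"""Configuration objects for the synthetic landscape and the linking experiment.

All spatial quantities are planar meters in a local synthetic frame; the
study area is district-scale, so geodesy is deliberately avoided and every
distance is Euclidean in meters. Probabilities are fractions in [0, 1].
Defaults are calibrated once to the care-seeking structure of a rural/urban
Zambian district (two strata, seven provider categories, government health
centers dominating the category mix) and are not meant to be tuned per run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml

#: The seven provider categories: public, private and informal sources of
#: curative child care present in the study area.
CATEGORIES = (
    "govt_hospital",
    "govt_health_center_post",
    "govt_cba_fieldworker",
    "pvt_hospital_clinic",
    "pharmacy",
    "shop_market",
    "traditional_faith",
)

STRATA = ("rural", "urban")

ROAD_CLASSES = ("paved", "graded", "footpath")


def _check_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass
class QualityProfile:
    """Per-category Bernoulli probabilities for the readiness checklist.

    ``indicator_p[category][domain]`` is the list of per-indicator success
    probabilities for the five binary checklist domains;
    ``knowledge_mean[category]`` is the expected fraction of the four
    clinical case scenarios a health worker handles correctly.
    """

    indicator_p: dict[str, dict[str, list[float]]]
    knowledge_mean: dict[str, float]

    def validate(self) -> None:
        from .quality import BINARY_DOMAINS

        for cat in CATEGORIES:
            if cat not in self.indicator_p:
                raise ValueError(f"quality profile missing category {cat!r}")
            for domain, n in BINARY_DOMAINS.items():
                ps = self.indicator_p[cat].get(domain)
                if ps is None or len(ps) != n:
                    raise ValueError(
                        f"profile for {cat!r} needs {n} probabilities in domain {domain!r}"
                    )
                for p in ps:
                    _check_prob(f"indicator_p[{cat}][{domain}]", p)
            _check_prob(f"knowledge_mean[{cat}]", self.knowledge_mean[cat])

    @classmethod
    def from_scalars(
        cls, level: dict[str, float], knowledge: dict[str, float] | None = None
    ) -> "QualityProfile":
        """Build a profile with one probability per category applied to all
        19 binary indicators; knowledge defaults to the same level."""
        from .quality import BINARY_DOMAINS

        indicator_p = {
            cat: {dom: [level[cat]] * n for dom, n in BINARY_DOMAINS.items()}
            for cat in CATEGORIES
        }
        kn = dict(knowledge) if knowledge is not None else dict(level)
        return cls(indicator_p=indicator_p, knowledge_mean=kn)

    @classmethod
    def default(cls) -> "QualityProfile":
        # Quality varies strongly between categories and little within:
        # skilled public/private providers are moderate-to-high, informal
        # sources low.
        level = {
            "govt_hospital": 0.95,
            "govt_health_center_post": 0.85,
            "govt_cba_fieldworker": 0.65,
            "pvt_hospital_clinic": 0.85,
            "pharmacy": 0.45,
            "shop_market": 0.10,
            "traditional_faith": 0.05,
        }
        return cls.from_scalars(level)

    @classmethod
    def homogeneous(cls) -> "QualityProfile":
        """Degenerate profile: every probability is exactly 0 or 1, so all
        providers of a category share one deterministic score. Used to
        exercise the zero-within-category-variance regime."""
        level = {
            "govt_hospital": 1.0,
            "govt_health_center_post": 1.0,
            "govt_cba_fieldworker": 1.0,
            "pvt_hospital_clinic": 1.0,
            "pharmacy": 0.0,
            "shop_market": 0.0,
            "traditional_faith": 0.0,
        }
        return cls.from_scalars(level)


@dataclass
class BehaviorConfig:
    """Illness and care-seeking behavior of children under five.

    Category mixes are conditional on seeking care and need not be
    normalised on input. The choice model picks the specific provider
    within the drawn category: ``nearest`` takes the travel-time-nearest
    provider with probability ``p_nearest`` and otherwise one of the next
    three nearest uniformly; ``gravity`` samples with probability
    proportional to exp(-d/lambda) * exp(beta * quality).
    """

    p_illness_by_stratum: dict[str, float] = field(
        default_factory=lambda: {"rural": 0.364, "urban": 0.346}
    )
    p_careseek_by_stratum: dict[str, float] = field(
        default_factory=lambda: {"rural": 0.789, "urban": 0.667}
    )
    category_mix_by_stratum: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            # Fractions of all sick children reporting each category; zero
            # entries are categories never used in that stratum.
            "rural": {
                "govt_hospital": 0.0,
                "govt_health_center_post": 0.613,
                "govt_cba_fieldworker": 0.181,
                "pvt_hospital_clinic": 0.0,
                "pharmacy": 0.005,
                "shop_market": 0.010,
                "traditional_faith": 0.025,
            },
            "urban": {
                "govt_hospital": 0.027,
                "govt_health_center_post": 0.597,
                "govt_cba_fieldworker": 0.005,
                "pvt_hospital_clinic": 0.005,
                "pharmacy": 0.011,
                "shop_market": 0.048,
                "traditional_faith": 0.0,
            },
        }
    )
    p_multi_source_by_stratum: dict[str, float] = field(
        default_factory=lambda: {"rural": 0.057, "urban": 0.040}
    )
    #: Probability the caregiver cannot name the specific provider, by
    #: category; informal shops dominate the unrecalled events.
    p_unrecalled_by_category: dict[str, float] = field(
        default_factory=lambda: {
            "shop_market": 0.8,
            "traditional_faith": 0.10,
        }
    )
    choice_model: str = "nearest"  # nearest | gravity
    #: Proximity metric behind the nearest-choice model: "walk" ranks
    #: providers by walking (straight-line) time, "travel_time" by the
    #: road-network travel time with vehicle speeds.
    choice_metric: str = "walk"
    p_nearest: float = 0.78
    n_alternatives: int = 3  # fallback pool when not choosing the nearest
    gravity_decay_lambda_m: float = 3000.0
    quality_preference_beta: float = 0.0

    def validate(self) -> None:
        for stratum in STRATA:
            _check_prob("p_illness", self.p_illness_by_stratum[stratum])
            _check_prob("p_careseek", self.p_careseek_by_stratum[stratum])
            _check_prob("p_multi_source", self.p_multi_source_by_stratum[stratum])
            mix = self.category_mix_by_stratum[stratum]
            total = sum(mix.values())
            if total <= 0:
                raise ValueError(f"category mix for {stratum!r} sums to zero")
            for cat, w in mix.items():
                if cat not in CATEGORIES:
                    raise ValueError(f"unknown category {cat!r} in mix")
                if w < 0:
                    raise ValueError(f"negative mix weight for {cat!r}")
        for cat, p in self.p_unrecalled_by_category.items():
            _check_prob(f"p_unrecalled[{cat}]", p)
        _check_prob("p_nearest", self.p_nearest)
        if self.choice_model not in ("nearest", "gravity"):
            raise ValueError(f"unknown choice model {self.choice_model!r}")
        if self.choice_metric not in ("walk", "travel_time"):
            raise ValueError(f"unknown choice metric {self.choice_metric!r}")

    def normalized_mix(self, stratum: str) -> dict[str, float]:
        mix = self.category_mix_by_stratum[stratum]
        total = sum(mix.values())
        return {cat: w / total for cat, w in mix.items() if w > 0}


@dataclass
class LandscapeConfig:
    """Geometry and composition of the synthetic study area.

    A rectangular admin polygon holds a dense urban core and a sparse
    rural remainder; household counts per stratum default to the enrolled
    study population (335 rural, 469 urban households with a child under
    five). Providers are placed uniformly within their stratum.
    """

    width_m: float = 24_000.0
    height_m: float = 16_000.0
    #: (xmin, ymin, xmax, ymax) of the urban core.
    urban_box: tuple[float, float, float, float] = (10_000.0, 5_500.0, 15_000.0, 10_500.0)
    n_households_by_stratum: dict[str, int] = field(
        default_factory=lambda: {"rural": 335, "urban": 469}
    )
    #: Truncated-Poisson rate for children under five per household,
    #: chosen so the stratum mean matches ~1.63 (rural) / ~1.15 (urban)
    #: children per enrolled household.
    children_lambda_by_stratum: dict[str, float] = field(
        default_factory=lambda: {"rural": 1.30, "urban": 0.28}
    )
    #: Neyman-Scott clustering of households: parents per stratum and
    #: offspring dispersion (meters).
    household_cluster_sigma_m: dict[str, float] = field(
        default_factory=lambda: {"rural": 600.0, "urban": 150.0}
    )
    households_per_parent: dict[str, float] = field(
        default_factory=lambda: {"rural": 12.0, "urban": 25.0}
    )
    #: Provider census: category -> stratum -> count. Health centers
    #: reflect the handful of facility catchment areas; community-based
    #: agents (CBAs) are predominantly rural; informal shops are common.
    n_providers: dict[str, dict[str, int]] = field(
        default_factory=lambda: {
            "govt_hospital": {"rural": 0, "urban": 1},
            "govt_health_center_post": {"rural": 4, "urban": 2},
            "govt_cba_fieldworker": {"rural": 16, "urban": 2},
            "pvt_hospital_clinic": {"rural": 0, "urban": 1},
            "pharmacy": {"rural": 1, "urban": 2},
            "shop_market": {"rural": 6, "urban": 10},
            "traditional_faith": {"rural": 5, "urban": 2},
        }
    )
    road_grid_spacing_m: float = 2_000.0
    road_jitter_m: float = 200.0
    #: Trunk-road position as a fraction of the area height, and the
    #: spacing of graded branch roads in grid cells. The trunk skirts the
    #: southern part of the area rather than bisecting the urban core.
    road_trunk_frac: float = 0.15
    road_branch_spacing_cells: int = 6
    max_offroad_m: float = 2_000.0
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    quality_profile: QualityProfile = field(default_factory=QualityProfile.default)

    def validate(self) -> None:
        if self.width_m <= 0 or self.height_m <= 0:
            raise ValueError("area extents must have positive width and height")
        x0, y0, x1, y1 = self.urban_box
        if not (0 <= x0 < x1 <= self.width_m and 0 <= y0 < y1 <= self.height_m):
            raise ValueError("urban box must be a non-degenerate sub-rectangle")
        self.behavior.validate()
        self.quality_profile.validate()
        for stratum in STRATA:
            mix = self.behavior.normalized_mix(stratum)
            for cat in mix:
                total = sum(self.n_providers.get(cat, {}).values())
                if total == 0:
                    raise ValueError(
                        f"category {cat!r} appears in the {stratum} care-seeking mix "
                        "but has zero providers configured"
                    )


@dataclass
class DisplacementConfig:
    """DHS-style geomasking parameters.

    Each cluster central point is displaced ``n_replicates`` times with a
    uniform random angle and a random distance capped at 2 km (urban) or
    5 km (rural), with a 1% rural subset allowed up to 10 km; optionally
    the displaced point is rejection-resampled into the admin polygon.
    """

    cap_rural_m: float = 5_000.0
    cap_rural_long_m: float = 10_000.0
    frac_rural_long: float = 0.01
    cap_urban_m: float = 2_000.0
    n_replicates: int = 5
    restrict_to_admin: bool = True
    #: uniform_distance is the documented DHS convention; uniform_area is
    #: offered for sensitivity.
    distance_dist: str = "uniform_distance"
    #: Re-draw the 1% long-range rural subset independently per replicate.
    long_subset_per_replicate: bool = True

    def validate(self) -> None:
        if min(self.cap_rural_m, self.cap_rural_long_m, self.cap_urban_m) < 0:
            raise ValueError("displacement caps must be non-negative")
        _check_prob("frac_rural_long", self.frac_rural_long)
        if self.distance_dist not in ("uniform_distance", "uniform_area"):
            raise ValueError(f"unknown distance_dist {self.distance_dist!r}")

    def replicate_labels(self) -> list[str]:
        return [chr(ord("A") + i) for i in range(self.n_replicates)]


@dataclass
class SpeedTable:
    """Travel speeds (km/h) by road class, plus off-road walking speed."""

    speeds_kmh: dict[str, float] = field(
        default_factory=lambda: {"paved": 60.0, "graded": 25.0, "footpath": 5.0}
    )
    offroad_walk_kmh: float = 4.0

    def validate(self) -> None:
        for cls_, v in self.speeds_kmh.items():
            if v <= 0:
                raise ValueError(f"speed for {cls_!r} must be positive")
        if self.offroad_walk_kmh <= 0:
            raise ValueError("off-road walk speed must be positive")


@dataclass
class ScenarioSpec:
    """A quality-reassignment scenario layered on fixed geometry/behavior."""

    name: str = "baseline"  # baseline | preferential | random
    sd_multiplier: float = 2.0
    clip_to_unit: bool = True
    random_dist: str = "uniform_0_1"
    include_unused_in_median: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.name not in ("baseline", "preferential", "random"):
            raise ValueError(f"unknown scenario {self.name!r}")
        if self.sd_multiplier < 0:
            raise ValueError("sd_multiplier must be >= 0")
        if self.random_dist != "uniform_0_1":
            raise ValueError(f"unsupported random_dist {self.random_dist!r}")


@dataclass
class ExperimentConfig:
    """Everything needed to run the full linking experiment once."""

    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    displacement: DisplacementConfig = field(default_factory=DisplacementConfig)
    speeds: SpeedTable = field(default_factory=SpeedTable)
    cluster_size: int = 150
    radius_m: float = 5_000.0
    n_boot: int = 1000
    ci_level: float = 0.95
    scenarios: list[str] = field(
        default_factory=lambda: ["baseline", "preferential", "random"]
    )

    def validate(self) -> None:
        self.landscape.validate()
        self.displacement.validate()
        self.speeds.validate()
        if self.cluster_size < 1:
            raise ValueError("cluster_size must be >= 1")
        if self.radius_m <= 0:
            raise ValueError("radius_m must be positive")


# ---------------------------------------------------------------------------
# YAML round-trip


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def config_to_dict(config: Any) -> dict:
    return _to_plain(config)


def experiment_config_from_dict(d: dict) -> ExperimentConfig:
    land = d.get("landscape", {})
    behavior = BehaviorConfig(**land.pop("behavior", {})) if "behavior" in land else BehaviorConfig()
    if "quality_profile" in land:
        qp = QualityProfile(**land.pop("quality_profile"))
    else:
        qp = QualityProfile.default()
    if "urban_box" in land:
        land["urban_box"] = tuple(land["urban_box"])
    landscape = LandscapeConfig(behavior=behavior, quality_profile=qp, **land)
    displacement = DisplacementConfig(**d.get("displacement", {}))
    speeds = SpeedTable(**d.get("speeds", {}))
    extra = {
        k: v
        for k, v in d.items()
        if k in ("cluster_size", "radius_m", "n_boot", "ci_level", "scenarios")
    }
    return ExperimentConfig(
        landscape=landscape, displacement=displacement, speeds=speeds, **extra
    )


def save_config(config: Any, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_experiment_config(path: str) -> ExperimentConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    cfg = experiment_config_from_dict(d)
    cfg.validate()
    return cfg
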