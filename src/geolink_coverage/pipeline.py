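"""End-to-end experiment: landscape -> scores -> clusters -> links -> coverage.

One run generates a landscape and care-seeking events, scores providers,
forms 150-household clusters, displaces their central points five times,
links every care-seeking child to providers with each method x location
source combination, and estimates quality-adjusted effective coverage per
stratum under each quality scenario, with paired contrasts against the
exact-match estimate and against the same method run from true household
locations. A JSON manifest records the configuration and every derived
seed, so a run can be reproduced byte-identically from the manifest
alone.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clusters import ClusterPoint, displace_replicates, form_clusters
from .config import (
    ExperimentConfig,
    ScenarioSpec,
    config_to_dict,
    experiment_config_from_dict,
    load_experiment_config,
)
from .coverage import (
    CoverageEstimate,
    assign_scores,
    compare_estimates,
    estimate_coverage,
    linkage_accuracy,
)
from .io import (
    clusters_to_frame,
    events_to_frame,
    load_manifest,
    write_landscape,
    write_manifest,
)
from .landscape import Landscape, generate_landscape, simulate_careseeking
from .linking import METHODS, TravelTimeEngine, link_events
from .quality import category_means, score_all, scores_to_frame
from .scenarios import apply_scenario


def derive_seeds(seed: int) -> dict[str, int]:
    """Named component seeds derived from one master seed, all < 2^31."""
    names = ["landscape", "careseek", "displacement", "bootstrap", "scenario"]
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(names, children)
    }


def _boot_seed(base: int, *tags: str) -> int:
    """Stable per-estimate bootstrap seed from the base seed and labels."""
    h = np.uint64(base)
    for tag in tags:
        for ch in tag:
            h = np.uint64((int(h) * 1000003 + ord(ch)) % (2**61 - 1))
    return int(h % 2**31)


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    seed: int
    seeds: dict[str, int]
    landscape: Landscape
    events: list
    clusters: list[ClusterPoint]
    baseline_scores: dict
    scenario_scores: dict[str, dict[str, float]]
    links: dict[tuple[str, str], list]  # (method, location_source) -> assignments
    estimates: list[CoverageEstimate] = field(default_factory=list)
    coverage: pd.DataFrame | None = None
    linkage: pd.DataFrame | None = None
    comparisons: pd.DataFrame | None = None
    bias: pd.DataFrame | None = None
    manifest: dict | None = None


def location_sources(config: ExperimentConfig) -> list[str]:
    return ["household", "central_point"] + [
        f"displaced_{lab}" for lab in config.displacement.replicate_labels()
    ]


def run_experiment(
    config: ExperimentConfig | str | Path,
    seed: int = 0,
    out_dir: str | Path | None = None,
    skip_bootstrap: bool = False,
) -> ExperimentResult:
    """Run the full linking experiment once.

    ``config`` may be an :class:`ExperimentConfig` or a path to its YAML
    form. With ``skip_bootstrap`` the coverage table carries point
    estimates only (used for fast Monte-Carlo sweeps); the default run
    includes percentile bootstrap intervals and paired comparisons.
    """
    if isinstance(config, (str, Path)):
        config = load_experiment_config(config)
    config.validate()
    seeds = derive_seeds(seed)

    stage = "landscape"
    try:
        land = generate_landscape(config.landscape, seeds["landscape"])
        events = simulate_careseeking(
            land, config.landscape.behavior, seeds["careseek"], speeds=config.speeds
        )

        stage = "scoring"
        baseline_scores = score_all(land.providers)

        stage = "clustering"
        clusters = form_clusters(
            land.households, cluster_size=config.cluster_size, seed=seeds["displacement"]
        )
        clusters = displace_replicates(
            clusters, config.displacement, land.admin_polygon, seeds["displacement"]
        )

        stage = "linking"
        engine = TravelTimeEngine(land.roads, config.speeds)
        sources = location_sources(config)
        links = {}
        for method in METHODS:
            for source in sources:
                links[(method, source)] = link_events(
                    events,
                    land,
                    clusters,
                    source,
                    method,
                    speeds=config.speeds,
                    radius_m=config.radius_m,
                    engine=engine,
                )

        stage = "coverage"
        strata = sorted({e.stratum for e in events})
        scenario_scores: dict[str, dict[str, float]] = {}
        estimates: list[CoverageEstimate] = []
        cov_rows = []
        cmp_rows = []
        child_scores_cache: dict[tuple[str, str, str], list] = {}
        for scen_name in config.scenarios:
            spec = ScenarioSpec(name=scen_name, seed=seeds["scenario"])
            scen_scores = apply_scenario(
                scen_name, baseline_scores, events, land.providers, spec
            )
            scenario_scores[scen_name] = scen_scores
            means = category_means(scen_scores, land.providers)

            exact = assign_scores(
                events, None, scen_scores, means, "exact_match", "true_source"
            )
            child_scores_cache[(scen_name, "exact_match", "true_source")] = exact
            arms = [("exact_match", "true_source", exact)]
            for method in METHODS:
                for source in sources:
                    recs = assign_scores(
                        events, links[(method, source)], scen_scores, means, method, source
                    )
                    child_scores_cache[(scen_name, method, source)] = recs
                    arms.append((method, source, recs))

            for method, source, recs in arms:
                for stratum in strata:
                    bseed = _boot_seed(seeds["bootstrap"], scen_name, method, source, stratum)
                    if skip_bootstrap:
                        from .coverage import effective_coverage

                        point = effective_coverage(recs, stratum)
                        est = CoverageEstimate(
                            method, source, stratum,
                            sum(r.stratum == stratum for r in recs),
                            point, float("nan"), float("nan"), 0, bseed,
                        )
                    else:
                        est = estimate_coverage(
                            recs, stratum, n_boot=config.n_boot,
                            level=config.ci_level, seed=bseed,
                        )
                    estimates.append(est)
                    cov_rows.append(
                        {
                            "scenario": scen_name,
                            "method": method,
                            "location_source": source,
                            "stratum": stratum,
                            "n": est.n_children,
                            "point_pct": round(100 * est.point, 3),
                            "ci_low_pct": round(100 * est.ci_low, 3),
                            "ci_high_pct": round(100 * est.ci_high, 3),
                        }
                    )

            if not skip_bootstrap:
                for method in METHODS:
                    hh_recs = child_scores_cache[(scen_name, method, "household")]
                    for source in sources:
                        recs = child_scores_cache[(scen_name, method, source)]
                        refs = [("exact_match", exact)]
                        if source != "household":
                            refs.append(("household", hh_recs))
                        for ref_name, ref_recs in refs:
                            for stratum in strata:
                                sub = [r for r in recs if r.stratum == stratum]
                                ref_sub = [r for r in ref_recs if r.stratum == stratum]
                                cseed = _boot_seed(
                                    seeds["bootstrap"], "cmp", scen_name, method,
                                    source, ref_name, stratum,
                                )
                                res = compare_estimates(
                                    sub, ref_sub, n_boot=config.n_boot, seed=cseed
                                )
                                cmp_rows.append(
                                    {
                                        "scenario": scen_name,
                                        "method": method,
                                        "location_source": source,
                                        "stratum": stratum,
                                        "reference": ref_name,
                                        "difference_pct": round(100 * res.difference, 3),
                                        "ci_low_pct": round(100 * res.ci_low, 3),
                                        "ci_high_pct": round(100 * res.ci_high, 3),
                                        "significant": res.significant,
                                    }
                                )

        stage = "accuracy"
        all_links = [l for ls in links.values() for l in ls]
        linkage = linkage_accuracy(all_links, events)
    except Exception as err:
        raise RuntimeError(f"experiment failed at stage {stage!r}: {err}") from err

    coverage = pd.DataFrame(cov_rows)
    comparisons = pd.DataFrame(cmp_rows)
    bias = bias_summary(coverage, comparisons)

    manifest = {
        "software": "geolink-coverage",
        "version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "master_seed": seed,
        "derived_seeds": seeds,
        "config": config_to_dict(config),
        "cluster_algorithm": "capacitated greedy assignment on globally sorted "
        "household-centroid distances, farthest-point init, centroid-update sweeps",
        "displacement_distance_dist": config.displacement.distance_dist,
    }

    result = ExperimentResult(
        config=config,
        seed=seed,
        seeds=seeds,
        landscape=land,
        events=events,
        clusters=clusters,
        baseline_scores=baseline_scores,
        scenario_scores=scenario_scores,
        links=links,
        estimates=estimates,
        coverage=coverage,
        linkage=linkage,
        comparisons=comparisons,
        bias=bias,
        manifest=manifest,
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def bias_summary(coverage: pd.DataFrame, comparisons: pd.DataFrame) -> pd.DataFrame:
    """Bias of each geolinked arm against exact-match, aggregated over the
    displacement replicates (displaced_A..E pooled as 'displaced') and
    strata: mean bias, mean absolute bias, and the fraction of contrasts
    whose paired-bootstrap interval excludes zero."""
    cov = coverage.copy()
    exact = cov[cov["method"] == "exact_match"].set_index(["scenario", "stratum"])["point_pct"]
    geo = cov[cov["method"] != "exact_match"].copy()
    geo["bias_pct"] = geo.apply(
        lambda r: r["point_pct"] - exact.loc[(r["scenario"], r["stratum"])], axis=1
    )
    geo["source_group"] = geo["location_source"].where(
        ~geo["location_source"].str.startswith("displaced_"), "displaced"
    )
    rows = []
    sig = None
    if comparisons is not None and not comparisons.empty:
        sig = comparisons[comparisons["reference"] == "exact_match"].copy()
        sig["source_group"] = sig["location_source"].where(
            ~sig["location_source"].str.startswith("displaced_"), "displaced"
        )
    for (scen, method, group), grp in geo.groupby(
        ["scenario", "method", "source_group"], sort=True
    ):
        row = {
            "scenario": scen,
            "method": method,
            "location_source": group,
            "mean_bias_pct": round(grp["bias_pct"].mean(), 3),
            "mean_abs_bias_pct": round(grp["bias_pct"].abs().mean(), 3),
        }
        if sig is not None:
            mask = (
                (sig["scenario"] == scen)
                & (sig["method"] == method)
                & (sig["source_group"] == group)
            )
            row["frac_significant"] = (
                round(sig.loc[mask, "significant"].mean(), 3) if mask.any() else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_outputs(result: ExperimentResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_landscape(result.landscape, out)
    events_to_frame(result.events).to_csv(out / "events.csv", index=False)
    clusters_to_frame(result.clusters).to_csv(out / "clusters.csv", index=False)
    frames = []
    for scen, scores in result.scenario_scores.items():
        df = scores_to_frame(result.baseline_scores, result.landscape.providers)[
            ["provider_id", "category"]
        ].copy()
        df["score"] = df["provider_id"].map(scores)
        df.insert(0, "scenario", scen)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(out / "provider_scores.csv", index=False)
    result.coverage.to_csv(out / "coverage_estimates.csv", index=False)
    result.linkage.to_csv(out / "linkage_accuracy.csv", index=False)
    if result.comparisons is not None and not result.comparisons.empty:
        result.comparisons.to_csv(out / "comparisons.csv", index=False)
    result.bias.to_csv(out / "bias_summary.csv", index=False)
    write_manifest(result.manifest, out / "manifest.json")
    _write_report(result, out / "report.txt")


def _write_report(result: ExperimentResult, path: Path) -> None:
    lines = ["Quality-adjusted effective coverage by linking method and location source", ""]
    lines.append("Percent of care-seeking children linked (any / true source):")
    for _, r in result.linkage.iterrows():
        true_s = "-" if pd.isna(r["pct_linked_true"]) else f"{r['pct_linked_true']:.1f}"
        lines.append(
            f"  {r['method']:<12} {r['location_source']:<14} {r['stratum']:<6} "
            f"any {r['pct_linked_any']:5.1f}%  true {true_s}%"
        )
    for scen in result.config.scenarios:
        lines.append("")
        lines.append(f"Scenario: {scen}")
        sub = result.coverage[result.coverage["scenario"] == scen]
        for _, r in sub.iterrows():
            ci = ""
            if not pd.isna(r["ci_low_pct"]):
                ci = f"  [{r['ci_low_pct']:.1f}, {r['ci_high_pct']:.1f}]"
            lines.append(
                f"  {r['method']:<12} {r['location_source']:<14} {r['stratum']:<6} "
                f"{r['point_pct']:5.1f}%{ci}"
            )
    path.write_text("\n".join(lines) + "\n")


def run_from_manifest(manifest_path: str | Path, out_dir: str | Path | None = None) -> ExperimentResult:
    """Re-execute a run from its manifest; every CSV output is reproduced
    byte-identically."""
    manifest = load_manifest(manifest_path)
    config = experiment_config_from_dict(manifest["config"])
    return run_experiment(config, seed=manifest["master_seed"], out_dir=out_dir)
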