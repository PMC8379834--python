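"""Tabular and GeoJSON serialisation of landscape and analysis objects.

Households, providers, events and clusters travel as CSV with documented
column schemas; the road network and admin polygon as GeoJSON in planar
local coordinates; run metadata as a JSON manifest.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
from shapely.geometry import mapping

from .clusters import ClusterPoint
from .landscape import CareSeekingEvent, HouseholdRecord, Landscape, ProviderAssessment, RoadNetwork
from .quality import ALL_DOMAINS, BINARY_DOMAINS


def households_to_frame(households: Sequence[HouseholdRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "household_id": h.household_id,
                "x": h.x,
                "y": h.y,
                "stratum": h.stratum,
                "n_children_u5": h.n_children_u5,
            }
            for h in households
        ]
    )


def providers_to_frame(providers: Sequence[ProviderAssessment]) -> pd.DataFrame:
    rows = []
    for p in providers:
        row = {"provider_id": p.provider_id, "x": p.x, "y": p.y, "category": p.category}
        for domain, n in BINARY_DOMAINS.items():
            for i in range(n):
                row[f"{domain}_{i + 1}"] = p.indicators[domain][i]
        row["knowledge_score"] = p.knowledge_score
        rows.append(row)
    return pd.DataFrame(rows)


def events_to_frame(events: Sequence[CareSeekingEvent]) -> pd.DataFrame:
    rows = []
    for e in events:
        rows.append(
            {
                "event_id": e.event_id,
                "household_id": e.household_id,
                "stratum": e.stratum,
                "care_sought": e.care_sought,
                "source_categories": ";".join(s.category for s in e.sources),
                "true_provider_ids": ";".join(
                    s.true_provider_id if s.true_provider_id is not None else "unknown"
                    for s in e.sources
                ),
            }
        )
    return pd.DataFrame(rows)


def clusters_to_frame(clusters: Sequence[ClusterPoint]) -> pd.DataFrame:
    labels = sorted({lab for c in clusters for lab in c.displaced})
    rows = []
    for c in clusters:
        row = {
            "cluster_id": c.cluster_id,
            "stratum": c.stratum,
            "n_members": c.n_members,
            "flagged_small": c.flagged_small,
            "x": c.x,
            "y": c.y,
        }
        for lab in labels:
            dx, dy = c.displaced.get(lab, (float("nan"), float("nan")))
            row[f"displaced_{lab}_x"] = dx
            row[f"displaced_{lab}_y"] = dy
        rows.append(row)
    return pd.DataFrame(rows)


def roads_to_geojson(network: RoadNetwork, path: str | Path) -> None:
    features = []
    for a, b, length_m, cls_ in network.edges:
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [list(network.nodes[a]), list(network.nodes[b])],
                },
                "properties": {"road_class": cls_, "length_m": round(length_m, 3)},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def polygon_to_geojson(polygon, path: str | Path, name: str = "admin") -> None:
    feature = {
        "type": "Feature",
        "geometry": mapping(polygon),
        "properties": {"name": name},
    }
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": [feature]}, fh)


def write_landscape(landscape: Landscape, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    households_to_frame(landscape.households).to_csv(out / "households.csv", index=False)
    providers_to_frame(landscape.providers).to_csv(out / "providers.csv", index=False)
    roads_to_geojson(landscape.roads, out / "roads.geojson")
    polygon_to_geojson(landscape.admin_polygon, out / "admin.geojson")


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def load_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
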