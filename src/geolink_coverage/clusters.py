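"""Cluster formation and DHS-style displacement of cluster central points.

Households are grouped into spatially compact clusters of a fixed size
(150 by default, mimicking survey enumeration areas built from a household
census); each cluster's central point is the arithmetic mean of its
members' coordinates. Central points are then geomasked the way DHS
displaces cluster coordinates: a uniform random angle and a random
distance capped at 2 km for urban clusters and 5 km for rural clusters,
with a small rural subset (1%) allowed up to 10 km, optionally restricted
to stay inside the administrative polygon by rejection resampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import Point, Polygon

from .config import DisplacementConfig
from .landscape import HouseholdRecord


@dataclass
class ClusterPoint:
    cluster_id: str
    member_household_ids: list[str]
    x: float
    y: float
    stratum: str
    flagged_small: bool = False
    displaced: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_members(self) -> int:
        return len(self.member_household_ids)


def _majority_stratum(households: Sequence[HouseholdRecord]) -> str:
    counts: dict[str, int] = {}
    for h in households:
        counts[h.stratum] = counts.get(h.stratum, 0) + 1
    # Deterministic tie-break: alphabetical (rural before urban).
    return max(sorted(counts), key=lambda s: counts[s])


def form_clusters(
    households: Sequence[HouseholdRecord],
    cluster_size: int = 150,
    seed: int = 0,
    max_sweeps: int = 20,
) -> list[ClusterPoint]:
    """Partition households into compact clusters of ``cluster_size``.

    Capacitated assignment: k = ceil(n / cluster_size) centroids are
    seeded by farthest-point initialisation, households are assigned by
    ascending household-centroid distance subject to capacity, centroids
    are updated, and the sweep repeats until the assignment is stable.
    Total capacity equals n exactly, so all clusters have exactly
    ``cluster_size`` members except a single remainder cluster, which is
    flagged. Deterministic given the seed.
    """
    if cluster_size < 1:
        raise ValueError("cluster_size must be >= 1")
    hh = list(households)
    n = len(hh)
    if n == 0:
        return []
    coords = np.array([(h.x, h.y) for h in hh])
    if n <= cluster_size:
        return [
            ClusterPoint(
                cluster_id="C000",
                member_household_ids=[h.household_id for h in hh],
                x=float(coords[:, 0].mean()),
                y=float(coords[:, 1].mean()),
                stratum=_majority_stratum(hh),
                flagged_small=n < cluster_size,
            )
        ]

    rng = np.random.default_rng(seed)
    k = math.ceil(n / cluster_size)
    remainder = n - (k - 1) * cluster_size
    capacities = np.full(k, cluster_size)
    capacities[-1] = remainder  # the remainder cluster, possibly smaller

    # Farthest-point initialisation.
    centroids = np.empty((k, 2))
    first = int(rng.integers(n))
    centroids[0] = coords[first]
    mind = np.linalg.norm(coords - centroids[0], axis=1)
    for j in range(1, k):
        centroids[j] = coords[int(np.argmax(mind))]
        mind = np.minimum(mind, np.linalg.norm(coords - centroids[j], axis=1))

    assignment = np.full(n, -1)
    for _sweep in range(max_sweeps):
        # Global greedy: take (household, centroid) pairs by ascending
        # distance, respecting capacities. Capacity sums to n, so every
        # cluster fills exactly.
        d = np.linalg.norm(coords[:, None, :] - centroids[None, :, :], axis=2)
        order = np.argsort(d, axis=None, kind="stable")
        new_assignment = np.full(n, -1)
        remaining = capacities.copy()
        unassigned = n
        for flat in order:
            i, j = divmod(int(flat), k)
            if new_assignment[i] != -1 or remaining[j] == 0:
                continue
            new_assignment[i] = j
            remaining[j] -= 1
            unassigned -= 1
            if unassigned == 0:
                break
        if np.array_equal(new_assignment, assignment):
            break
        assignment = new_assignment
        for j in range(k):
            centroids[j] = coords[assignment == j].mean(axis=0)

    clusters: list[ClusterPoint] = []
    for j in range(k):
        members = [hh[i] for i in range(n) if assignment[i] == j]
        pts = np.array([(h.x, h.y) for h in members])
        clusters.append(
            ClusterPoint(
                cluster_id=f"C{j:03d}",
                member_household_ids=[h.household_id for h in members],
                x=float(pts[:, 0].mean()),
                y=float(pts[:, 1].mean()),
                stratum=_majority_stratum(members),
                flagged_small=len(members) < cluster_size,
            )
        )
    return clusters


def displace_point(
    point: tuple[float, float],
    stratum: str,
    config: DisplacementConfig,
    admin_polygon: Polygon | None,
    rng: np.random.Generator,
    force_long: bool = False,
) -> tuple[float, float]:
    """Displace one point: uniform random angle, random distance up to the
    stratum's cap (10 km for the rural long-range subset).

    With ``restrict_to_admin`` the draw is rejection-resampled until the
    displaced point falls inside the admin polygon, preserving the
    angle/distance distributions conditional on containment.
    """
    if stratum == "urban":
        cap = config.cap_urban_m
    elif stratum == "rural":
        cap = config.cap_rural_long_m if force_long else config.cap_rural_m
    else:
        raise ValueError(f"unknown stratum {stratum!r}")
    restrict = config.restrict_to_admin and admin_polygon is not None
    for _ in range(10_000):
        angle = rng.uniform(0.0, 2.0 * math.pi)
        u = rng.uniform(0.0, 1.0)
        dist = cap * math.sqrt(u) if config.distance_dist == "uniform_area" else cap * u
        x = point[0] + dist * math.cos(angle)
        y = point[1] + dist * math.sin(angle)
        if not restrict or admin_polygon.covers(Point(x, y)):
            return (x, y)
    raise RuntimeError(
        "displacement rejection sampling exceeded 10000 draws; the admin "
        "polygon is too small relative to the displacement cap"
    )


def displace_replicates(
    cluster_points: Sequence[ClusterPoint],
    config: DisplacementConfig,
    admin_polygon: Polygon | None,
    seed: int,
) -> list[ClusterPoint]:
    """Fill each cluster's displaced map with labelled replicates (A..E).

    The rural long-range subset (round(frac_rural_long * n_rural)
    clusters) is drawn uniformly at random, independently per replicate
    by default.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    out = [
        ClusterPoint(
            cluster_id=c.cluster_id,
            member_household_ids=list(c.member_household_ids),
            x=c.x,
            y=c.y,
            stratum=c.stratum,
            flagged_small=c.flagged_small,
            displaced={},
        )
        for c in cluster_points
    ]
    rural_idx = [i for i, c in enumerate(out) if c.stratum == "rural"]
    n_long = int(round(config.frac_rural_long * len(rural_idx)))
    fixed_long: set[int] = set()
    if not config.long_subset_per_replicate and n_long > 0:
        fixed_long = set(rng.choice(rural_idx, size=n_long, replace=False).tolist())
    for label in config.replicate_labels():
        if config.long_subset_per_replicate and n_long > 0:
            long_set = set(rng.choice(rural_idx, size=n_long, replace=False).tolist())
        else:
            long_set = fixed_long
        for i, c in enumerate(out):
            c.displaced[label] = displace_point(
                (c.x, c.y),
                c.stratum,
                config,
                admin_polygon,
                rng,
                force_long=i in long_set,
            )
    return out


def household_cluster_map(clusters: Sequence[ClusterPoint]) -> dict[str, ClusterPoint]:
    mapping: dict[str, ClusterPoint] = {}
    for c in clusters:
        for hid in c.member_household_ids:
            if hid in mapping:
                raise ValueError(f"household {hid!r} appears in two clusters")
            mapping[hid] = c
    return mapping
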