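"""Quality-adjusted effective coverage and linkage-accuracy metrics.

Effective coverage is the mean structural quality score over all sick
children in a stratum: a child who sought no care contributes zero; a
child linked to a specific provider contributes that provider's score; a
child linked to several providers (multiple reported sources, or a radius
buffer) contributes the mean of their scores; an unlinkable child
contributes the mean score of the reported provider category. Uncertainty
comes from a percentile bootstrap over children within stratum, and
method-vs-method contrasts from a paired bootstrap over the same
children.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .landscape import CareSeekingEvent
from .linking import LinkAssignment
from .quality import QualityScore

EXACT_MATCH = "exact_match"


def _score_value(scores: Mapping[str, QualityScore] | Mapping[str, float], pid: str) -> float:
    s = scores[pid]
    return s.score if isinstance(s, QualityScore) else float(s)


@dataclass(frozen=True)
class ChildScoreRecord:
    event_id: str
    stratum: str
    method: str
    location_source: str
    assigned_score: float
    assignment_path: str  # no_care_zero | exact_match | geolink | category_mean_fallback | multi_source_mean


def assign_child_score(
    event: CareSeekingEvent,
    link: Optional[LinkAssignment],
    scores: Mapping[str, QualityScore] | Mapping[str, float],
    category_means: Mapping[str, float],
    method: str = "geolink",
    location_source: str = "",
) -> ChildScoreRecord:
    """Per-child assigned quality score under one linking arm.

    ``link`` is None for the exact-match arm (and for no-care children in
    any arm): exact-match uses each source's known true provider, falling
    back to the category mean when the specific provider is unknown.
    """
    if not event.care_sought:
        return ChildScoreRecord(
            event.event_id, event.stratum, method, location_source, 0.0, "no_care_zero"
        )
    per_source: list[float] = []
    used_fallback = False
    if link is None:  # exact-match arm
        for src in event.sources:
            if src.category not in category_means:
                raise ValueError(f"unknown category {src.category!r}")
            if src.true_provider_id is not None:
                per_source.append(_score_value(scores, src.true_provider_id))
            else:
                per_source.append(category_means[src.category])
                used_fallback = True
        base_path = EXACT_MATCH
    else:
        for src, ids in zip(event.sources, link.linked_ids):
            if src.category not in category_means:
                raise ValueError(f"unknown category {src.category!r}")
            if len(ids) == 0:
                per_source.append(category_means[src.category])
                used_fallback = True
            else:
                per_source.append(
                    sum(_score_value(scores, pid) for pid in ids) / len(ids)
                )
        base_path = "geolink"
    score = sum(per_source) / len(per_source)
    if len(per_source) > 1:
        path = "multi_source_mean"
    elif used_fallback:
        path = "category_mean_fallback"
    else:
        path = base_path
    return ChildScoreRecord(event.event_id, event.stratum, method, location_source, score, path)


def assign_scores(
    events: Sequence[CareSeekingEvent],
    links: Sequence[LinkAssignment] | None,
    scores: Mapping[str, QualityScore] | Mapping[str, float],
    category_means: Mapping[str, float],
    method: str,
    location_source: str = "",
) -> list[ChildScoreRecord]:
    """Child score records for every sick child under one arm.

    For the exact-match arm pass ``links=None`` and
    ``method="exact_match"``.
    """
    by_event = {l.event_id: l for l in links} if links is not None else {}
    out = []
    for ev in events:
        link = by_event.get(ev.event_id) if links is not None else None
        if links is not None and ev.care_sought and link is None:
            raise ValueError(f"missing link assignment for event {ev.event_id!r}")
        out.append(
            assign_child_score(ev, link, scores, category_means, method, location_source)
        )
    return out


def effective_coverage(child_scores: Sequence[ChildScoreRecord], stratum: str) -> float:
    """Mean assigned score over all sick children in the stratum (no-care
    zeros included)."""
    vals = [r.assigned_score for r in child_scores if r.stratum == stratum]
    if not vals:
        raise ValueError(f"no sick children in stratum {stratum!r}")
    return sum(vals) / len(vals)


def bootstrap_ci(
    child_scores: Sequence[ChildScoreRecord],
    stratum: str,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap interval for effective coverage, resampling
    children with replacement within the stratum."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    vals = np.array([r.assigned_score for r in child_scores if r.stratum == stratum])
    if len(vals) < 2:
        raise ValueError(f"need >= 2 children in stratum {stratum!r} for a bootstrap")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
    means = vals[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass(frozen=True)
class CoverageEstimate:
    method: str
    location_source: str
    stratum: str
    n_children: int
    point: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


def estimate_coverage(
    child_scores: Sequence[ChildScoreRecord],
    stratum: str,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> CoverageEstimate:
    recs = [r for r in child_scores if r.stratum == stratum]
    point = effective_coverage(child_scores, stratum)
    lo, hi = bootstrap_ci(child_scores, stratum, n_boot=n_boot, level=level, seed=seed)
    # Guard: the point estimate always lies inside its percentile interval
    # up to floating error; clip to preserve the invariant exactly.
    lo, hi = min(lo, point), max(hi, point)
    return CoverageEstimate(
        method=recs[0].method,
        location_source=recs[0].location_source,
        stratum=stratum,
        n_children=len(recs),
        point=point,
        ci_low=lo,
        ci_high=hi,
        n_boot=n_boot,
        seed=seed,
    )


@dataclass(frozen=True)
class ComparisonResult:
    difference: float  # mean(a) - mean(b)
    ci_low: float
    ci_high: float
    significant: bool
    n: int


def compare_estimates(
    child_scores_a: Sequence[ChildScoreRecord],
    child_scores_b: Sequence[ChildScoreRecord],
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> ComparisonResult:
    """Paired bootstrap of the difference in effective coverage between
    two arms computed on the same children.

    Children are resampled once per replicate and both means recomputed,
    respecting the pairing; the contrast is significant when the interval
    excludes zero.
    """
    a = {r.event_id: r.assigned_score for r in child_scores_a}
    b = {r.event_id: r.assigned_score for r in child_scores_b}
    if set(a) != set(b):
        raise ValueError("paired comparison requires identical event sets")
    ids = sorted(a)
    va = np.array([a[i] for i in ids])
    vb = np.array([b[i] for i in ids])
    diff = float(va.mean() - vb.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(ids), size=(n_boot, len(ids)))
    d = va[idx].mean(axis=1) - vb[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(d, [alpha, 1.0 - alpha])
    return ComparisonResult(
        difference=diff,
        ci_low=float(lo),
        ci_high=float(hi),
        significant=not (lo <= 0.0 <= hi),
        n=len(ids),
    )


def linkage_accuracy(
    links: Sequence[LinkAssignment], events: Sequence[CareSeekingEvent]
) -> pd.DataFrame:
    """Percent of care-seeking children linked to any provider and to the
    true source, by method x location source x stratum.

    Linked-to-true is reported only for the single-closest methods
    (euclidean, travel_time), among children with at least one known true
    provider.
    """
    stratum_of = {e.event_id: e.stratum for e in events if e.care_sought}
    rows = []
    df = pd.DataFrame(
        [
            {
                "event_id": l.event_id,
                "method": l.method,
                "location_source": l.location_source,
                "linked_any": l.linked_any,
                "linked_true": l.linked_true,
            }
            for l in links
        ]
    )
    if df.empty:
        return pd.DataFrame(
            columns=["method", "location_source", "stratum", "n", "pct_linked_any", "pct_linked_true"]
        )
    df["stratum"] = df["event_id"].map(stratum_of)
    for (method, source, stratum), grp in df.groupby(
        ["method", "location_source", "stratum"], sort=True
    ):
        pct_any = 100.0 * grp["linked_any"].mean()
        if method in ("euclidean", "travel_time"):
            known = grp["linked_true"].dropna()
            pct_true = 100.0 * known.astype(bool).mean() if len(known) else np.nan
        else:
            pct_true = np.nan
        rows.append(
            {
                "method": method,
                "location_source": source,
                "stratum": stratum,
                "n": len(grp),
                "pct_linked_any": round(pct_any, 1),
                "pct_linked_true": round(pct_true, 1) if pct_true == pct_true else np.nan,
            }
        )
    return pd.DataFrame(rows)
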