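"""Quality-reassignment sensitivity scenarios.

The homogeneous-quality setting of the primary analysis limits how much a
mislinked child can change the coverage estimate. Two scenarios probe
settings with greater quality diversity while keeping locations, links
and care-seeking behavior fixed:

* preferential — providers seeing more than their category's median
  number of reported visits gain two within-category standard deviations
  of the original scores; never-used or below-median providers lose two,
  simulating selective bypassing of lower-quality providers;
* random — every provider's score is replaced by an independent
  Uniform[0, 1] draw (median ~50%, IQR ~25-75%).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np

from .config import ScenarioSpec
from .landscape import CareSeekingEvent, ProviderAssessment
from .quality import QualityScore


def _plain_scores(scores: Mapping[str, QualityScore] | Mapping[str, float]) -> dict[str, float]:
    return {
        pid: (s.score if isinstance(s, QualityScore) else float(s))
        for pid, s in scores.items()
    }


def utilization_counts(
    events: Sequence[CareSeekingEvent], providers: Iterable[ProviderAssessment]
) -> dict[str, int]:
    """Reported visits per provider, with explicit zeros for providers no
    sampled child reported using. Each reported source counts once, so
    multi-source events contribute one visit per named source."""
    counts = {p.provider_id: 0 for p in providers}
    for ev in events:
        if not ev.care_sought:
            continue
        for src in ev.sources:
            if src.true_provider_id is not None:
                if src.true_provider_id not in counts:
                    raise ValueError(f"event {ev.event_id} names unknown provider")
                counts[src.true_provider_id] += 1
    return counts


def preferential_quality_reassignment(
    scores: Mapping[str, QualityScore] | Mapping[str, float],
    counts: Mapping[str, int],
    providers: Sequence[ProviderAssessment],
    spec: ScenarioSpec,
) -> dict[str, float]:
    """Shift scores by +/- sd_multiplier within-category SDs according to
    utilization rank.

    Per category: providers above the median visit count gain, providers
    with zero or below-median visits lose, exact-median providers with at
    least one visit are unchanged. The SD is the sample SD (n-1) of the
    category's original scores; single-provider categories are left
    unchanged with a warning. Adjusted scores are clipped to [0, 1]
    unless ``spec.clip_to_unit`` is off.
    """
    spec.validate()
    plain = _plain_scores(scores)
    out = dict(plain)
    by_cat: dict[str, list[ProviderAssessment]] = {}
    for p in providers:
        by_cat.setdefault(p.category, []).append(p)
    for cat, provs in sorted(by_cat.items()):
        if len(provs) < 2:
            warnings.warn(f"category {cat!r} has a single provider; scores unchanged")
            continue
        pids = [p.provider_id for p in provs]
        cat_counts = np.array([counts[pid] for pid in pids])
        if not spec.include_unused_in_median:
            used = cat_counts[cat_counts > 0]
            m = float(np.median(used)) if len(used) else 0.0
        else:
            m = float(np.median(cat_counts))
        s = float(np.std([plain[pid] for pid in pids], ddof=1))
        delta = spec.sd_multiplier * s
        for pid, c in zip(pids, cat_counts):
            if c > m:
                out[pid] = plain[pid] + delta
            elif c == 0 or c < m:
                out[pid] = plain[pid] - delta
            # c == m with c > 0: unchanged
            if spec.clip_to_unit:
                out[pid] = min(1.0, max(0.0, out[pid]))
    return out


def random_quality(
    providers: Sequence[ProviderAssessment], spec: ScenarioSpec
) -> dict[str, float]:
    """Independent Uniform[0, 1] score per provider, deterministic given
    the spec's seed; draw order follows sorted provider ids."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pids = sorted(p.provider_id for p in providers)
    draws = rng.uniform(0.0, 1.0, size=len(pids))
    return {pid: float(v) for pid, v in zip(pids, draws)}


def apply_scenario(
    name: str,
    scores: Mapping[str, QualityScore] | Mapping[str, float],
    events: Sequence[CareSeekingEvent],
    providers: Sequence[ProviderAssessment],
    spec: ScenarioSpec | None = None,
) -> dict[str, float]:
    """Dispatch a named scenario; baseline returns the original scores."""
    spec = spec or ScenarioSpec(name=name)
    if name == "baseline":
        return _plain_scores(scores)
    if name == "preferential":
        counts = utilization_counts(events, providers)
        return preferential_quality_reassignment(scores, counts, providers, spec)
    if name == "random":
        return random_quality(providers, spec)
    raise ValueError(f"unknown scenario {name!r}")
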