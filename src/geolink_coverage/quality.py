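"""Structural quality scoring of providers from a SARA-style checklist.

A provider's readiness to manage common child illness is summarised by six
equally weighted domains: diagnostics (4 binary indicators), basic
medicines (4), severe/complicated-illness medicines (3), human resources
(3), available services (5), and knowledge (the mean performance on four
clinical case scenarios, a continuous fraction). Each binary domain scores
the fraction of its indicators met; the composite score is the arithmetic
mean of the six domain scores, ranging from 0 (no capacity to provide
care) to 1 (full capacity), rendered as a percent only at report
boundaries.

Composite indicators (e.g. "malaria diagnostic: RDT or microscopy") must
be resolved to a single binary upstream; the scorer is a pure function of
19 binaries plus the knowledge fraction. All 19 indicators are scored for
every category, including community-level providers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping

import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .landscape import ProviderAssessment

#: Binary checklist domains and their indicator counts.
BINARY_DOMAINS: dict[str, int] = {
    "diagnostics": 4,
    "basic_medicines": 4,
    "severe_medicines": 3,
    "human_resources": 3,
    "available_services": 5,
}

KNOWLEDGE_DOMAIN = "knowledge"

#: The six equally weighted domains, in reporting order.
ALL_DOMAINS: tuple[str, ...] = tuple(BINARY_DOMAINS) + (KNOWLEDGE_DOMAIN,)


@dataclass(frozen=True)
class QualityScore:
    provider_id: str
    score: float
    domain_scores: dict[str, float]


def domain_score(indicator_values: Iterable[int], domain: str) -> float:
    """Score one binary domain as the fraction of indicators met.

    The knowledge domain is not scored here: it is carried as a
    pre-computed fraction on the assessment itself.
    """
    if domain == KNOWLEDGE_DOMAIN:
        raise ValueError(
            "knowledge is a continuous domain stored on the assessment; "
            "domain_score only handles binary checklist domains"
        )
    if domain not in BINARY_DOMAINS:
        raise ValueError(f"unknown domain {domain!r}")
    values = list(indicator_values)
    expected = BINARY_DOMAINS[domain]
    if len(values) != expected:
        raise ValueError(
            f"domain {domain!r} expects {expected} indicators, got {len(values)}"
        )
    for v in values:
        if v not in (0, 1, True, False):
            raise ValueError(f"indicator values must be binary, got {v!r}")
    return sum(values) / expected


def structural_quality_score(assessment: "ProviderAssessment") -> QualityScore:
    """Equal-domain-weight composite score of one provider assessment."""
    domains: dict[str, float] = {}
    for domain in BINARY_DOMAINS:
        if domain not in assessment.indicators:
            raise ValueError(f"assessment {assessment.provider_id} missing domain {domain!r}")
        domains[domain] = domain_score(assessment.indicators[domain], domain)
    k = assessment.knowledge_score
    if not 0.0 <= k <= 1.0:
        raise ValueError(f"knowledge_score must be in [0, 1], got {k}")
    domains[KNOWLEDGE_DOMAIN] = k
    score = sum(domains[d] for d in ALL_DOMAINS) / len(ALL_DOMAINS)
    return QualityScore(provider_id=assessment.provider_id, score=score, domain_scores=domains)


def score_all(assessments: Iterable["ProviderAssessment"]) -> dict[str, QualityScore]:
    return {a.provider_id: structural_quality_score(a) for a in assessments}


def category_mean_score(
    scores: Mapping[str, QualityScore] | Mapping[str, float],
    providers: Iterable["ProviderAssessment"],
    category: str,
) -> float:
    """Unweighted mean score of the providers in one category.

    Used as the fallback score for children who could not be linked to a
    specific provider.
    """
    vals = []
    for p in providers:
        if p.category == category:
            s = scores[p.provider_id]
            vals.append(s.score if isinstance(s, QualityScore) else float(s))
    if not vals:
        raise ValueError(f"no providers in category {category!r}")
    return sum(vals) / len(vals)


def category_means(
    scores: Mapping[str, QualityScore] | Mapping[str, float],
    providers: Iterable["ProviderAssessment"],
) -> dict[str, float]:
    """Mean score per category, for every category present among providers."""
    providers = list(providers)
    cats = sorted({p.category for p in providers})
    return {c: category_mean_score(scores, providers, c) for c in cats}


def scores_to_frame(
    scores: Mapping[str, QualityScore], providers: Iterable["ProviderAssessment"]
) -> pd.DataFrame:
    """Provider-scores table: provider_id, category, six domain columns, score."""
    cat = {p.provider_id: p.category for p in providers}
    rows = []
    for pid in sorted(scores):
        q = scores[pid]
        row = {"provider_id": pid, "category": cat.get(pid, "")}
        row.update({d: q.domain_scores[d] for d in ALL_DOMAINS})
        row["score"] = q.score
        rows.append(row)
    return pd.DataFrame(rows)
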