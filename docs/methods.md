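# Methods

This note documents the generative model, the linking and estimation
procedures, the default parameters and where they come from, and what
the synthetic design can and cannot say about real survey data.

## 1. Synthetic landscape

All geometry lives in a planar local frame in meters. The study area is
a 24 × 16 km rectangle (the admin polygon) containing a 5 × 5 km urban
core; the remainder is the rural stratum. At district scale the error
from ignoring geodesy is far below the location errors under study, and
a planar frame makes every distance oracle exact.

**Households.** 335 rural and 469 urban households (the enrolled
population of the motivating field study) are placed by a Neyman–Scott
cluster process: uniform parent points (one per ~12 rural / ~25 urban
households) with Gaussian offspring dispersion (σ = 600 m rural, 150 m
urban), rejected back into the stratum region. This produces the
village/compound structure that makes 150-household survey clusters
geographically large in rural areas and compact in town — the feature
that drives the rural/urban asymmetry in location error. Children under
five per household follow a truncated Poisson on {1, 2, 3} with rate
1.30 (rural) and 0.28 (urban), matching the observed ≈1.63 and ≈1.15
children per enrolled household (547 and 537 children per stratum in
expectation). Illness is independent across children.

**Providers.** Seven categories (government hospital, government health
center/post, government CBA/fieldworker, private hospital/clinic,
pharmacy, shop/market, traditional/faith practitioner). Counts per
category and stratum are a design choice — the motivating study
enumerated a provider census but published no counts — set once to a
realistic district mix: 6 health centers/posts (the handful of facility
catchment areas), 18 community-based agents mostly rural, 1 hospital,
1 private clinic, 3 pharmacies, 16 shops, 7 traditional practitioners.
Providers are placed uniformly within their stratum.

**Readiness checklists.** Each provider's 19 binary indicators are
independent Bernoulli draws at a category-level probability
(`QualityProfile`), and the knowledge score is the mean of four
simulated case scenarios, each Bernoulli at the category's knowledge
mean. The default profile (hospital 0.95, health center 0.85, private
clinic 0.85, CBA 0.65, pharmacy 0.45, shop 0.10, traditional 0.05)
reproduces the empirical regime of strong between-category and mild
within-category variation. `QualityProfile.homogeneous()` rounds every
probability to 0 or 1, giving exactly zero within-category variance —
the degenerate regime used to demonstrate the null-result mechanism.

**Roads.** A grid with 2 km spacing covers the area (so no point is
farther than ~1.4 km from a node, inside the 2 km off-road cap), with
diagonal footpaths in every cell so that walking routes are
near-isotropic rather than rectilinear. A paved trunk crosses the area
at 15% of its height — skirting, not bisecting, the urban core — and
graded branches run perpendicular every 12 km; everything else is
footpath. Nodes off the fast roads are jittered ±200 m. Default speeds:
paved 60 km/h, graded 25 km/h, footpath 5 km/h, off-road walking
4 km/h; the speeds are configurable and recorded in the run manifest.

**Care-seeking.** One event per sick child. Illness prevalence (36.4%
rural, 34.6% urban), care-seeking (78.9% / 66.7%), the category mix
(health centers ≈61/60% of sick children, CBAs 18% rural, shops 5%
urban, …) and the multi-source rate (5.7% / 4.0% of care-seekers) are
calibrated to the field study's reported event table. The specific
provider within the drawn category follows a nearest-choice model: with
probability 0.78 the child uses the nearest provider, otherwise one of
the next three nearest, uniformly. "Nearest" is measured in *walking*
time (equivalently, straight-line distance) by default: caregivers with
sick children predominantly walk, whereas the analyst's travel-time
method assumes vehicle speeds on the road network. This asymmetry is
deliberate — it reproduces the observed pattern that Euclidean linking
from household locations identifies the true source more often than
travel-time linking does. Setting `choice_metric="travel_time"` makes
behavior follow the network metric instead; a gravity model
(P ∝ exp(−d/λ)·exp(β·quality)) is also available. The probability that
a caregiver cannot name the specific provider is category-specific
(0.8 for shops, 0.1 for traditional practitioners, 0.005 otherwise),
which reproduces exact-match completeness of ≈99% rural / ≈93–94%
urban.

## 2. Quality scoring

Each binary domain scores the fraction of its indicators met
(diagnostics 4, basic medicines 4, severe-illness medicines 3, human
resources 3, available services 5); knowledge is carried as a
continuous fraction rather than binarized. The composite is the
unweighted mean of the six domain scores, so one complete domain is
worth exactly 1/6 regardless of its indicator count. Scores are stored
as fractions in [0, 1] and rendered as percent only at report
boundaries, which avoids 100× unit bugs. Composite indicators
("RDT *or* microscopy") must be resolved to one binary upstream; all 19
indicators are scored for every category, including community-level
providers — arguably severe-illness medicines are not applicable to
CBAs, but the assessment instrument did not exempt them, and this
implementation follows suit.

## 3. Clusters and displacement

Households are partitioned into spatially compact clusters of exactly
150 (the survey's enumeration-area size) by capacitated assignment:
k = ⌈n/150⌉ centroids seeded by farthest-point initialisation,
households assigned in order of ascending household–centroid distance
subject to capacity, centroids updated, and the sweep repeated until
stable (≤20 sweeps). Total capacity equals n exactly, so every cluster
has 150 members except a single flagged remainder cluster (804
households → five clusters of 150 plus one of 54). The global-distance
ordering — rather than a random household order — makes the remainder
cluster unique by construction and the partition deterministic given
the seed. A cluster's central point is the arithmetic mean of member
coordinates and its stratum the member majority.

Displacement draws a uniform angle on [0, 2π) and a distance uniform on
[0, cap], with cap 2 km (urban), 5 km (rural), or 10 km for a rural
long-range subset of round(1% × n_rural) clusters, redrawn
independently per replicate (the convention when the subset's
persistence across replicates is unspecified; a flag fixes it instead).
Uniform-on-distance is the documented DHS convention; uniform-on-area
is available via `distance_dist`. Five labelled replicates (A–E) are
produced. When admin restriction is on, draws are rejection-resampled
until the displaced point is inside the polygon — preserving the
angle/distance law conditional on containment, unlike clipping — and
an error is raised after 10,000 failed draws.

## 4. Linking

All three methods are restricted to providers of the reported category.

* **Euclidean**: argmin of planar distance; ties broken by provider id
  for determinism.
* **Travel time**: origin and destination snap to their nearest network
  node; time = off-road walk + shortest network path (edge minutes =
  length/speed) + off-road walk, *or* the direct off-road walk,
  whichever is faster. The direct-walk alternative matters: without it,
  a 600 m trip can cost 50 minutes of snap-node detour while a 3 km
  trip costs 24, and that artifact — not geography — would drive link
  orderings at sub-grid scales. Ties break by Euclidean distance, then
  provider id. Shortest-path trees are cached per snap node.
* **5 km radius**: all category providers within 5000 m (Euclidean,
  boundary inclusive — the method approximates an isotropic one-hour
  walk buffer), possibly none.

Neither single-closest method caps the link distance, so they link
every child; the radius method can leave a child unlinked. Multi-source
events are linked independently per reported source from the same
origin. An event counts as *linked to its true source* only if every
reported source with a known true provider was linked to exactly that
provider (or, for the radius method, to a set containing it); events
with no recallable source are excluded from that denominator.

## 5. Coverage estimation and uncertainty

Per-child scores follow the assignment rules in the README; effective
coverage is the stratum mean over all sick children including the
no-care zeros. Uncertainty is a percentile bootstrap (default 1000
replicates) resampling children within stratum; cluster-level
resampling would be the design-based alternative and is a recognised
limitation, since children within a cluster share geography.
Method-vs-method contrasts use a *paired* bootstrap — children are
resampled once and both arm means recomputed — because the same
children appear in every arm, which CI-overlap checks ignore. A
contrast is "significant" when the 95% interval excludes zero. The
original analysis never names its test; this procedure is a documented
stand-in, not a claim about what was done there.

**Homogeneity identity.** If every provider within each category has an
identical score, every linking arm's estimate equals exact-match
*exactly*: any assigned provider of the right category carries the
right score, the radius-set mean is that score, and the category-mean
fallback is that score. The test suite asserts this to 1e-12 at module
level and to <1 percentage point at full-study scale. This identity is
the mechanism behind the null result in homogeneous-quality settings.

## 6. Sensitivity scenarios

Scenarios reassign provider scores while freezing geometry, links and
behavior. **Preferential**: within each category, providers above the
median reported-visit count gain two within-category sample standard
deviations (ddof = 1) of the original scores, providers with zero or
below-median visits lose two; exact-median providers with at least one
visit are unchanged (the tie case is unspecified in the source
procedure and flagged here); never-used providers are included in the
median (a flag excludes them); adjusted scores are clipped to [0, 1] by
default. Single-provider categories are left unchanged with a warning
(the SD is undefined). **Random**: independent Uniform[0, 1] per
provider — median ≈50%, IQR ≈25–75% — drawn in sorted-provider-id order
for determinism.

## 7. Experiment pipeline, determinism and problem sizes

One run = 1 landscape × 5 displacement replicates, i.e. 3 scenarios ×
(3 methods × 7 location sources + exact-match) × 2 strata = 132
coverage estimates, plus 234 paired contrasts and the linkage-accuracy
table; `analysis/05_bias_monte_carlo.py --repeat N` wraps independent
repetitions for Monte-Carlo summaries (default 10). All component seeds
(landscape, care-seeking, displacement, bootstrap, scenario) are
derived from one master seed via `SeedSequence` and recorded in the run
manifest; re-running from the manifest reproduces every CSV
byte-identically. Default problem sizes (804 households, ~1100
children, 52 providers, ~120-node road network, 1000 bootstrap
replicates) keep a full run under ten seconds on one core, so the test
suite exercises the complete study repeatedly rather than a toy
excerpt.

## 8. What the generator does and does not emulate

Emulated: two strata with contrasting household density; cluster-size-
induced location error; DHS displacement law and caps; a provider
census with category-structured readiness; category-restricted linking;
care-seeking rates, category mix, multi-source events, and imperfect
provider recall at the reported frequencies.

Not emulated: enumeration-area boundaries (clusters are built from the
household census itself, so central points sit closer to households
than real EA centroids would — biases measured here are conservative);
within-household illness correlation; seasonal dynamics; GPS
measurement error and urban/rural misclassification; survey weights and
loss to follow-up; real road topology from OSM; raster friction
surfaces or one-way roads. Passing tests therefore demonstrate the
*mechanisms* — which linking arms are fragile and why — not the
magnitude of bias in any particular country's survey.

## 9. Known limitations

* The nearest-choice model is stationary and ignores bypassing for
  perceived quality except through the optional gravity term.
* Travel-time snapping is node-based; edge-interior snapping would
  reduce residual detour error (bounded by half the 2 km edge length).
* The child-level bootstrap understates variance relative to
  cluster-level resampling in strongly clustered designs.
* Provider counts per category are a scenario choice; absolute coverage
  levels move with them, though the bias *orderings* studied here were
  stable across the layouts explored during design.
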