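# Methods

This note documents the statistical models, the numerical choices, and the
design decisions behind `isoniche`, in the spirit of the model documentation
that accompanies packages such as statsmodels or msprime.

## Data model and scale

All analyses operate on per-individual (δ¹³C, δ¹⁵N) pairs in per-mil (‰),
grouped by species within one ecosystem. Point coordinates follow the
bi-plot convention (x = δ¹³C, y = δ¹⁵N). One taxon per ecosystem is the
designated *baseline*; everything downstream of standardization lives on
the baseline-centered scale, so "standardized δ¹⁵N = 4.7" means 4.7 ‰ above
the local baseline mean.

## Baseline standardization and comparability

Standardization subtracts the baseline group's mean (δ¹⁵N, δ¹³C) from every
sample in the community. It is exactly shift-invariant and idempotent, both
asserted as property tests. A baseline with n = 1 is allowed for
standardization (its mean is the single value) but not for comparability
checking, which needs a CI.

Whether two ecosystems may share a baseline is an *operational* question the
literature leaves loose ("similar ranges"). We fix it as: the two-sided 95%
t-intervals of the baseline means must intersect in **both** isotopes,
with closed intervals (touching endpoints overlap). The check is symmetric
by construction. An alternative reading — overlap of raw data ranges rather
than mean CIs — is defensible; the mean-CI rule was chosen because it
sharpens with sample size instead of widening. When no shared baseline
exists at all (the whirligig-beetle situation: the donor study had no
macrophyte), superimposition can proceed against the target's own baseline
under an explicit `allow_incomparable` flag, and the verdict is recorded in
the audit trail rather than silently accepted — the caveat travels with the
result.

Superimposition inserts the donor's standardized group with
`provenance="donor"` and never re-centers anything; resident samples are
bitwise untouched (tested).

## Layman metrics

NR, CR, TA, CD, NND, SDNND over a point cloud; community versions pool the
*individuals* of all included groups (baseline included), not species
means. Pooling individuals is what makes the community carbon range equal
the span between the single most extreme individuals across species — the
reading confirmed by the case study's printed community CR. TA is the
convex-hull area (scipy Qhull; degenerate inputs give 0), cross-checked
against an exhaustive orientation-test hull oracle at 1e-9. Nearest
neighbours are decided purely by distance (ties irrelevant); duplicated
points contribute 0 to NND. SDNND uses the n−1 denominator, matching the
field's R convention.

## Ellipse niches

For a fitted group (unbiased sample covariance Σ, n ≥ 3):

* SEA = π√det(Σ) — the standard (1 Mahalanobis unit) ellipse, exact
  coverage 1 − e^(−1/2) ≈ 39.35%, conventionally reported as "40%".
* SEAc = SEA·(n−1)/(n−2).
* area at coverage q = π·χ²₂(q)·√det(Σ)·(n−1)/(n−2), so
  SEAb/SEAc = χ²₂(0.95) ≈ 5.9915 identically.

The "40%" level is implemented as the standard ellipse (χ² scale exactly 1)
rather than the literal 0.40 quantile (scale 1.0217): only the former
reproduces the ×5.99 SEAc→SEAb scaling that the case-study tables print.
The same (n−1)/(n−2) correction is applied at every coverage so the ratio
stays exact.

Ellipse–ellipse intersection discretizes both boundaries as 720-vertex
polygons and clips them exactly (shapely). The inscribed-polygon area error
is O(1/m²) ≈ 1.3e-5 relative at m = 720, far inside the stated 1e-3
tolerance; a uniform-box rejection sampler is provided as an independent
cross-check and the two agree within 3 Monte Carlo SEs in tests. Percent
overlap is percent of the union, 100·I/(A+B−I) — the convention validated
by reproducing the eel block of the printed overlap table. (The tench
block of that table is not reproducible under union, either-species or
min/max-denominator conventions from its printed areas; it is documented
as irreconcilable and carries no numeric target.) A "Bayesian SEA" is
available as posterior draws of π√det(Σ) under the conjugate
inverse-Wishart; the point estimate remains the reported default since the
reference tables print single numbers.

## Directional niche probability

Each species gets a conjugate normal–inverse-Wishart posterior:
μ₀ = sample mean, κ₀ = 1e-3, ν₀ = 3 (minimal proper), Ψ₀ = 1e-3·I.
Centering the vague prior on the sample mean makes the posterior mean exact
and the prior contribute spread only; posterior draws are Σ ~ IW(ν₀+n,
Ψ₀+S) and μ | Σ ~ N(x̄, Σ/(κ₀+n)), with S the scatter matrix. A hand-computed
three-point update and a large-n concentration check pin the update
equations in tests.

P(A→B) pairs 20,000 posterior draws (the configured chain length; 20.000 in
the source's European notation), samples 10 posterior-predictive points of
A per draw, and counts the fraction inside B's α = 0.95 ellipse
(Mahalanobis² ≤ χ²₂(α) under B's drawn (μ, Σ)). Reported as percent with
the Monte Carlo SE of the mean fraction. Self-overlap calibrates to ≈ 95%
and the quantity is invariant under a common rigid motion of both datasets
(tested). Direction matters: a narrow niche nested in a wide one scores
high A→B and low B→A.

## Trophic position

Point estimator: TP = λ + δ¹⁵N_std/Δ_N with λ = 2 and Δ_N = 3.4 ‰. λ = 2 is
the natural level for a primary-producer baseline and is the unique choice
that reproduces the six reconcilable printed TPs of the case study (λ = 1
fails all six). The TDF defaults Δ_N ~ N(3.4, 0.98), Δ_C ~ N(0.39, 1.3) ‰
are the classic meta-analytic values; Δ_C rides along for the mixing model
but never enters TP. (One printed TP — the beetle's 2.1 against a
standardized mean of −4.9 — is arithmetically impossible under any λ and is
excluded everywhere, as the source itself flags a baseline problem for that
species.)

The Bayesian estimator models consumer δ¹⁵N ~ N(b + Δ_N(TP−λ), σ²) and
baseline δ¹⁵N ~ N(b, σ_b²), with the TDF distribution as the Δ_N prior and
half-Cauchy(5) scales. The sampler is adaptive random-walk Metropolis
(2 chains × 10,000 iterations, first half discarded, acceptance tuned to
0.3 during warm-up in blocks of 200). Crucially it samples the *enrichment*
Δμ = Δ_N(TP−λ) rather than TP itself: the likelihood constrains only the
product, so sampling (TP, Δ_N) directly walks a curved ridge and stalls,
whereas (Δμ, Δ_N) are nearly independent and split-R̂ lands at ~1.01.
TP = λ + Δμ/Δ_N is reconstructed per draw. R̂ > 1.1 attaches a
non-convergence warning to the result. Posterior medians track the point
estimator within 0.15 and recover a known generating TP in tests.

## Mixing model

Consumer values are normal with mixture mean Σₖ pₖ(μₖ + TDFₖ) and variance
Σₖ pₖ²(sₖ² + TDF_sdₖ²) + σⱼ² per isotope j — the standard SIMM formulation
with process plus residual error. Prior: Dirichlet(1,…,1) on **p**,
half-Cauchy(5) on residual scales. The simplex is parameterized by K
unconstrained log-gamma coordinates (p = g/Σg with gₖ = e^{wₖ}, wₖ having
the log-Exp(1) density), which maps iid Exp(1) variates exactly onto a flat
Dirichlet — verified by a prior-only run recovering marginal means 1/K and
Beta(1, K−1) variance. Sampling is adaptive Metropolis, 4 chains × 10,000
iterations, half warm-up, split-R̂ per proportion. Sources are canonically
sorted inside the sampler and un-permuted afterwards, which makes source
order irrelevant bit-for-bit under a fixed seed.

Scenario assembly enforces the one-native-at-a-time rule: superimposed
natives belong to different energy pathways, and fitting two at once would
let the model trade one for the other meaninglessly, so that request raises
a `ConfoundingError`. A single consumer point with ≥ 3 sources is accepted
but flagged with an identifiability warning. The "did the predator eat it"
summary is P(p_source > t) with configurable threshold (default t = 0.05),
since no fixed printed definition of that probability exists to hard-code.

## Synthetic data

The generator draws each species as a bivariate normal with diagonal
covariance (no C–N correlation is assumed anywhere in the workflow;
correlation is available as a spec field for property tests). Published
tables print means with min–max ranges, not SDs; ranges convert as
sd = range/4 (±2 SD spans the range), overridable. Each ecosystem adds a
raw baseline offset to every value so that standardization is exercised
nontrivially — offsets are chosen as plausible raw macrophyte signatures
(e.g. δ¹³C ≈ −27, δ¹⁵N ≈ 8 for the target lake) but their exact values are
irrelevant by shift invariance. Generators are pure functions of
(spec, seed).

The packaged case-study fixture reproduces the published species table:
target lake with bass (n=15), pumpkinseed (15), carp (11), red swamp
crayfish (15) over a macrophyte baseline (5), and three donor ecosystems
holding tench (26), eel (45) and whirligig beetle (17). What the fixture
emulates is the *summary structure* (means, spreads, n); what it cannot
emulate is the raw data's skew, seasonal structure or C–N correlation.
Consequently tests pin only quantities that are functions of that summary
structure (counts, means, ranges, TP, the χ² area scaling, near-zero vs
near-one probabilities), never the individual-level statistics (CD, NND,
SDNND, absolute SEAc/TA values, or the mid-range overlap probabilities of
the printed tables), which depend on the unpublished raw samples.

## Numerical choices and degenerate inputs

* Ellipse boundary discretization 720 vertices; boundary export 180.
* Collinear/duplicate point sets: hull area 0; covariance singular →
  niche flagged degenerate (SEA 0), intersections refuse degenerate input.
* Zero-variance baselines give degenerate CIs [c, c]; closed-interval
  overlap still behaves.
* All RNG flows through `numpy.random.default_rng` seeds; every stochastic
  routine takes an explicit seed and is bit-reproducible under it.
* Rounding for human-facing tables defaults to 2 decimals; round-tripping
  preserves values to the formatted precision.

## Problem sizes

Defaults mirror the study conditions: 20,000 posterior draws for niche
probabilities, 2×10,000 MCMC iterations for trophic positions, 4×10,000
for mixing models, 720-vertex clipping for intersections. The test suite
runs reduced but structurally identical sizes (1,500–4,000 draws, 2,000–
3,000 iterations) where the assertion concerns calibration rather than
Monte Carlo precision; the acceptance script uses the full 20,000-draw
setting for the directional-probability check.

## Known limitations

* Two-baseline trophic-position models, concentration-dependent or routed
  mixing models, and non-elliptical (kernel/hull) niche regions are out of
  scope.
* The comparability rule tests mean similarity, not distributional
  similarity; two baselines with equal means but very different spreads
  pass it.
* Directional probabilities inherit the bivariate-normal niche assumption;
  heavy-tailed or multimodal niches will be summarized optimistically.
* The mixing model's identifiability degrades with more than ~3 sources at
  these sample sizes; R̂ and CI widths are the guardrails, and warnings are
  attached rather than results suppressed.
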