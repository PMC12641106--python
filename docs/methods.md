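# Methods

## The estimator

Average taxonomic distinctness (Δ⁺) of a presence/absence assemblage is
the arithmetic mean of pairwise distinctness weights over all s(s−1)/2
unordered species pairs. The weight of a pair is a step value determined
by the lowest Linnaean rank the two species share, read from a five-rank
lineage (species → genus → family → order → class). Exactly these five
ranks are used; there are no subspecies, suborders or superfamilies, and
no branch lengths — the method is deliberately phylogeny-free so that it
can run on checklist data.

Two step dialects are built in:

| lowest shared rank | `step1` (default) | `w0` |
|---|---|---|
| genus | 1 | 0 |
| family | 2 | 1 |
| order | 3 | 2 |
| class | 4 | 3 |
| none (different classes) | 5 | 4 |

The dialects differ by a uniform +1 on every weight, so for any assemblage
Δ⁺(step1) = Δ⁺(w0) + 1 exactly; this identity is property-tested and is
also recomputed by the acceptance script. `step1` is the default because
it is the convention under which published regional Δ⁺ magnitudes for
marine tetrapods are reproducible: values above 3 for within-class
assemblages are impossible under `w0`, whose maximum within one class is
3. `w0` is retained for completeness.

Δ⁺ is undefined for s < 2 (no pairs). Such regions carry an `undefined`
flag and are excluded from funnels, null ensembles and tests rather than
imputed.

Weights are computed by integer-coding each rank column and counting
shared ranks per pair, which vectorises to a dense s × s matrix; the
implementation is checked against a brute-force pair-enumeration oracle
(tolerance 1e-12) and against the independent `vegan::taxondive`
implementation in R, which agrees exactly up to vegan's fixed rescaling of
the maximum distance to 100.

## Funnel (randomization) confidence limits

The funnel at richness s is built by drawing 10,000 uniform size-s subsets
(without replacement) of the group's **master pool** and computing Δ⁺ of
each. The reported expectation is the replicate mean; the 95% limits are
the empirical 2.5% and 97.5% quantiles with linear (type-7) interpolation
and no distributional smoothing. At s = |pool| only one subset exists and
the band has width zero.

The master pool is the group's own full species list (all mammals when
analysing mammals), not a pool merged across groups: per-group confidence
limits are only meaningful against the group's own pool. Classification
uses strict inequalities — an observed Δ⁺ exactly equal to a limit counts
as `within`, so ties go to the null. Because Δ⁺ takes finitely many values
at small s, the empirical band can over-cover slightly; the coverage test
and the acceptance script therefore allow about one percentage point
beyond binomial noise around the nominal 5% escape rate.

## Richness-constrained null models

A null occurrence matrix preserves every region's species count exactly
and redraws species identities uniformly (without replacement) from the
master pool, independently across regions. Rows — species range sizes —
are deliberately unconstrained: the null hypothesis is random assembly
from the pool, not fixed range structure, and no swap/trial-swap algorithm
is used. Column-sum conservation is asserted on every draw. The default
ensemble size is k = 3 null matrices, mirroring the standard design this
package reproduces; the per-region Δ⁺ of all k matrices are pooled into
"Dataset B".

## Hypothesis tests

Observed per-region Δ⁺ values (one per defined region, "Dataset A") are
compared against the pooled null values (k × defined regions) with:

* **Mann–Whitney U** on midranks, tie-corrected normal approximation,
  no continuity correction; the reported U is min(U₁, U₂) and z is
  reported both signed and as a magnitude. A degenerate pooled sample
  (all values equal) yields z = 0, p = 1. The implementation is verified
  against direct pair counting, exhaustive rank-arrangement enumeration
  for small samples, and scipy's asymptotic test.
* **Monte-Carlo permutation test** on the absolute difference of medians
  (means optional): group labels are shuffled B = 9,999 times with group
  sizes preserved and p = (1 + #{|stat*| ≥ |stat|}) / (B + 1), so p is
  never below 1/(B+1) and the test is symmetric in the two samples.

A group's distribution is called *patterned* only when both tests reject
at α = 0.05 (two-sided); otherwise *random*. No multiple-testing
correction is applied across groups. A comparison of two single means
cannot feed a U test, so the region-level comparison above is the
implemented reading of "observed vs null"; k separate observed-vs-replicate
tests are also available (`per_replicate_tests`).

With only ~15 regions per side the U test at k = 3 has modest power;
exact U and z values for any published dataset depend on the unrecorded
null-model realizations, so only the significance classification — not
the statistic's digits — is a stable reproduction surface.

## Randomness and reproducibility

Every stochastic component takes an integer master seed and derives
independent child streams with `numpy.random.SeedSequence` keyed by
purpose (funnel richness value, region index, replicate index). Identical
config + seed reproduces byte-identical output bundles; the run manifest
records the seed and a config hash that excludes the output directory.

## Synthetic data generator

The generator emulates the shape of a regional marine-tetrapod dataset:

* **Taxonomy** — a fixed rank scaffold (default 1 class, 4 orders, 2
  families per order, 3 genera per family) with species-per-genus counts
  drawn geometric (p = 0.25, truncated at ≥ 1), giving a pool of roughly a
  hundred species whose largest family holds far more than its even share,
  the way one radiating family dominates real sea-snake lists.
* **Assemblages** — per region a richness is drawn uniformly (default
  range 2–60, clipped to the pool) and species are sampled in one of three
  modes. *random*: uniform without replacement. *clustered*: each draw is,
  with probability κ, restricted to one seed clade (a family), otherwise
  uniform; the seed clade is chosen by drawing a seed species uniformly
  among the families large enough to host the whole assemblage (falling
  back to the largest family when none is), because an undersized seed
  clade would force the uniform fallback and destroy the structure the
  mode exists to create. Exhausted clades fall back to uniform draws and
  are logged. *overdispersed*: with probability κ a greedy round-robin
  across orders, maximising the number of orders represented before any
  order contributes twice. κ = 0 reduces both structured modes to the
  random mode exactly (same RNG path, identical matrices).

Recovery behaviour, recomputed by the acceptance script at the sizes
stated there (200 seeded runs, 6 regions, richness 5–20, 1,000-replicate
funnels): at κ = 0.9 clustered regions fall below the funnel's lower limit
in well over 95% of runs while unstructured regions stay within about 95%
of the time, and the patterned-verdict frequency of the pooled test rises
monotonically with κ, reaching ~100% at κ = 0.9 with a type-I error near
1–4% at κ = 0 (the two-test conjunction makes the verdict conservative).

What the generator does **not** emulate: spatial autocorrelation between
neighbouring regions, shared range structure (a species' presences are
drawn independently per region), detection/effort bias, and any
environmental covariate structure. Passing synthetic-recovery tests
therefore shows the estimator and tests recover known compositional
structure — not that real assemblages are free of these confounds.

The frozen demonstration dataset (`paper_like_fixture`, 30 species, 6
regions, SHA-256 checksummed) is hand-built so that all three funnel
outcomes and the undefined case occur deterministically.

## Numerical choices and degenerate inputs

* Species matching is exact-string after trimming and collapsing internal
  whitespace; no synonym resolution (silent merging would corrupt
  weights).
* Latitude bands partition [−90°, 90°] with boundaries assigned poleward
  (60° → Arctic, 23° → North, −23° → South, −60° → Southern).
* An optional `extinct` flag is carried per species; extinct species are
  included in analyses by default and can be excluded per group.
* Empty samples, self-pairs, duplicate species, richness above pool size,
  and non-0/1 cells raise typed errors at the boundary rather than
  propagating NaNs; dataset validation separates fatal entries (species
  missing from the taxonomy) from warnings (never-present species,
  richness < 2 regions).

## Limitations

Presence/absence only — no abundance-weighted Δ or Δ*, and no variation
in taxonomic distinctness (Λ⁺). Rank steps treat all sister ranks as
equidistant; real evolutionary divergence within a rank varies widely.
The null model fixes column sums only, so groups whose biogeography is
driven by range-size structure can test "patterned" for reasons other
than relatedness. Regions are treated as independent samples in the U
test, which overstates the effective sample size when faunas overlap
heavily between adjacent regions.
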