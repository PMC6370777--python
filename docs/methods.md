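# Methods

This note documents the statistical models and procedures implemented in
`graftmicrobe`, the choices made where several defensible options existed,
and what the synthetic-data tests do and do not demonstrate about real
field data.

## Study design the package assumes

The analyses target amplicon surveys of grafted-plant field trials laid
out as a crossed design: `variety` (rootstock genotypes, typically eight
plus an ungrafted control, nine levels), `location` (replicate sets, i.e.
spatial blocks in the field, typically fifteen) and `line` (planting
rows). With one plant per (variety, location) cell this gives 135
samples, each profiled as integer read counts over OTUs. All analyses
treat counts per sample as compositional: only rarefied counts or
relative abundances are ever compared across samples.

## Preprocessing cascade

The fixed order is cell filter → rarefaction → (collapsing) → occurrence
filter. `run_preprocess` enforces it.

**Low-abundance cell filter.** A cell is zeroed when its count is
strictly below `cell_filter_fraction` × the sample's total
(default 0.001, i.e. 0.1%), a standard guard against index hopping and
PCR bleed-through. The threshold uses each sample's total *before any
zeroing*, in a single pass. This makes the operation exactly idempotent
and avoids order-dependent cascades that recomputed totals would create;
whether totals should be recomputed is genuinely ambiguous in common
practice, so the single-pass rule is pinned here and tested.

**Rarefaction.** Each sample is subsampled uniformly *without
replacement* to `rarefaction_depth` reads (default 500); samples with
fewer reads are discarded and reported. Sampling without replacement is
the behaviour of the standard community-ecology subsamplers and is
implemented via numpy's multivariate hypergeometric generator, whose
moments the tests verify. Each sample draws from its own random stream
derived from `(master seed, sha256(sample id))`, so removing one sample
from a table never changes another sample's subsample — a reproducibility
property plain sequential RNG use would not have.

**Collapsing.** OTUs sharing the lineage down to the requested rank are
summed. An OTU unassigned at that rank goes to a bin named
`unidentified <deepest assigned name>`, i.e. unassigned taxa are binned
per parent lineage rather than pooled into one global "unknown" (or,
optionally, dropped). With the bins kept, per-sample totals are conserved
— an invariant the tests assert. Collapsing requires the target rank to
be strictly coarser than the input rank.

**Occurrence filter.** Taxa present (count > 0) in fewer than
`occurrence_min_samples` samples (default 30, roughly two per variety
condition) are removed before per-taxon testing, at the rank being
analysed.

## Raup–Crick dissimilarity

A presence/absence β-diversity: the probability, under a null assembly
model, that two samples share more taxa than observed, with ties split
evenly,

d(a, b) = [#{S_null > S_obs} + ½·#{S_null = S_obs}] / n_sim.

Values near 0.5 mean "as shared as chance"; values near 1 mean less
shared than chance. Two variants are provided:

* **null-model** (default, `n_sim` = 999): each sample's richness is
  fixed and taxa are drawn without replacement with probability
  proportional to their occurrence frequency across samples — the
  standard occurrence-weighted null. Weighted sampling without
  replacement uses the exponential-keys method. One null community per
  sample per iteration is shared across all pairs; each pair's marginal
  distribution is exact.
* **analytic**: with an equiprobable pool the shared richness of two
  samples with richnesses n₁, n₂ over S taxa is hypergeometric, so the
  dissimilarity has a closed form, d = P(X > x) + ½·P(X = x),
  X ~ Hypergeom(S, n₁, n₂). The pool is every taxon column of the
  matrix. This variant exists mainly as the independent oracle for the
  simulated one; the tests verify agreement on equal-occurrence fixtures,
  where the weighted null reduces to the equiprobable one.

Note that two samples sharing *no* taxa get d ≥ 0.5 (the null can only
share ≥ 0), i.e. disjoint pairs are at least as dissimilar as chance —
a direct consequence of the definition, asserted by enumeration in the
tests.

## PERMANOVA

Multi-term permutational ANOVA on a distance matrix, in the sequential
(order-of-entry, "type I") form: the distance matrix is Gower-centred,
G = −½·J·D²·J, and each term's sum of squares is the increment in
tr(H·G) as the term's dummy block enters the design after the preceding
terms. Pseudo-F uses the full-model residual mean square; R² = SS/tr(G).
The implementation is checked three independent ways: against classical
sequential ANOVA on Euclidean distances of univariate data (exact
equality), against scikit-bio's one-way PERMANOVA statistic, and against
R `vegan::adonis2(..., by = "terms")` on a multivariate fixture.

Default term order is `(variety, location)` with location modelled as an
ordinary term, not a permutation stratum, so labels are permuted freely;
p = (1 + #{F* ≥ F}) / (1 + n_perm) with 10,000 permutations by default.
On the near-balanced designs this package targets, term order barely
matters, but on unbalanced data sequential SS are order-dependent — the
tests demonstrate this rather than hide it.

## Per-taxon ANOVA

For each taxon passing the occurrence filter, a two-way fixed-effects
ANOVA (no interaction) of its relative abundance on variety + location,
sequential SS with variety entered first, parametric F p-values (via
statsmodels). A taxon with constant response is reported with NaN
statistics and a `degenerate` flag rather than raising. Proportions
violate ANOVA's distributional assumptions in principle; the parametric
p-values are reported as the field conventionally does, with the
permutation-based preference test available for assumption-free claims.

## Host-genotype preference index

The package's central statistic. For taxon *i* and variety *j*:

Preference(i, j) = [N_obs(i, j) − Mean(N_rand(i, j))] / SD(N_rand(i, j))

with N_obs the mean (rarefied) read count of *i* over variety-*j*
samples and the null ensemble generated by shuffling the variety labels
across all samples (default B = 100,000 shuffles). Implementation and
conventions:

* One full label permutation per iteration, shared by every taxon. This
  preserves the cross-taxon dependence of the data; each taxon's marginal
  null is identical to what independent streams would give (tested).
* Significance is decided on the empirical upper-tail p,
  (1 + #{null mean ≥ observed}) / (1 + B), ties counted as exceedances —
  a valid, conservative convention that can never return 0. The z-score
  is descriptive only; the permutation null need not be normal.
* Bonferroni correction with m = number of variety conditions (9),
  applied per taxon. Cross-taxon multiplicity is *not* corrected — a
  deliberate property of the method (the report lists per-taxon-corrected
  hits), so a few chance hits among hundreds of taxa are expected and the
  calibration suite quantifies exactly that family-wise-per-taxon rate.
* Null SD is the population (divide-by-B) form — the moments of the
  realized permutation ensemble. Where the null SD is zero (a taxon
  constant across samples) the convention is preference = 0, p = 1.
* The default tail is upper (preference); `tail="lower"` tests avoidance.
* The permutation loop is vectorized in chunks (gather + `add.reduceat`
  over contiguous variety blocks); results are independent of chunk size
  and reproducible given the seed (both tested). 100,000 shuffles on a
  135 × 100 table takes a few seconds.

## Synthetic field-experiment generator

The generator emulates the statistical structure the analyses consume,
not the sequencing process itself:

* **Baselines**: taxon relative abundances are log-normal
  (`baseline_log_mean_sd` = 1.5, a realistic steep rank-abundance curve)
  and assigned to taxa in decreasing order, so taxon indices are
  abundance ranks — "plant an effect on t_010" is a seed-stable statement
  about a moderately abundant taxon (~1–3% of reads).
* **Effects**: variety-preference and location effects are multiplicative
  fold-changes on expected relative abundance before renormalization;
  `expected_composition` returns the exact post-renormalization target,
  which the oracle tests compare against sampled group means.
* **Noise**: per-sample composition ~ Dirichlet(overdispersion ×
  expected), counts ~ Multinomial(depth, composition). The concentration
  default 50 gives the moderate overdispersion typical of leaf amplicon
  data; → ∞ recovers plain multinomial sampling (tested via a large-
  concentration limit).
* **Depth**: log-normal (median 2,000, log-sd 0.5); with probability
  `low_depth_fraction` (default 0.07) a sample instead gets a uniform
  depth below 500, emulating failed libraries. At the 500-read cutoff
  this discards ≈ 9–10 of 135 samples on average, matching the retention
  profile of real field runs (tested over seeds).
* **Taxonomy**: taxa are assigned round-robin to ~n/3 genera within ≤ 10
  orders; a configurable fraction (default 0.1) is unassigned at genus to
  exercise the `unidentified` binning path.

What passing synthetic tests do **not** show: the generator has no
phylogenetic correlation between taxa, no spatial autocorrelation beyond
the categorical location factor, no taxon-specific amplification bias,
and independent samples — so the suites validate the *statistical
machinery* (calibration, power, exactness, invariants), not ecological
conclusions about any particular field system.

## Numerical and procedural choices

* p-value convention everywhere: (1 + exceedances) / (1 + permutations).
* Seeds: one master seed per entry point; derived streams use
  `numpy.random.SeedSequence` with stable (hash-based) keys, never
  Python's salted `hash()`.
* Count tables are validated on construction (non-negative integers,
  unique ids, no tabs in identifiers); TSV cells are never quoted; the
  on-disk orientation of count tables is auto-detected against metadata
  ids with an explicit override, preventing silent transposition.
* BIOM v1 JSON support covers the sparse and dense matrix types with
  integer counts.
* Sizes used by the validation suites — 200 null datasets and 100
  planted datasets at 999 shuffles, 50 design draws for the ANOVA
  equality check, 10,000 null draws for the Raup–Crick closed-form
  comparison — are chosen so each check's Monte-Carlo error is small
  against the tolerance it asserts while the whole suite runs in about a
  minute on one CPU.

## Known limitations

* Sequential (type-I) SS only, for both PERMANOVA and the per-taxon
  ANOVA; marginal (type-II/III) partitions are not implemented.
* Free permutation only — no restricted/stratified permutation schemes.
* No FDR alternatives to Bonferroni in the preference test beyond what a
  user can compute from the returned p matrix.
* The Raup–Crick null fixes richness and weights by occurrence frequency;
  abundance-weighted nulls are out of scope.
* `filter_low_abundance_cells` assumes the single-pass totals rule; data
  preprocessed under a recompute-totals rule will differ in edge cases.
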