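# Methods

## The proxy problem and the filtering rule

A buccal swab (BS) of a ruminant samples a convex mixture of two latent
communities: the resident oral microbiota and rumen content deposited by
regurgitation. Writing λ for the rumen share of a swab's composition, a
BS sample's expected composition is `λ · rumen + (1 − λ) · oral`; a
stomach-tube sample (R) is pure rumen (λ = 1). The analysis does not try
to estimate λ probabilistically (no source-tracking); it applies a
deterministic threshold rule on genus-level maxima, which is what makes
it reproducible across labs with nothing but a feature table.

With abundances on the percent scale after total-sum scaling (TSS):

1. **rare** if the genus stays below `rare_cutoff_pct` (default 1%) in
   *every* sample of both types. Rare taxa are set aside before the
   oral/rumen decision and never receive either label.
2. **oral-specific** if `max_BS − max_R ≥ oral_cutoff_pp` (default 1
   percentage point). The phrase "maximum abundance ≥ 1% in BS as
   compared to any R sample" admits a second reading —
   `max_BS ≥ 1% and max_BS > max_R` — which is implemented behind
   `oral_rule="bs_exceeds_any_r"`; the difference-of-maxima form is the
   default because it is the direct formalization of "≥ 1% more than
   anything seen in the rumen". Both rules are exercised by the tests.
3. **rumen-specific** otherwise.

The rule is computed on the confidence-filtered, genus-aggregated,
TSS-normalized table over *all* study days at once (a single global
partition, not per-day partitions), and OTUs inherit their genus's label.
Raising `oral_cutoff_pp` can only shrink the oral set (monotonicity, a
tested invariant).

## Preprocessing

Fixed order: drop samples with < 5000 reads (strict inequality); drop
OTUs whose within-sample relative abundance is ≤ 0.2% in every sample
(global removal — the alternative per-sample zeroing is available via
`per_sample_low_abundance`); relabel taxonomy assignments whose
classifier confidence falls below rank cut-offs (genus 0.945, family
0.865, order 0.820, class 0.785, phylum 0.750; retain iff confidence ≥
cut-off) to `unclassified <deepest retained ancestor>`, with the break
propagating to all deeper ranks; then TSS for composition analyses or
rarefaction for alpha diversity.

Rarefaction is a single multivariate-hypergeometric draw per sample (no
averaging over repeated draws), seed-controlled; samples below the depth
are dropped with a warning, never silently. The default depth is
"auto-min" (the smallest post-filter sample total of the fraction being
analysed). Alpha diversity is computed at the OTU level by default; the
aggregation rank is a parameter.

## Statistics

All core procedures are direct implementations of their definitions
(scipy supplies only rank/distribution primitives; scikit-bio and
statsmodels appear solely as independent cross-checks in the test suite):

* **Shannon** `H = −Σ p ln p` in nats. Natural log is the default because
  typical OTU-level values for developing rumen communities (≈ 3.9–4.5)
  are on that scale; the base is configurable.
* **Bray–Curtis** `Σ|x−y| / Σ(x+y)` per pair, bounded in [0, 1]; a pair of
  all-zero samples is an error rather than a silent 0/0.
* **PCoA** by Gower double-centering `B = −½ J D² J` and symmetric
  eigendecomposition; coordinates are eigenvectors scaled by √eigenvalue,
  proportion explained uses positive eigenvalues only, and negative
  eigenvalues are counted and reported, not corrected.
* **ANOSIM** ranks all `M = n(n−1)/2` dissimilarities (mean ranks on
  ties); `R = (r̄_between − r̄_within) / (M/2)`. The `M/2` divisor is
  Clarke's: it is the unique scaling for which perfectly separated groups
  give R = 1 and equidistant data give R = 0, both asserted in tests.
  The null permutes sample labels; for small n an exhaustive-enumeration
  oracle (`enumerate_anosim_p`) verifies the permutation p-value.
* **Mantel** correlates upper triangles (Pearson default — the
  conventional default of the R implementations this analysis style uses;
  Spearman available) permuting one matrix jointly over rows and columns.
* **Permutation p-values** use `(1 + b)/(1 + m)` with `b` the count of
  permuted statistics ≥ the observed one, so p is never 0 and the test is
  exact-conservative.
* **Kruskal–Wallis** with tie correction `C = 1 − Σ(t³−t)/(N³−N)`;
  **Dunn's** pairwise `z = (R̄_i − R̄_j) / √[(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/n_i + 1/n_j)]`
  with two-sided normal p-values and no continuity correction;
  **Benjamini–Hochberg** step-up adjustment across each pairwise family
  (and across taxa for tablewide scans). BH is monotone in raw-p order
  but not idempotent — re-adjusting adjusted values is a user error the
  API does not hide.
* **Matched Spearman** pools all (taxon, matched-animal) abundance pairs
  into one rank correlation by default; per-taxon-mean pooling is offered
  behind a flag because either pooling is defensible for a scatter-grid
  summary. Per-taxon Spearman requires ≥ 3 matched, non-constant pairs;
  failing taxa are reported missing and excluded from the mean.

Default permutation count is 9999 (seed-controlled); the acceptance
script uses 999 to keep the full battery fast, which resolves p down to
10⁻³ — ample for effects of the size the study design produces.

## The synthetic study generator

The generator emulates the statistical structure the analysis assumes,
not sequences: 59 animals (default), buccal swabs at days 42, 70, 98,
112, 140 of life, stomach tubing at day 140 only, lognormal sequencing
depth around 20,000 reads.

* **Genus pools.** 141 oral and 29 rumen "detectable" genera (lognormal
  shares, σ = 0.5 / 0.7) plus an 80-genus rare tail carrying 3% of each
  compartment's mass. Pools are disjoint by default so every taxon has an
  unambiguous origin; `shared_taxa_fraction` lets one study the rule's
  failure modes and defaults to 0. Genera expand into OTUs (Poisson
  counts around 8 oral / 40 rumen per genus; Dirichlet within-genus
  weights).
* **Carryover.** Per BS sample, λ ~ Beta with concentration 60 and
  day-specific means placing the *oral* fraction at 36.0, 66.2, 65.0,
  53.2 and 57.1% — the regurgitation band the proxy literature reports.
* **Age.** Each rumen OTU has an emergence day (55% active at day 42,
  linearly reaching 100% at day 140) and within-genus weights are
  tempered by an exponent relaxing from 1.35 to 1.0, so OTU-level
  richness and evenness — hence Shannon — rise strictly with age while
  genus shares stay fixed. The latent per-day profile Shannon is stored
  as ground truth.
* **Weaning.** A lognormal shock (sd = `weaning_shock`, default 1.0)
  reorganizes within-genus OTU weights between a pre- and a post-weaning
  state. The early-weaned group switches between days 42→70, the
  late-weaned between 98→112 (partially at 112), and both share the
  mature profile at day 140 — so group separation appears at days 70–112
  and vanishes at the final day. Acting on within-genus weights keeps the
  genus-level rumen signature stable across weaning, which is what lets a
  single global partition stay valid over the whole study.
* **Noise.** Overdispersion is animal-persistent: each animal draws its
  genus composition once per compartment from Dirichlet(c · shares) with
  c = 99 (intra-class correlation ≈ 0.01), and each sample adds a mild
  Dirichlet layer (c = 1000) before multinomial counting. Persistent
  animal effects are the realistic correlation structure for repeated
  measures of the same animals; making the same noise independent per
  sample would let extreme-value asymmetry (295 BS draws vs 59 R draws)
  dominate the max-based rule, which no repeated-measures design actually
  exhibits.
* **Taxonomy.** Each genus gets a private synthetic lineage; 10% of OTUs
  draw a sub-threshold genus confidence so the relabelling rule is
  exercised, splitting off `unclassified <family>` genus-level fragments
  exactly as real low-confidence assignments do.

What the generator deliberately does *not* emulate: shared oral/rumen
taxa (off by default), sequencing error, chimeras, primer bias, and
genus-level diet effects at weaning. Passing tests therefore demonstrate
that the pipeline recovers the truth *of this mixture model* under
realistic noise — not that the 1%-threshold rule is unbiased on real
data, where oral and rumen communities share taxa and weaning shifts
genus composition too.

Recovery metrics score primary named genera only: the
`unclassified <family>` fragments produced by confidence relabelling are
artifacts of the taxonomy, not additional true genera, and the rare tail
sits below the rule's 1% ceiling by construction, so it is tracked via
the `detectable` truth flag rather than counted against recall.

## Pipeline and reproducibility

`run_all` executes input (simulate or load + align) → preprocess →
partition (labels, OS/RS renormalization, oral fractions, core OTUs over
day-70…140 BS groups plus day-140 R) → statistics (rarefied Shannon for
RS and OS — the OS dataset is BS-only, as tube samples carry no oral
fraction; ANOSIM for method before/after filtering, for age, and for
weaning per day; within-group similarity; Mantel between day-140 R and
day-140 BS-RS matrices on matched animals, each renormalized separately
before Bray–Curtis; matched and per-OTU Spearman; per-genus
Kruskal–Wallis by age with tablewide BH). Every stochastic stage consumes
an independent sub-seed derived from one master seed
(`numpy.random.SeedSequence`), so runs are bit-reproducible and single
stages can be re-run in isolation; the report echoes all parameters and
flags those differing from defaults. A stage failure aborts with the
stage name and offending entity.

Problem sizes: the shipped tests run the full battery on the default
59-animal design (354 samples, ≈ 2400 OTUs) with 199 permutations, and
the acceptance script with 999; both complete in seconds on one core.

## Known limitations

* The rule's oral/rumen boundary is a max-statistic over samples, so its
  behaviour on borderline genera depends on cohort size and noise
  structure; the generator's recovery rates quantify this only under the
  model above.
* Per-sample masking vs global removal for the ≤ 0.2% OTU filter changes
  the surviving OTU set; only the global variant matches a single global
  OTU count.
* BIOM support covers the minimal dense JSON dialect, not HDF5.
* Ordination output is coordinates only; no plotting is included.
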