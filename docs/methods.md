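# Methods

## Study design emulated by the generator

The synthetic-data module reproduces the structure of a blocked
factorial deadwood-decomposition experiment: `n_blocks` spatial blocks
(default 4), each holding an open-canopy and a closed-canopy site, each
site with a pure-beech, a pure-fir and a mixed plot. Per block × canopy
× year the design yields 8 composite samples — 2 beech from the pure
plot, 2 fir from the pure plot, and 2 beech + 2 fir from the mixed plot —
so every sample is of exactly one deadwood species and mixture is a
plot-level flag only. At the defaults (4 blocks, 6 years) this gives 64
samples per year and 384 in total. The layout is deterministic; the seed
argument exists only for interface uniformity.

## Generative model for communities

Each taxon is an archetype with tree affinity `pi_tree` ∈ [0, 1]
(1 = beech-only), canopy affinity `pi_canopy` (1 = closed-only), a
Gaussian temporal occupancy window (peak `mu` in years, width `sigma`),
and a log-normal base abundance. The expected (unnormalised) abundance in
a sample is

    base × w_tree × w_canopy × exp(−(year − mu)² / (2 sigma²)),

with `w_tree = pi_tree` on beech samples and `1 − pi_tree` on fir, and
analogously for canopy with closed as reference. The Gaussian kernel was
chosen because it gives each taxon a single interpretable peak (the
target of the succession-time estimator) and width (the target of the
duration estimator); the field data motivating this package do not
prescribe a generative form.

Counts are Dirichlet-multinomial: per sample the expected proportions are
perturbed by a Dirichlet draw with concentration `proportions /
overdispersion` (structural zeros stay exactly zero via the gamma
representation), then `depth` reads are drawn multinomially, so every
column sums exactly to `depth`. `overdispersion` (default 0.01) adds
depth-independent compositional noise of roughly `sqrt(p(1−p) ×
overdispersion)` per taxon — of the order of a few percent of a
proportion's own scale, which is a modest ecological replicate-to-replicate
wobble. Taxon parameters: `specialist_fraction` of taxa (default 0.5) are
strict specialists (affinity 0 or 1, independently per factor, reflecting
that a large share of deadwood fungi are substrate-restricted), the rest
draw affinities from Beta(2, 2); `sigma` is log-uniform on [0.4, 2.5]
years, spanning single-season spikes to residents of most of the
experiment.

All randomness descends from a single master seed with one child stream
per operation (design, taxa, community, chemistry, rarefaction, each
permutation test), so stages can be re-run independently and the whole
pipeline is byte-identical under a fixed config.

### What the generator does and does not emulate

It reproduces the factorial balance, sequencing-depth closure, substrate
and microclimate affinities, temporal occupancy windows and heavy-tailed
abundance distribution of real ITS amplicon studies. It does not simulate
spatial autocorrelation among blocks, read-level artefacts (chimeras,
clustering error), taxon–taxon interactions, or year-to-year weather
effects; passing tests therefore demonstrate estimator correctness under
the stated model, not robustness to those real-data complications.

### Chemistry covariates

Noiseless trajectories are anchored to the printed study values: pH falls
linearly 5.3 → 4.0 over the experiment for both species; ergosterol rises
linearly 31 → 110 µg g⁻¹ (beech, years 1–6) and 10 → 48 µg g⁻¹ (fir,
years 1–5, then flat); nitrogen is flat at its species-specific year-1
value (0.27% beech, 0.16% fir) since no temporal trend is reported;
carbon starts at C:N × N (41.6% beech, 43.2% fir) and drifts up 2
percentage points over the run; moisture rises linearly with a +5% beech
offset (beech deadwood retains more water). Values without a printed
anchor (C slope, moisture levels, within-year noise) are the package's
own choices. `noise_sd` is a *relative* standard deviation — each value
is multiplied by `1 + noise_sd × N(0,1)` — because a single absolute sd
cannot serve pH (~5) and ergosterol (~100) at once; results are clipped
to physical bounds, and the default in the pipeline config is 0.05.

## Preparation

* **Species aggregation**: OTUs whose best database hit reaches 97%
  identity and 95% coverage merge under the hit's binomial; weaker hits
  merge under "<genus> sp."; host-plant and other non-fungal OTUs are
  discarded before merging. The pipeline aggregates before rarefying (the
  order is configurable since the convention varies between labs).
* **Rarefaction** subsamples each sample to a fixed depth (default 2,000
  reads) *without replacement* (multivariate hypergeometric). Samples
  below the depth cannot be subsampled at that depth and are dropped, and
  their ids recorded in the result's log, rather than resampled with
  replacement.
* **Hellinger transform**: square root of relative abundances; each
  sample vector then has unit Euclidean norm, making Euclidean distances
  between samples ecologically sensible.
* **Abundance-filter presets** (strict inequalities throughout): `fig2`
  keeps taxa over 0.5% in ≥ 3 samples; `fig6` additionally requires over
  1% in at least one sample (so its set is a subset of `fig2`'s); `fig5`
  works on *yearly observations* — the taxon's mean relative abundance
  over the samples of one year within one tree × canopy treatment — and
  keeps taxa over 1% in ≥ 3 years or over 2% in some year. A taxon passes
  `fig5` if any treatment satisfies the clause; a pooled-across-treatments
  variant is available by keyword since the defining convention is not
  fixed in the literature.

## Diversity

Shannon entropy in nats over positive proportions; Pielou evenness
J = H / ln S with J = 1 for a single-taxon sample; Chao1 in the
bias-corrected form S + F₁(F₁−1)/(2(F₂+1)) (defined also without
doubletons), with the classic S + F₁²/(2F₂) behind a flag. Indices are
meant for rarefied counts, where S and the singleton/doubleton counts are
comparable across samples.

## Succession statistics

Specificity uses per-sample *relative* abundances, not raw counts, so
unequal sample depths cannot bias it. Taxa absent from every sample have
undefined specificity and are reported missing, never 0 or 1. Thresholds
are inclusive: S = 0.95 is specific, S = 0.05 is alternative-specific.
Yearly profiles pool all samples of a year by default (per-treatment
profiles can be formed by subsetting the table first). Succession time is
reported as a real number in [1, n_years]; duration as whole years, via
the shortest contiguous window reaching 90% coverage with ties broken by
the earliest window. The central-interval alternative (years spanned
between the 5th and 95th percentile of the cumulative profile) is behind
`method="central"`; the contiguous-minimal form is the default because it
matches the intuition of "how long was this taxon around" for unimodal
profiles, and the two differ only for strongly multimodal profiles. Both
statistics are invariant to rescaling the profile by a positive constant.

## Permutation multivariate tests

* **PERMANOVA** uses the distance-based linear model: the squared
  distance matrix is Gower-centered, and each term's sum of squares is
  the trace of the centered matrix under the difference of projection
  ("hat") operators of nested dummy-coded model matrices. For two-way
  designs the term tests are Type II (each main effect adjusted for the
  other; the interaction adjusted for both), a clearly-documented choice
  since desktop packages vary in their scheme. On Euclidean distances of
  one-dimensional data the one-way pseudo-F reduces exactly to the
  classical ANOVA F (the McArdle–Anderson identity), which the tests
  verify to 1e-9. Permutations shuffle sample identities freely —
  block-restricted permutation is deliberately not the default, matching
  the unrestricted analysis the design emulates — and an exact mode
  enumerates all distinct label arrangements for small one-way designs.
  Note that with two groups the pseudo-F is invariant to swapping the
  group labels, so the smallest attainable exact p with n = 3 + 3 is
  2/20 = 0.1; calibration at α = 0.05 is therefore checked with Monte
  Carlo permutations at n = 5 + 5, where the measured type-I rate is
  ≈ 0.04–0.05.
* **Mantel** correlates the off-diagonal entries of two distance matrices
  (Pearson by default, Spearman by flag) and permutes rows and columns of
  the second matrix simultaneously; the test is two-sided on |r|.
* **NMDS** alternates isotonic regression of configuration distances on
  the dissimilarity order (primary/weak tie treatment: tied
  dissimilarities are ordered by the current configuration distances, not
  forced equal) with Guttman-transform updates, minimising Kruskal
  stress-1. Because normalised stress is not strictly monotone under raw
  majorisation, an iteration is accepted only if stress does not
  increase; the recorded stress history is therefore non-increasing by
  construction. One start uses the classical (metric) scaling solution,
  the rest are random; the best stress wins and is never worse than the
  metric start. Non-convergence within `max_iter` flags the result
  instead of raising.
* **envfit** regresses a variable on the two ordination axes; the fitted
  arrow is the unit coefficient vector, R² the explained fraction, and p
  comes from permuting the variable. Constant variables are reported
  missing.
* **Variation partitioning** decomposes the (column-centered) community
  matrix over two predictor blocks via redundancy-analysis R² with the
  Ezekiel adjustment 1 − (1 − R²)(n − 1)/(n − p − 1), p being the rank of
  the centered predictor block. Fractions are differences of adjusted
  R²s, so the identities a + b = adjR²(X1), b + c = adjR²(X2),
  a + b + c = adjR²(X1 ∪ X2) hold to machine precision by construction;
  negative adjusted fractions are possible and left as computed.
  Permutation p-values (pseudo-F, free permutation of community rows) are
  attached to the testable fractions: each block's total contribution,
  the joint model, and the two pure fractions. Residual-permutation
  schemes for the partial tests exist in other software; free permutation
  was chosen for simplicity and is recorded in every result.
* **Univariate helpers** delegate to scipy/statsmodels: Spearman's rho
  (mid-ranks, t approximation), Kruskal–Wallis with tie correction for
  one-factor calls, and two-way ANOVA with Type II sums of squares. A
  zero-residual design reports an infinite F rather than failing.

p-values use (b + 1)/(m + 1) with b the permutations at or above the
observed statistic, so p ≥ 1/(m + 1) and the observed statistic counts
itself; every permutation result records its seed and permutation count.
Default permutation counts mirror the emulated analysis: 9,999
(PERMANOVA), 99,999 (Mantel), 999 (envfit and varpart).

## FWD census

Per plot and diameter class, dry mass = wet mass × dry-mass fraction,
scaled by 10,000/area (2,500 for the default 2 × 2 m plot) and converted
to tonnes; the estimate averages over plots and reports per-class shares
of the total (undefined shares, e.g. with zero stock, are NaN, and a
convenience accessor rounds shares to the integer percent used in
reporting). The edge-piece field rule (collect pieces crossing the
eastern and southern borders only) is a sampling protocol, documented on
the record type but not computable. The CWD equivalence is plain
arithmetic — stock × turnover ratio (default 5) — expressing a fast-
cycling FWD stock as the coarse-deadwood stock with the same yearly
production. Volume conversions (m³ via wood density) are deliberately out
of scope.

## Numerical choices and degenerate inputs

Specificity values are clipped to [0, 1] against float round-off before
classification. Duration uses a 1e-12 relative tolerance when checking
the 90% coverage so exact-boundary profiles (e.g. a year holding exactly
90%) resolve to the shorter window. Distance matrices are validated
symmetric to 1e-12 with the diagonal forced to zero. The permutation
exceedance comparison uses a 1e-12 slack so ties at the observed
statistic count as exceeding, keeping the (b+1)/(m+1) convention
conservative. All-zero samples, empty taxa lists, single-level factors,
saturated designs and out-of-range parameters raise informative errors
naming the offender.

## Problem sizes in tests and the acceptance script

The shipped checks run on deliberately small instances — the full default
design (384 samples) with 200 taxa for parameter recovery, 1,000
six-to-ten-sample null simulations for test calibration, tens of samples
for ordination — sizes at which every oracle (exhaustive enumeration,
classical ANOVA, closed forms) is computable exactly and the whole suite
completes in well under two minutes. Full-scale permutation counts
(9,999/99,999) remain the library defaults for real analyses.

## Known limitations

* The specificity estimator inherits a small compositional bias: because
  per-sample relative abundances are renormalised by the whole community,
  a taxon's estimate converges (with depth and replication) to the
  expected-proportion specificity, which can differ from its generative
  affinity by a few hundredths when community totals differ between
  sample types. At the default study conditions the mean absolute
  deviation for abundant taxa is ~0.02, well inside the 0.05 band used by
  the recovery checks, but it does not vanish with deeper sequencing.
* NMDS stress is minimised per start by majorisation and can stall in
  local minima; more random starts are cheap insurance for small n.
* Variation partitioning assumes the linear (RDA) model on Hellinger
  coordinates; strongly unimodal gradients would call for a different
  response model.
* The guild map shipped by the pipeline is synthetic plumbing for the
  generator's genera; real analyses must supply a literature-based
  genus → guild table.
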