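# Methods

## Dissimilarity partitioning

For two communities described by presence/absence vectors over a common
species ordering, with `a` shared species and `b`, `c` unique species,
the package computes

* total Sørensen dissimilarity βsor = (b + c) / (2a + b + c),
* the turnover (Simpson) component βsim = min(b, c) / (a + min(b, c)),
* the nestedness-resultant component βnes = βsor − βsim.

The decomposition is additive by construction and all three indices are
symmetric (via the `min`).  βsim = 0 exactly when the poorer community is
a subset of the richer one, so βnes carries all dissimilarity produced by
ordered species loss; when b = c the components coincide and βnes = 0.
A pair with `a + b + c = 0` (two empty communities) has an undefined
index (0/0) and raises `EmptyPairError`; an empty-vs-nonempty pair is
well defined (βsor = 1, all nestedness) and is computed normally.
Species absent from every sample are dropped before all-pairs
computation — they cannot affect `a`, `b` or `c`.

In the experimental design, each treatment plot is compared with the
ambient (0 g N m⁻²) plot of its own block, giving (levels − 1) × blocks
comparison rows per organism group.  Species-pool accounting defines the
local pool as the union of species present in any ambient replicate and
counts, per dose level, pool species absent from exactly k of the r
replicate plots (k = 1..r; absent from all r = "species loss") and
non-pool species present in exactly k plots (present in all r =
"new species occurring").

## Rarefaction and incidence

Microbial count tables are rarefied sample-by-sample to a fixed depth by
a multivariate hypergeometric draw (subsampling reads without
replacement), the standard equal-effort normalisation before
incidence-based analysis; samples shallower than the target are dropped
with a logged warning rather than padded.  The pipeline defaults use the
conventional amplicon depths of 18,877 reads (bacteria) and 24,945
(fungi); plant quadrat data enter as incidence directly, since
point-intercept records carry no sequencing-effort artefact.  Presence is
count ≥ 1 with no minimum-abundance filter.  Incidence is computed after
rarefaction.

## Permutation tests and ordination

**PERMANOVA.** SS_total = (1/N)·Σ_{i<j} d²ᵢⱼ, SS_within =
Σ_g (1/n_g)·Σ_{i<j∈g} d²ᵢⱼ, pseudo-F = (SS_between/(g−1)) /
(SS_within/(N−g)).  The default null distribution is free permutation of
group labels with n_perm = 999; the p-value includes the observed
statistic, p = (1 + #{F* ≥ F}) / (1 + n_perm), so the smallest attainable
p is 1/(n_perm + 1).  Exact enumeration of all distinct label
assignments is available for small N, and stratified permutation (within
blocks) is exposed as an option for Latin-square-style designs; free
permutation is the default.

**PERMDISP.** Samples are embedded by PCoA of the double-centred Gower
matrix; negative eigenvalues — expected because Sørensen is semi-metric
— are retained, and each sample's squared distance to its group centroid
is computed as (distance on positive axes)² − (distance on negative
axes)², floored at 0.  Group centroids (not spatial medians) are used.
The statistic is the one-way ANOVA F on these distances; the null is
obtained by permuting the distances across groups.

**NMDS** minimises Kruskal stress-1, sqrt(Σ(d − d̂)² / Σ d²), where the
disparities d̂ are the isotonic regression of configuration distances on
the rank order of the observed dissimilarities.  Ties are treated with
the primary (weak) approach: within a block of tied dissimilarities the
pairs are ordered by current configuration distance, so ties impose no
constraint among themselves.  Optimisation is SMACOF (Guttman
transform), run from a PCoA initialisation plus 20 random restarts,
max 300 iterations, stopping when the stress decrease falls below 1e-7.
SMACOF's surrogate is raw stress, so stress-1 can in principle tick up
at convergence; the implementation detects this, keeps the previous
(better) configuration, and therefore reports a non-increasing stress
trace for every start.  The best configuration is centred and rotated to
its principal axes, leaving it canonical up to reflection.

## Gradient regressions

Each group's treatment-vs-ambient dissimilarity is regressed on
log₂(dose) by OLS using all block-level points (n = 28 for 7 non-ambient
levels × 4 blocks); a per-level-means mode and an optional block
covariate exist but are not the default, preserving n for the slope
t-test.  Ambient rows are excluded: log₂ 0 is undefined and the
dissimilarity of a plot to itself is 0 by construction.  Slopes are
compared pairwise by covariance analysis — the pooled model
y ~ x + group + x:group — reporting the interaction estimate and its
test; for balanced designs the interaction estimate equals the
difference of the separately fitted slopes exactly.

## Model selection and averaging

Predictors are per-comparison environmental deltas (treatment minus
same-block ambient) of soil total N, DIN, pH, exchangeable Al³⁺ and
Mn²⁺, z-scored (n−1 SD) so coefficients are standardized effects.
Collinearity is screened by VIF = 1/(1 − R²_j).  All 2^p subsets
(including intercept-only) are fitted by OLS and ranked by
AICc = −2·logLik + 2k + 2k(k+1)/(n − k − 1), where k counts the
intercept, the slopes and the residual variance.  Akaike weights are
normalised over the full candidate set; averaging is restricted to the
ΔAICc < 4 confidence set with renormalised weights.

Full (zero-substitution) averaging is the default — a model that omits a
predictor contributes a 0 coefficient, shrinking weakly supported
effects — with conditional (natural) averaging available by flag.
Unconditional standard errors combine within-model variance and
between-model spread, SE_j = Σ wᵢ·sqrt(var(β̂_j|i) + (β̂_ij − β̄_j)²);
95% CIs use the normal quantile 1.96, matching common model-averaging
practice.  Relative effects are |β̄_j| as a percentage of Σ|β̄| (absolute
values, since mixed-sign signed ratios are uninterpretable); they sum to
100 by construction.  "Variability explained" is reported as the global
(all-predictors) model's R² × 100, with the best-AICc model's R²
alongside, since the quantity is otherwise ambiguous between the two.

## The synthetic experiment generator

The generator emulates a blocked multi-level N-addition experiment:
8 doses (0, 1, 2, 4, 8, 16, 32, 64 g N m⁻²) × 4 blocks, one plot per
cell, on a log₂(d + 1) dose axis so the ambient level is representable.
Community assembly mixes two mechanisms:

* **Filtering (nestedness channel).**  Tolerance thresholds are
  exponential with scale x_max/filtering_strength; above its threshold a
  species is absent with probability 1 − exp(−filtering_strength·excess).
  This produces progressive, ordered loss along the gradient and exact
  subset communities in the pure-filtering limit.
* **Replacement (turnover channel).**  Niche optima are uniform on the
  dose axis; presence probability is baseline prevalence times a
  Gaussian kernel with bandwidth 1/replacement_rate, renormalised at
  every dose so expected richness is constant — losses and gains stay
  balanced, which is what makes pure replacement produce βnes ≈ 0.

One latent uniform per species is drawn for the whole experiment: the
baseline community is treated as a fixed property of the site, so the
zero-rate limit yields identical plots, and replicate variation flows
entirely through the per-plot filtering survival draws, Poisson
colonisation (arrivals of currently-absent pool species) and detection
noise (independent false absences).  Counts for present species are
1 + multinomial over log-normal(0, 1) relative abundances at a
Poisson-distributed depth; the guaranteed single read keeps the
count-derived incidence identical to the simulated presence/absence.
Environmental covariates respond linearly to log₂(d + 1) with Gaussian
noise, with semiarid-steppe baselines (total N 1.65 g kg⁻¹, pH 6.84) and
signs encoding eutrophication and acidification (total N, DIN, Al³⁺,
Mn²⁺ rise; pH falls); pH is clipped to (0, 14) and concentrations to
≥ 0.  All randomness flows from one seeded generator; outputs are
bit-reproducible.

Defaults (chosen once as a realistic desk-scale regime, not fitted to
anything): pool of 300 species, mean ambient occupancy 0.4 with
Beta-distributed per-species prevalence (concentration 4, giving a
common/rare spread), filtering_strength 0.6, replacement_rate 0.35,
colonisation 1 arrival/plot, detection noise 0.02, depth 20,000 reads.
The pipeline's three default groups differ only in regime: plants
filtering-dominated (small pool, no rarefaction), bacteria
replacement-dominated (large pool, rarefied to 18,877), fungi weakly
structured (rarefied to 24,945).

What the generator does *not* emulate: spatial dispersal, phylogenetic
structure in the pool, sequencing error or compositionality of counts,
and any feedback between groups.  Passing regime-recovery tests
therefore shows that the analysis chain correctly attributes dissimilarity
to the mechanism that generated it — not that field data will be as
clean: real ambient replicates vary more than the model's
(noise + colonisation)-driven replicates, and real environmental drivers
are confounded with dose rather than generated from it.

## Problem sizes and numerical choices

The test suite and the reproduction script run everything at desk scale,
chosen as the smallest sizes at which the checked contrasts are stable:
pools of 120–400 species, read depths of 1,500–30,000, 100–200 replicate
simulations for regime-recovery and parameter-recovery checks, 999
permutations for reported p-values (199 inside calibration loops), and
Monte-Carlo enumeration cross-checks at N = 6.  Distance-matrix
symmetry is required to 1e-10; partition additivity is asserted at
1e-12; PCoA eigenvalues within 1e-10 of the largest magnitude are
treated as zero.  Seeds are explicit everywhere; permutation tests,
NMDS and the generator accept either an integer or a Generator.

## Known limitations

* One-way PERMANOVA only; the blocked design can be honoured through
  stratified permutation but multi-factor partitions are out of scope.
* Abundance-based (Bray–Curtis) decompositions and multi-site Baselga
  indices are not implemented; the analysis is strictly pairwise and
  incidence-based.
* AICc assumes Gaussian residuals; dissimilarities are bounded in
  [0, 1], so model-averaged inferences near the bounds are approximate.
* Whether incidence should be computed before or after rarefaction is a
  judgment call; the package fixes rarefy-then-incidence.
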