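# Methods

This note documents the models implemented in `flocknet`, the design
decisions behind them, the synthetic-data generator used for validation,
and known limitations. Nothing here reports an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Data model and filters

A study is a set of per-locality binary flock × species matrices. Two
exclusion rules are standard for such compilations and are applied before
any analysis: flocks must contain ≥ 3 species (`min_flock_species`), and
species recorded in < 3 flocks pooled over all localities
(`min_species_flocks`) are treated as anecdotal participants and dropped.
Because removing a rare species can push a flock below the size threshold,
which in turn lowers other species' counts, the implementation iterates
both rules to a fixed point; the result is the largest sub-table satisfying
both constraints simultaneously, and re-applying the filters is a no-op
(tested). Whether to re-check flock sizes after species exclusion is a
genuinely open choice; the fixed point was chosen because it makes the
stated constraints actually hold in the analyzed data.

**Flocking propensity** for species s is n_s / N, where n_s counts the
flocks containing s. By default N is the total number of flocks in the
dataset (`denominator="global"`, the literal "proportion of flocks in which
it was detected"); `denominator="range"` restricts N to flocks at
localities where s was recorded, for sensitivity analysis. Propensity is
log-transformed (natural log) for modeling; no zero-handling is needed
because retained species have ≥ 3 occurrences.

## Networks and species-level metrics

Each locality matrix is projected to a weighted unipartite graph,
W = occᵀ·occ with zero diagonal, so w(i,j) counts shared flocks. Metrics
per species and locality:

* **Connectivity** (normalized degree): #{j : w(i,j) > 0} / (S−1), with S
  the species in that locality's network. Normalization makes networks of
  different sizes comparable.
* **Strength:** Σ_j w(i,j), the total frequency of interspecific
  associations.
* **Weighted closeness:** shortest-path distances on edge lengths 1/w
  (strong associations = short distances), Dijkstra via
  `scipy.sparse.csgraph`. Because locality networks can be disconnected,
  the Wasserman–Faust component scaling is used:
  closeness(i) = (R/(S−1)) · (R/Σ_{j reachable} d(i,j)), with R the number
  of reachable nodes. Isolated nodes get 0. This keeps values finite, gives
  small components low scores, and agrees with `networkx`'s
  `closeness_centrality(..., wf_improved=True)` (cross-checked in tests).
  A pooled "metanetwork" variant (`pooled_network`) is available, but the
  default treats closeness like the other metrics: computed per locality,
  then averaged.

Per-species summaries are unweighted arithmetic means over the localities
where the species occurs (no weighting by locality sample size).

## Fixed-fixed null models

The null hypothesis of random assembly holds flock sizes (row sums) and
species occurrence frequencies (column sums) fixed and treats all binary
matrices with those margins as equally likely. Sampling uses the
**curveball trade algorithm**: pick two flocks, pool the species present in
exactly one of them, and re-deal that pool at random while keeping each
flock's count — a move that preserves both margins and whose stationary
distribution is uniform on the fixed-margin set. Each replicate runs an
independent chain of `trades_factor × fill` trades (default 5×, fill =
number of 1s) starting from the observed matrix. Uniformity is verified in
the tests against exhaustive enumeration of a 4×4 fixed-margin set
(chi-square at α = 0.01, 20,000 draws) and by coverage of small enumerable
sets. A classic checkerboard-swap sampler is available behind
`method="swap"` for comparison. Matrices whose margins determine them
uniquely (no 2×2 checkerboard submatrix; detected exactly) are returned
unchanged with a warning.

z-scores standardize each observed metric against the per-locality null
ensemble: z = (obs − null mean)/null SD, with the sample SD (ddof = 1) over
`reps` replicates (default 500). Cells with zero null SD yield missing z
(a zero-variance null carries no standardization information); they are
tallied and excluded downstream. z-scores are computed per locality and
then averaged per species, mirroring the treatment of the observed metrics.

Seeds: every ensemble takes one seed; per-replicate seeds are spawned with
`numpy.random.SeedSequence`, so any replicate can be reproduced in
isolation. The trade kernel is JIT-compiled with numba when available, with
an equivalent pure-numpy fallback (different RNG stream; determinism holds
per backend).

## Trait assembly

* **Size correction.** Beak depth/width/nares/culmen, eye axial diameter,
  and maximum song frequency are regressed on body mass by phylogenetic GLS
  (λ jointly ML-estimated) and replaced by their residuals. Both sides are
  log10-transformed by default (standard morphometric/acoustic allometry;
  comparative song data typically show a log-log frequency–mass slope near
  −0.23, which the generator reproduces and the tests recover). A linear
  option is retained.
* **Beak PCA** on the correlation matrix of the four residual traits —
  correlation rather than covariance because the residuals live on
  different scales. PC1 is the composite beak-shape axis; its sign is fixed
  so large/thick beaks (positive depth/width residuals) score negative: if
  the mean PC1 loading of depth and width is positive, the axis is flipped.
* **Plumage color classes.** Twelve body-coverage proportions are grouped
  by pigmentary/structural origin: structural = blue + purple, carotenoid =
  yellow + orange + red, melanin = black + grey + brown + rufous, green =
  green + olive, white. The olive category is assigned to the green class
  (chromatically closest; the five classes then conserve the total of the
  twelve inputs exactly, which is asserted). Structural coloration is
  excluded from the default predictor set because of its typical negative
  correlation with melanin coverage; the exclusion list is configurable.
* **Missing eye data.** Eye size is commonly available only for a subset of
  species; models involving it run on complete cases, and the subset size
  is logged.
* **Collinearity.** Pairwise Pearson/Spearman correlations plus generalized
  VIFs computed from correlation-matrix determinant ratios,
  GVIF_j = det(R_{-j})/det(R) for single-column predictors (equal to the
  classical VIF; cross-checked against statsmodels), reported as
  GVIF^(1/(2·Df)) and flagged at ≥ 2.

## Phylogenetic comparative models

**VCV.** C[i,j] is the shared root-to-tip path length of tips i and j
(diagonal = tip depths), built by a single post-order traversal. Pagel's λ
multiplies off-diagonals by λ ∈ [0,1].

**Pagel's λ / PGLS.** Profile maximum likelihood: for fixed λ the GLS
coefficients and σ̂² are analytic; λ is optimized by bounded scalar search
(tolerance 1e-6), with the endpoints 0 and 1 evaluated explicitly so
boundary estimates are reported exactly. For ultrametric trees (constant
diagonal h) C(λ) = λC + (1−λ)hI shares C's eigenvectors, so one
eigendecomposition serves every λ; otherwise a Cholesky factorization is
done per evaluation. The λ = 0 likelihood-ratio test halves the χ²₁ tail
(boundary mixture). PGLS standard errors use σ̂² = RSS_GLS/(n−p) with
t-based intervals; rank-deficient designs fail with the aliased columns
named. Estimates are invariant to rescaling all branch lengths (σ² absorbs
the scale; tested). The implementation is validated against the explicit
(XᵀC⁻¹X)⁻¹XᵀC⁻¹y formula and against R `phytools::phylosig` on a shared
fixture.

**Bayesian phylogenetic linear model.** y = Xβ + u + ε with
u ~ N(0, σ²_phylo C) and ε ~ N(0, σ²_resid I); priors N(0, 10²) per
coefficient and half-Cauchy(0, 5) on both SDs. After rotating into C's
eigenbasis the errors are independent with variances σ²_phylo·w_i +
σ²_resid, so each iteration is O(np²). The sampler is a collapsed
Gibbs/Metropolis scheme: the variance components move by two 1-D Metropolis
steps — overall scale on the log scale, and the phylogenetic share
ρ = σ²_phylo/(σ²_phylo+σ²_resid) by a reflected random walk on [0,1] with
the reparametrization Jacobian — against the β-marginalized posterior, and
β is then drawn exactly from its Gaussian conditional. Marginalizing β and
bounding the ρ walk are what keep autocorrelation low when one variance
component is near zero. Proposal SDs adapt toward ~40% acceptance during
burn-in only. Defaults mirror common practice for this model class:
2 chains × 4,000 iterations, 2,000 burn-in, no thinning (2,500 retained
draws per chain, i.e. 5,000 per tree); a thinning option exists.
Split-Rhat and bulk ESS come from `arviz`; Rhat > 1.1 flags the fit with a
warning. Tree uncertainty: the model is refit on each tree of the supplied
sample (default 50) with spawned seeds and the posterior draws are
concatenated into one pooled posterior; pooling duplicates of one tree
reproduces the single-tree posterior (tested).

Predictors are standardized (mean 0, SD 1 over each model's complete
cases) before fitting so effect sizes are comparable; responses are left on
their own scales.

## Synthetic studies

The generator emulates the structure of a large Neotropical flock
compilation and is the ground truth for all validation:

* **Tree:** pure-birth with the requested number of tips, scaled to unit
  height. The simulator stops at the n-th birth, which would leave a
  zero-length terminal pair, so all tip branches are extended by the
  waiting time to the next (uncounted) event — keeping the tree ultrametric
  and its VCV well conditioned. "Posterior" tree samples are emulated by
  lognormal jitter of internal branch lengths with terminal branches reset
  to restore unit height (same topology).
* **Traits:** latents drawn from N(0, σ²(λC + (1−λ)diag C)) with
  λ_signal = 0.7 by default. Body mass is log-normal (median ≈ 20 g); beak
  dimensions, eye axial diameter and song frequency follow log-log
  allometries on mass (song slope −0.23) plus phylogenetically structured
  residuals; the 12 color proportions come from a softmax over
  BM-correlated latents with offsets making melanin-based categories
  dominant, as in real plumage data. Eye measurements are masked for a
  configurable fraction of species (default ≈ 0.50) to exercise
  complete-case handling.
* **Flocks:** per locality, a uniform species pool (default 40 of 559) and
  a normal locality effect; every flock includes each pool species
  independently with probability logistic(baseline + βᵀz + species effect +
  locality effect). The baseline is set from `mean_flock_size/pool_size`
  (default 5/40). The default effect vector is β = (+0.3 song frequency,
  −0.3 eye size) per SD, the two signals the recovery analyses target.
  A phylogenetically structured species-level intercept
  (`phylo_intercept_sd` = 0.4) adds heritable propensity variation beyond
  the measured traits, giving log-propensity a moderate phylogenetic signal
  (λ ≈ 0.3 under defaults) as observed in real flock data. Defaults mirror
  the compilation scale: 559 species, 83 localities, ~42 flocks each.
  Sub-3-species flocks and sub-3-occurrence species arise naturally, so the
  filters always have work to do.

Because the joining model is additive on the logit scale in species-level
and locality-level terms only (no flock-level or pairwise terms), the
observed matrix conditioned on its margins is uniform on the fixed-margin
set; pooled z-scores are therefore standard-normal calibrated under β = 0,
which the tests verify (|mean| < 0.1, SD within 1 ± 0.15). What the
generator does *not* emulate: detection error, observer effects,
biogeographic structure in pools, and direct species attraction/avoidance
(flock membership is conditionally independent given traits). Passing tests
therefore validate the estimators under these idealized conditions, not the
behaviour of the method under, e.g., pairwise interaction structure.

## Problem sizes used in validation

Simulation sizes were chosen so the full suite runs comfortably on a
single CPU while keeping each check statistically meaningful: the
null-model volume check runs the full 83-locality × 500-replicate stage on
compact matrices (≤ 30 flocks × ≤ 40 species); margin preservation is
asserted over > 10,000 replicates across five shapes; λ recovery uses 200
replicates of 300-tip trees per generating level (|mean bias| < 0.05);
PGLS coverage uses 200 replicates (400 intervals, band 93–97%); the
Bayesian/PGLS agreement and end-to-end recovery scenarios use 400- and
250-species studies with shortened chains (2 × 800–1,000 iterations,
3–5 trees). In the end-to-end recovery scenario eye coverage is set to 1 so
the complete-case subset equals the full species set and the check isolates
the estimator rather than the missingness pattern; the default study
configuration keeps the realistic ~50% coverage.

## Known limitations

* The Bayesian sampler is exact for this conjugate-normal model family but
  is not a general-purpose PPL; non-Gaussian responses are out of scope.
* Closeness on disconnected graphs has no unique convention; the
  Wasserman–Faust scaling is one defensible choice and is applied
  uniformly. Raw within-component closeness can be obtained from the edge
  lists if needed.
* Species–tree name matching is exact string matching after whitespace
  trimming; no taxonomic reconciliation is attempted. Species absent from a
  tree are dropped from that tree's fit with a logged count.
* Curveball chain length (5 × fill) is a mixing heuristic; it passes the
  uniformity checks used here, but extremely structured margins may need a
  larger `trades_factor`.
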