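# flocknet

Trait-linked **nuclearity** in mixed-species bird flock co-occurrence
networks: species-level network metrics, margin-preserving null models, and
phylogenetic comparative regression, with a synthetic-study generator that
makes the whole pipeline testable end to end.

## The problem

In mixed-species flocks, some species act as *nuclear* members: they flock
often, associate with many partners, and occupy central network positions
that hold the group together. Given per-locality tables of flock
composition (flock × species, 0/1), a species trait table, and one or more
dated phylogenies, `flocknet` quantifies each species' position on the
nuclearity continuum and asks which phenotypic traits predict it:

1. **Filters & propensity.** Flocks with < 3 species and species recorded
   in < 3 flocks (pooled over localities) are excluded, iterating the two
   rules to a fixed point. *Flocking propensity* is the proportion of
   flocks in which a species was detected; it is modeled on the natural-log
   scale.
2. **Networks.** Each locality's flock matrix is projected to a weighted
   species × species graph (w(i,j) = number of shared flocks). Per species:
   *connectivity* = degree/(S−1); *strength* = Σ_j w(i,j); *weighted
   closeness* on edge lengths 1/w with Wasserman–Faust component scaling
   (R/(S−1))·(R/Σd). Metrics are averaged over the localities where the
   species occurs.
3. **Null models.** Each matrix is randomized preserving *both* row sums
   (flock sizes) and column sums (species frequencies) with the curveball
   trade algorithm; observed metrics are standardized as
   z = (obs − null mean)/null SD over 500 replicates per locality.
4. **Traits.** Size correction by phylogenetic regression (PGLS residuals,
   λ estimated by ML) of log trait on log body mass; beak shape summarized
   by PC1 of the four size-corrected beak measurements (thick beaks score
   negative); 12 plumage color categories grouped into structural,
   carotenoid, melanin, green and white classes; collinearity screened with
   GVIF^(1/(2·Df)).
5. **Comparative models.** Pagel's λ (profile ML with boundary-aware LRT),
   PGLS, and a Bayesian phylogenetic linear model
   y = Xβ + u + ε, u ~ N(0, σ²_phylo C), fit by a collapsed
   Gibbs/Metropolis sampler and pooled over a sample of trees, with Rhat
   and effective-sample-size diagnostics.

## Worked example

```python
import flocknet as fn

cfg = fn.SimulationConfig(seed=11, n_species=400, n_localities=40,
                          flocks_per_locality=40, pool_size=40,
                          eye_coverage=1.0, n_trees=5)
study = fn.simulate_study(cfg)                      # tree, traits, flocks
mats = [fn.filter_flocks(m) for m in study.flock_matrices]
mats, kept = fn.filter_species(mats)
prop = fn.flocking_propensity(mats)
pred = fn.build_predictor_table(study.traits, study.tree)

lam = fn.pagel_lambda_ml(prop["log_propensity"], study.tree)
print(f"lambda = {lam.lam:.3f} (p = {lam.p_value:.2g})")

cols = ["white", "green", "carotenoid", "melanin",
        "beak_pc1", "res_eye_size", "res_max_freq"]
fits = fn.fit_all_models({"log_propensity": prop["log_propensity"]},
                         pred[cols], study.trees, seed=3,
                         n_chains=2, n_iter=1000, burn=500)
print(fits[["parameter", "mean", "lower95", "upper95"]].round(3).to_string())
```

Output (the generator's true effects are +0.3 SD for residual song
frequency and −0.3 SD for residual eye size on the joining log-odds; other
traits have no effect):

```
lambda = 0.333 (p = 5.1e-15)
      parameter   mean  lower95  upper95
0     Intercept -4.449   -4.720   -4.167
1         white  0.034   -0.215    0.289
2         green -0.068   -0.292    0.160
3    carotenoid -0.020   -0.219    0.177
4       melanin -0.009   -0.354    0.342
5      beak_pc1 -0.003   -0.078    0.072
6  res_eye_size -0.216   -0.292   -0.136
7  res_max_freq  0.231    0.144    0.318
8  sigma2_phylo  0.192    0.100    0.325
9  sigma2_resid  0.266    0.201    0.332
```

The pooled 95% credible intervals exclude zero with the correct signs for
the two active predictors and cover zero for the five null predictors;
log-propensity shows the moderate phylogenetic signal the generator builds
in. (Coefficients are per SD of the *measured* predictor, which is a noisy
proxy of the generative latent, so their magnitudes are attenuated relative
to the generating ±0.3.)

The same stages are available from the shell:

```bash
flocknet simulate --seed 11 --out-dir study/
flocknet propensity --input-dir study/flocks --out propensity.csv
flocknet metrics   --input-dir study/flocks --out metrics.csv
flocknet nulls     --input-dir study/flocks --reps 500 --seed 42 --out z.csv
flocknet traits    --traits study/traits.csv --tree study/trees.nwk --out predictors.csv
flocknet fit       --metrics metrics.csv --propensity propensity.csv \
                   --predictors predictors.csv --trees study/trees.nwk --out fits.csv
flocknet run       --config study.yaml --out-dir results/
```

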