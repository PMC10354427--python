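# Methods

This note records the modelling assumptions, default parameters, numerical
choices and limitations of `droughtstab`. It is written for users who want to
know *why* the pipeline behaves as it does, not just what it computes.

## Trajectory model

The vegetation-index trajectory of genotype *i* is modelled as
y_it = b_t + Σ_k φ_k(t) u_ik + e_it with one fixed effect per measurement
date, normalized Legendre polynomials φ_k(x) = √((2k+1)/2)·P_k(x) on the
min–max standardized time axis x = −1 + 2(t − t_min)/(t_max − t_min), i.i.d.
genotype coefficient vectors u_i ~ MVN(0, Q), and homoscedastic residuals.
Choices worth calling out:

- **Identity (not kinship) covariance across genotypes.** The coefficients
  are i.i.d. across genotypes by design; relatedness enters the pipeline only
  later, in the genomic models. This keeps the trajectory stage usable when no
  marker data exist, and it is the model whose AIC bookkeeping the parameter
  count below reflects.
- **Normalization of the basis** puts Q on a comparable scale across orders,
  so AIC comparisons across nr are not confounded by basis scaling.
- **Parameter count** p = (T−1) + (nr+1)(nr+2)/2 + 1: T−1 free date contrasts,
  the half-vectorization of Q, and σ²e. With T = 7 this gives p = 8, 10, 13
  for nr = 0, 1, 2.
- **REML criterion**: −2ℓ = log|V| + log|X'V⁻¹X| + y'Py + (n−T)·log 2π,
  decomposed over per-genotype blocks grouped by missingness pattern (records
  with missing VI are dropped, not imputed). Balanced data therefore costs one
  T×T factorization per criterion evaluation regardless of panel size.
- **Optimization** is over the Cholesky factor of Q (log-diagonal) and
  log σ²e with L-BFGS-B from three starts that split the phenotypic variance
  1:1, 1:2 and 2:1 between genetic and residual parts; convergence tolerance
  1e-8 on the criterion, 500 iterations. The Cholesky parameterization keeps
  Q positive semidefinite by construction; roundoff negatives are clipped at 0.
- **Order selection** minimizes AIC; ties break toward the smaller order.

A caution from the degenerate case: when data are generated with Q = 0 the
fitted Q̂ is small but strictly positive (a boundary estimate under noise), so
the fitted criterion sits slightly above the closed-form iid value — tests
assert the nesting inequality plus proximity rather than exact equality.

## Stability index

Fresh weight is min–max scaled to [0, 1] within each treatment-year
combination before CV_i = σ_i/μ_i × 100 is computed with the sample (n−1)
standard deviation over combinations. Per-environment scaling is essential —
raw CV would be dominated by the environments with large means — but note its
strong side effect: *any* environment main effect is removed, so only
genotype main effects and genotype×environment interaction survive into the
CV. Genotypes whose normalized mean falls below 1e-6 get a missing CV (the
ratio is undefined near zero) rather than an arbitrary large value, and are
thereby excluded from prediction.

## Genomic models

**Marker pipeline** (order fixed): heterozygous calls are treated as errors
in an inbred panel — the default policy drops the whole marker, a `mask`
policy instead sets the call missing; markers with missing fraction > 0.95
are dropped; MAF < 0.025 dropped; missing calls imputed to the marker mean;
MAF < 0.05 dropped again; windowed LD pruning (same chromosome, < 25 kb,
dosage r² ≥ 0.8) greedily keeps the left-most marker. MAF bounds are strict
(< drops, = keeps). Filtering is idempotent: the output carries an `imputed`
flag so a second pass does not reinterpret an imputed mean dosage of exactly
1.0 as a heterozygous call. The relationship matrix is VanRaden method 1,
G = WW'/(2Σp̂(1−p̂)) with W the 2p̂-centred dosages; a genotype sitting exactly
at the allele-frequency centroid legitimately has a zero diagonal entry, so
validation requires the diagonal to be non-negative, not strictly positive.

**GBLUP** is fitted by spectral REML: after eigendecomposition of the
observed-genotype block of G, the criterion is profiled down to the single
ratio λ = σ²e/σ²g, located by a 41-point scan of log λ ∈ [−10, 10] followed by
bounded refinement (tolerance 1e-8). A ratio pinned at the upper bound is
reported as σ²g = 0, h² = 0. Genetic values for unphenotyped genotypes come
from the cross-covariance block, u = G[:,obs](G_obs + λI)⁻¹(y − μ).

**Multi-trait model.** Gibbs sampler over (U, missing cells, μ, Σ, R):

1. *Genetic values.* In the eigenbasis of G the N×(M+1) conditional of U
   factorizes into independent rows, and the generalized eigendecomposition
   W'ΣW = Λ, W'RW = I diagonalizes each row, so the whole update is three
   matrix products plus one (M+1)×(M+1) decomposition per sweep — no
   per-genotype loops. Eigenvalues of G are floored at 1e-8 (the Σ update
   needs G⁻¹) and eigenvalues of Σ relative to R at 1e-12.
2. *Missing phenotypes* are drawn from their conditional normal given the
   genotype's observed traits, grouped by missingness pattern. This is what
   implements "test genotypes have trajectories but no CV" and the partial
   secondary-trait designs.
3. *Trait means* have a flat prior: μ | rest ~ MVN(mean residual, R/N).
4. *Σ and R* have inverse-Wishart full conditionals with weakly-informative
   priors: ν₀ = (M+1) + 2 and scale = diag(half the phenotypic variances), so
   the prior mean sits at half the phenotypic variance with the lightest
   proper weight. Library-default chain: 12 000 sweeps, 2 000 burn-in, thin 5.
   The evaluation loops use much shorter chains (below); posterior *means* of
   this near-conjugate model stabilize quickly, and effective sample sizes of
   the variance components are reported in `MTMFit.chain` so users can check.
   Freezing Σ and R (`fix_sigma`/`fix_r`) turns the sampler into a conjugate
   draw around the GLS/BLUP solution, which the tests exploit as an oracle.

## Synthetic study design

Defaults emulate a 178-accession soybean drought trial: 2 000 independent
Hardy–Weinberg markers with allele frequencies uniform on (0.05, 0.5) — LD is
deliberately not simulated, so a few thousand markers already give a
well-conditioned G; 9 treatment-year environments; 7 NDVI dates in DAS 35–65.
Trajectory coefficients (u0, u1) and a drought-sensitivity latent s are drawn
jointly from MVN(0, K ⊗ G) with K assembled from Q (default intercept
variance 0.01, slope variance 0.004, covariance 0.003), unit sensitivity
variance, and cov(u1, s) = rg·√(q11) so that corr(u1, s) equals the
configured `rg_coeff_stability`. NDVI residual sd is √0.005 ≈ 0.07, typical
of plot-median UAV data.

Fresh weight is w_ie = env_mean_e + m_i + s_i·δ_e + ε_ie (then truncated at
0): genotype main effect m ~ MVN(0, 64·G) grams, environment means declining
from 320 g to 130 g, and environment deviations δ_e equally spaced on
[−45, 0] g. The deviation grid is **skewed toward drought, not symmetric
about zero, on purpose**: per-environment min–max normalization removes all
environment main effects, and with a symmetric grid the surviving interaction
makes the CV an even function of s — the coefficient–stability correlation
would be structurally zero no matter what rg is configured. A stress-heavy
grid (all environments at or below the well-watered reference, as in a
drought trial where most combinations are stressed) restores a linear channel
from s to the CV. Even so the mapping s → CV is attenuated (the m channel and
a residual |s| component remain), so at rg = −0.4 the trait-level genetic
correlation realizes around −0.3; recovery tests score the seed average
against the configured value with that attenuation in mind. Residual variance
is scaled per environment so the realized heritability matches `env_h2`
(default 0.4, within the 0.18–0.64 range typical of fresh weight); the CV
index then emerges with genomic heritability around 0.3–0.4.

What the generator does **not** emulate: linkage disequilibrium and
population structure, spatial field trends, genotype×year trajectory shape
changes beyond an exchangeable cross-year coefficient correlation, non-normal
residuals, and measurement dropout patterns. Passing tests therefore show the
estimators recover the generating process, not that field data satisfy it.

## Evaluation designs

Fold partitions are drawn per replicate from a seed-derived RNG and shared
across models, so model comparisons are paired; the replicate accuracy is the
Pearson correlation of pooled fold predictions. Case 2 masks the secondary
traits of the non-selected training genotypes (test genotypes keep theirs —
trajectories are cheap, CV is what is expensive) and redraws the subset
`n_subset_draws` times per replicate, giving replicates × draws correlations;
at proportion 1.0 it reduces exactly to Case 1 because chain seeds depend on
(seed, replicate, fold) only. Case 3 fits one joint MTM in which training
genotypes carry CV plus train-year secondary traits and test genotypes carry
only test-year secondary traits; the raw-trajectory variant is restricted to
dates present in both years, while the coefficient variant uses each year's
full trajectory through its own RRM fit — that asymmetry is the point of the
comparison.

Problem sizes: the acceptance script and the directional tests run the full
178-genotype panel with 5-fold cross-validation, 2 replicates and 1 200-sweep
chains (400 burn-in, thin 2); parameter-recovery checks use n = 400 panels
and 5 000-sweep chains. These sizes were chosen so a complete run stays
comfortable on a single CPU while leaving the comparisons well outside
Monte-Carlo noise; all defaults scale up through `CVScheme` and `GibbsConfig`.

## Known limitations

- The RRM assumes homoscedastic residuals across dates; heteroscedastic or
  autocorrelated within-genotype noise is not modelled.
- Gibbs output is summarized by posterior means only; credible intervals are
  not exposed (the raw draws are not stored).
- The GBLUP profile search brackets log λ in [−10, 10]; heritabilities within
  ~5e-5 of 0 or 1 are reported at the boundary.
- LD pruning is O(markers × window occupancy) with a dense greedy scan —
  adequate for panels in the 10⁵-marker range, not for whole-genome
  sequence data.
- `select_order` requires at least nr+2 distinct dates, so order 2 cannot be
  assessed on a 4-date year by design.
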