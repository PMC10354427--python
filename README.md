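# droughtstab

Genomic prediction of drought stability in a crop diversity panel from
longitudinal vegetation-index trajectories.

Breeders screening for drought tolerance face two measurement problems: the
stability of a genotype's yield across water regimes is expensive to observe
(it needs multi-environment, multi-year trials), while canopy reflectance is
cheap to observe repeatedly from a UAV. `droughtstab` implements a pipeline
that connects the two. Per-genotype NDVI/NDRE trajectories through an
irrigation-change experiment are condensed into a handful of genetic
regression coefficients with a random regression model; those coefficients
then serve as secondary traits in a multi-trait genomic model that predicts a
coefficient-of-variation stability index for untested genotypes.

## The models

**Trajectory model (random regression, RRM).** For the vegetation index of
genotype *i* at measurement date *t*,

    y_it = b_t + Σ_{k=0..nr} φ_k(t) u_ik + e_it

where *b_t* is a fixed date effect, φ_k is the normalized Legendre polynomial
of degree *k* evaluated at min–max standardized time in [−1, 1], the
coefficient vectors u_i ~ MVN(0, **Q**) are i.i.d. across genotypes and
e_it ~ N(0, σ²e). **Q** and σ²e are estimated by REML; the polynomial order nr
is chosen by AIC = −2·loglik + 2p with p = (T−1) + (nr+1)(nr+2)/2 + 1. The
coefficient BLUPs are exported as traits L0 (trajectory level), L1 (slope), …

**Stability index.** Fresh weight over E treatment-year combinations is
min–max scaled to [0, 1] within each combination, then per genotype

    CV_i = σ_i / μ_i × 100 ,

the coefficient of variation across combinations; low CV = stable.

**Genomic models.** Marker dosages are filtered (het calls, missingness, MAF,
windowed r² pruning) and turned into a VanRaden relationship matrix **G**.
Single-trait GBLUP, y = μ + u + e with u ~ MVN(0, **G**σ²g), is fitted by
spectral REML and gives genomic heritability h² = σ²g/(σ²g+σ²e). The
multi-trait model (MTM) stacks CV with M secondary traits,

    y_im = μ_m + u_im + e_im ,  u ~ MVN(0, Σ ⊗ G),  e ~ MVN(0, R ⊗ I),

and is fitted by Gibbs sampling with inverse-Wishart full conditionals and
data augmentation for missing cells — which is what lets test genotypes carry
trajectory data while their CV is masked. Genetic correlations come from the
posterior mean of Σ.

**Evaluation.** Three cross-validation designs mirror practical use:
within-environment k-fold CV (Case 1), training sets where only a fraction of
genotypes have secondary traits (Case 2), and cross-year prediction within a
treatment (Case 3). Accuracy is the Pearson correlation between observed and
predicted CV; the benefit of coefficients over raw per-date values is
POV(%) = (PA_RRM − PA_All)/PA_All × 100.

Because the pipeline is validated on synthetic data, the package ships a
first-class generator (`droughtstab.synthetic_data`) that simulates the whole
study — Hardy–Weinberg markers, kinship-structured trajectory coefficients and
a drought-sensitivity latent with a controllable genetic correlation, and
Finlay–Wilkinson-style fresh weights with per-environment heritability — so
every stage can be scored against known truth.

## Worked example

```python
import pandas as pd
from droughtstab import (SyntheticConfig, simulate_study, select_order, fit_gblup,
                         fit_mtm, genetic_correlation, minmax_normalize, compute_cv,
                         CVScheme, run_case1)
from droughtstab.prediction import GibbsConfig

study = simulate_study(SyntheticConfig(seed=7, rg_coeff_stability=-0.4))

best = select_order(study.vi_series, [0, 1, 2])
cv = compute_cv(minmax_normalize(study.weights)).cv
mtm = fit_mtm(pd.concat([cv.rename("CV"), best.U], axis=1), study.kinship,
              gibbs=GibbsConfig(n_iter=5000, burn_in=1500, thin=2, seed=1))
```

prints (via the obvious f-strings):

```
selected order: 1  (AIC -2431.3)
Q = [[0.008, 0.0025], [0.0025, 0.0042]]  resid sd = 0.0695
CV: mean 33.5%  h2 = 0.59
rg(CV, L0) = -0.24   rg(CV, L1) = -0.39
case1 GBLUP_only: mean r = 0.137 (SE 0.067)
case1 MT_RRM: mean r = 0.321 (SE 0.041)
```

Reading: the AIC picks the linear (nr = 1) trajectory model; the estimated
coefficient covariance is close to the generating values (intercept sd 0.1,
slope sd 0.063, residual sd 0.071); both coefficients are negatively
genetically correlated with the stability CV (stable genotypes keep greener,
flatter NDVI trajectories); and using the coefficients as secondary traits
roughly doubles the cross-validated prediction accuracy over plain GBLUP in
this replicate.

The same steps are available from the shell:

```
droughtstab simulate --config config.yaml --out study/
droughtstab grm --geno study/genotypes.csv --out grm.csv
droughtstab fit-rrm --series study/vi_series.csv --orders 0,1,2 --out rrm
droughtstab stability --pheno study/weights.csv --out cv.csv
droughtstab evaluate --case 1 --study study/ --model mtrrm --seed 1 --out eval
```

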