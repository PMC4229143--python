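# Methods

This note documents the statistical models, the numerical choices, and the
limits of what the synthetic-data tests demonstrate.

## Trial model and BLUPs

Plot-level observations from a clonally replicated randomized complete
block design are modeled as

    y = μ + year + block(year) [+ field] + genotype + genotype×year + ε,

with every non-intercept term random and independent:
u_i ~ N(0, σ²_i I). The `field` term enters only when the data contain
more than one field (a single level is confounded with the intercept).
Population is deliberately **not** a term in this model: population-level
genetic structure is removed later by regressing the trait on SNP
principal components, and fitting both would correct structure twice. A
`include_population=True` switch restores it for users who prefer the
alternative reading.

Variance components are estimated by REML on Henderson's mixed-model
equations. Each iteration factorizes the (p+q)×(p+q) coefficient matrix
(q = total random-effect levels; ≈ 2,700 for a 660-genotype, 3-year
panel), which yields the restricted log-likelihood, the BLUPs, the EM
update, and the average-information (AI) matrix in one pass. The
optimizer takes 3 EM warm-up steps, then AI steps projected onto the
feasible region with step-halving whenever the restricted likelihood
would decrease, falling back to the (monotone) EM update. Convergence:
relative change in restricted log-likelihood < 1e-8 or relative parameter
change < 1e-7, capped at 200 iterations. Components are kept ≥ a floor of
1e-8·var(y); estimates within 10× of the floor are reported with a
boundary warning. On a crossed-layout test the estimates agree with
lme4's REML to ~5 decimal places.

The asymptotic covariance of the variance components is the inverse AI
matrix at the optimum, symmetrized and eigenvalue-clipped to positive
semidefinite (boundary estimates can tip a tiny eigenvalue negative).

## Outlier screening

Before the BLUP model, each trait is screened with a mixed model using
year, block(year), field (when present) and **population** as random
effects — the coarse screening model operates at the population level
precisely because genotype effects would absorb single-plant errors. For
each record the conditional residual is internally studentized with the
mixed-model leverage h_ii (diagonal of [X Z] C⁻¹ [X Z]'), then converted
to the deleted (external) form t_i = r_i·√((ν−1)/(ν−r_i²)) with
ν = n − tr(H) effective residual degrees of freedom. Records with
|t_i| > 4 (configurable; no threshold is standard) are removed from all
downstream fitting. Under the null the flag rate is ≪ 1%.

## Repeatability

Clone-mean repeatability follows the standard plant-breeding convention

    H = σ²_g / (σ²_g + σ²_gy/y + σ²_e/(y·r)),

the genetic share of the variance of a genotype mean over y years and r
replicates, an upper bound on broad-sense heritability. `y` is the number
of observed years and `r` the modal replicate count per genotype-year
cell, so mild unbalance is tolerated. The standard error is first-order
delta method: SE = √(g'Cg) with g the analytic gradient of H in
(σ²_g, σ²_gy, σ²_e) and C the AI-based covariance.

## Growing degree days

Accumulation starts the day after the first five consecutive days whose
mean temperature strictly exceeds 32 °F (scanned from the start of the
series, i.e. January 1 for calendar-year series). Daily GDD is
max(0, (Adj.Min + Adj.Max)/2 − 32) with Adj.Min = max(t_min, 32) °F and
Adj.Max = min(t_max, 86) °F; the base of 32 °F matches the onset rule.
Cumulative GDD sums from onset through the event date inclusive.

## Box-Cox

λ is chosen on the grid [−2, 2] in steps of 0.01 by maximizing the
profile log-likelihood (scipy's `boxcox_llf`); λ = 0 means log. Non-positive
BLUPs are shifted by (1 − min) when the shift option is enabled; the grid
and shift are recorded in the output metadata.

## Prediction models

**RR-BLUP.** y = 1μ + Zu + ε with u ~ N(0, σ²_u I) over all markers. The
ratio δ = σ²_e/σ²_u is profiled on the spectrum of the marker kernel ZZ'
rotated into an orthonormal basis of the intercept's complement (a
Helmert basis — exact for any kernel rank), and optimized in one
dimension by bounded scalar minimization on log δ over e^±12. Effects are
the BLUPs Z'(ZZ' + δI)⁻¹(y − μ̂) with μ̂ from GLS. Negative kernel
eigenvalues (numerical) are floored at zero with a warning.

**LASSO / elastic net.** The objective
(1/2n)‖y − μ1 − Zb‖² + λ[α‖b‖₁ + (1−α)/2‖b‖²] is minimized by cyclic
coordinate descent (scikit-learn's solver, tol 1e-8) on markers
standardized to unit variance; effects are returned on the dosage scale,
zero-variance markers get zero effect with a warning. α = 1 is LASSO;
the elastic net default α = 0.5 weights the two penalties equally. The
1/(2n) loss scaling keeps λ comparable across fold sizes.

**Penalty selection.** A 100-point log-spaced path from λ_max (smallest
all-zero-coefficient penalty; for α < 10⁻³ the α in λ_max is floored at
10⁻³ since ridge has no finite λ_max) down to λ_max·10⁻³; the λ
minimizing mean squared error over 5 random inner folds of the training
set is selected. Inner folds are population-agnostic: grouping matters
for the outer evaluation split, not for tuning. The selection never sees
held-out phenotypes.

## Structure correction and cross-validation

PCs are computed from the **full** imputed marker set (before MAF
filtering), on centered, unscaled dosages — the common GBS convention; a
`scale=True` switch enables unit-variance scaling since the choice is a
convention, not a derivation. Each trait (Box-Cox BLUPs by default) is
residualized by OLS on the first two PCs, and the residuals are the GS
response.

Folds are built over whole source populations: populations are shuffled
by the run seed and greedily assigned to the smallest fold. This keeps
clones of one population together — random splits would let the model
memorize family means and inflate accuracy. The same fold plan is used
for all three models so they are compared on identical partitions. Every
fold asserts that training and prediction populations are disjoint.
Per-fold Pearson correlations are averaged; the spread column is the SD
of the fold correlations (an SD/√k variant is available); accuracy is
mean_r/√H, never clipped, so negative values survive. Constant
predictions in a fold record r = 0 with a warning.

MAF filtering (≥ 0.05) is applied once on the phenotyped sample subset,
not per training fold — matching how the allele frequencies were used in
the study design this pipeline follows; a fold-wise option exists for
leakage-sensitive users.

## Synthetic panel

Two-level Balding–Nichols structure: ancestral frequencies uniform on
[MAF floor, 1−floor]; cluster frequencies Beta-distributed with
differentiation F_st (default 0.2, three clusters); population
frequencies around their cluster with F_st/5. Dosages are
Binomial(2, p): diploidized regardless of nominal ploidy, because that
is how diversity-panel GBS dosages are consumed downstream. Clones are
distinct genotypes within a population (the panel's "clones" are
distinct plants, each clonally replicated across blocks); missing calls
are MAR at a configurable rate, never blanking a whole marker.

Traits are additive: a random QTL subset (default 200) gets N(0,1)
effects on centered dosages, rescaled so the genetic variance is 1. Year
(SD 0.5), block(year) (SD 0.25) and genotype×year (SD 0.5) effects are
Gaussian; the residual SD is solved so the clone-mean repeatability
equals the target (default 0.85, within the 0.75–0.93 range typical of
morphological traits in such panels; infeasible targets raise with the
feasible bound). Default panel dimensions mirror the emulated design: 66
populations × 10 clones, 3 clusters, ~12,000 markers, 3 years × 2
replicates. One master seed drives everything through spawned
sub-streams, so a run is bit-reproducible.

What the generator does **not** emulate: linkage and LD decay (markers
are exchangeable given population frequencies), sequence-level error,
octoploid dosage genetics, spatial field trends, and assay drift in
laboratory traits. Passing tests therefore demonstrate correctness of
the estimators and the leakage-free evaluation under the stated
generative model — not that real GBS data meet those assumptions.

## Problem sizes in tests and the acceptance run

Simulation-heavy checks run at deliberately modest sizes chosen as the
smallest designs where the properties under test are statistically
crisp: REML recovery at 300 genotypes × 3 years × 2 replicates (20
seeds); accuracy-vs-heritability monotonicity at 50 populations × 6
clones, 800 markers, 150 QTL (6 seeds, 3-fold inner CV, 50-point penalty
path); the acceptance script at 50 populations × 8 clones, 2,000 markers,
five traits (3-fold inner CV, 50-point path). The
defaults of the generator itself stay at the full panel dimensions.

## Known limitations

- The REML engine targets independent variance components with indicator
  designs; correlated random effects (pedigree/kinship covariance) are
  out of scope.
- RR-BLUP accuracy on held-out populations is bounded by ~√(n/(n+Mₑ))
  with Mₑ the effective marker dimension; with thousands of exchangeable
  markers even a noiseless trait cannot reach r ≈ 1, and sparse traits
  favor LASSO — visible in the worked example.
- The deleted-residual screen uses the plug-in variance components (the
  model is not refitted per left-out record), the standard large-n
  approximation.
- Published-panel checks in the test suite require the original study's
  packaged data, which are not redistributed here; without them those
  tests report the missing input.
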