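# Methods

`sgeblup` implements single-step genomic evaluation for growth traits that
are shaped by social (indirect) genetic effects, the situation of pigs grown
in pens where each animal's average daily gain (ADG, g/d) depends on its own
direct genetic effect and on the social effects of its pen mates.

## The model

For the record of animal *i* in pen *P*:

```
y = X b + Z_D a_D + Z_S a_S + W l + V g + e
```

* `b` — fixed effects: batch (a year-month-week contemporary-group class),
  sex, pen-size class, and age at target weight as a covariate.  Class
  effects use reference (first-level-dropped) coding with an intercept.
* `a_D`, `a_S` — direct and social additive genetic effects with joint prior
  `(a_D, a_S) ~ N(0, C ⊗ K)`, `C = [[σ²_aD, σ_aDaS], [σ_aDaS, σ²_aS]]`,
  and `K` the relationship matrix (below).  The classic variant drops `a_S`
  and keeps a univariate prior.
* `l ~ N(0, I σ²_l)` birth-litter effects, `g ~ N(0, I σ²_g)` non-genetic pen
  effects, `e ~ N(0, I σ²_e)` residuals.
* Each `Z_S` row carries the dilution covariate `d_g = √((n̄−1)/(n_g−1))` on
  the `n_g − 1` pen mates of the record's animal, so heritable social
  variance is comparable across pen sizes; `n̄` is the mean pen size of the
  phenotyped records after group-size filtering, `d_g = 0` for a pen of one,
  and `d_g = 1` when dilution is disabled.

Derived parameters at group size *n* (we use *n* = n̄, the same mean pen size
as the dilution covariate, since "average group size" admits several
readings): total breeding value `TBV_i = a_D,i + (n−1) a_S,i`, total
heritable variance `σ²_TBV = σ²_aD + 2(n−1)σ_aDaS + (n−1)²σ²_aS`, phenotypic
variance `σ²_P = σ²_aD + (n−1)σ²_aS + σ²_g + σ²_l + σ²_e`, total
heritability `T² = σ²_TBV/σ²_P` (which may exceed 1 for large pens — a
documented property of this parameter, not an error), and the direct–social
correlation `r = σ_aDaS/√(σ²_aD σ²_aS)`.

## Relationship matrices

* **A** — numerator relationship matrix.  Inbreeding coefficients come from
  the Meuwissen–Luo algorithm (exact, O(n·depth²)); `A⁻¹` from Henderson's
  rules with inbreeding, using Mendelian-sampling variances
  `d_i = 0.5 − 0.25(F_s + F_d)` (0.75 − 0.25F with one known parent, 1 with
  none).  `log|A| = Σ log d_i` falls out of the same decomposition.  Unknown
  parents are unrelated non-inbred founders; no unknown-parent groups.
* **A22** — pedigree relationships of the genotyped animals, computed by the
  tabular method on the ancestor closure of the genotyped set only.
* **G** — VanRaden method 1 with observed post-QC allele frequencies:
  `G = ZZ′ / (2Σp(1−p))`, `Z` the dosage matrix centered at `2p`.  Missing
  dosages are mean-imputed to `2p` after QC.  Which frequency source the
  original analyses used is not documented; observed frequencies are the
  conventional ssGBLUP default.
* **H⁻¹** — `A⁻¹` plus `τ(0.95G + 0.05A22)⁻¹ − ω A22⁻¹` on the genotyped
  block.  τ is fixed at 1 and ω gridded over (0, 1]; ω can be read as the
  polygenic share the markers leave unexplained.  The 0.95/0.05 blend keeps
  the genomic block invertible.  `log|H⁻¹|` is evaluated densely on the
  genotyped-block-augmented matrix (desk scale keeps this cheap).

Genotype QC applies, in order: animal call rate < 0.90 dropped, then
non-autosomal markers (when chromosome metadata is present), monomorphic
markers, marker call rate < 0.90, MAF < 0.01, and a Hardy–Weinberg
chi-square (1 df) test at p < 1e−6.  Every threshold is a configuration
knob; these defaults are the conventional SNP-chip values.

## REML

Variance components are estimated by average-information (AI) REML on the
mixed-model equations (MME).  Per iteration the dense Cholesky factor of the
coefficient matrix `M` supplies the REML log-likelihood

```
logL = −0.5 [ (n−p)·log 2π + log|R| + log|G| + log|M| + y′Py ]
```

(the `(n−p) log 2π` constant is included; it cancels in every ΔAIC), the
inverse blocks give the gradient traces through the identity
`Z′PZ = G⁻¹ − G⁻¹ C_uu G⁻¹`, and the AI matrix needs only MME re-solves with
working vectors `V_i Py`.  Updates are Newton steps `AI⁻¹·grad` with:

* an active set — scalar variances pinned at the floor (1e−10 × Var(y)) with
  an outward gradient are excluded from the step;
* projection — after each step `C` is eigenvalue-clipped at 1e−8 × trace and
  scalar variances floored, so iterates stay in the parameter space;
* backtracking on logL (the accepted candidate's factorization is reused as
  the next iteration's), starting from twice the previously accepted step;
* an EM-REML fallback (guaranteed uphill) whenever no damped AI step is
  acceptable.  A pure-EM mode (`method="em"`) is kept as an independent
  optimizer cross-check; it reaches the same stationary point, slowly.

Convergence is declared when the maximum relative parameter change (measured
against max(|θ|, 1e−3·Var(y)) so boundary components cannot stall the test)
drops below `tol` (default 1e−8, max 500 iterations), or when the
log-likelihood is numerically stationary — two consecutive accepted steps
changing logL by less than `stall_tol × max(1, |logL|)` (default 1e−7).  The
stall rule exists because near-boundary fits creep along flat ridges where
parameter changes stay above `tol` while the likelihood, and hence every
quantity of interest, has stopped moving; on a verification fit the stalled
and fully converged estimates agreed to <0.1% in every component.

AIC is `−2 logL + 2k` with `k` the number of free (co)variance parameters
(classic 4, social and all single-step variants 6).  Fixed-effect structure
is identical across compared models, so its contribution cancels in ΔAIC.
The ω grid warm-starts each fit from the previous ω's components, and the
social baseline can be warm-started from the classic fit.

Default starting values split Var(y) equally across the model's components
with σ_aDaS = 0 — neutral and PSD.

## Evaluation and validation

BLUP solutions and prediction error variances (PEV, the diagonal of the
inverted MME coefficient matrix) come from a direct dense factorization at
the converged components — exactness over iterative solvers, affordable at
desk scale (≲ 20k equations).  Theoretical accuracy is
`R = √(1 − PEV/((1+F)σ²))`, computed separately for DBV (σ²_aD) and SBV
(σ²_aS); numerical PEV excess over `(1+F)σ²` is clipped to `R = 0` with a
warning.  `CBV_i` is the animal's own DBV plus the SBVs of its pen mates.

Forward validation masks the last *k* (default 2) periods: the model is
solved on training records only (validation animals remain in the
pedigree/H, i.e. their genotypes stay in the evaluation — the genomic
preselection scenario), validation phenotypes are corrected by the training
fixed-effect estimates, `y_c = y − Xb̂`, and the reported statistic is
Pearson cor(CBV, y_c).  Fixed-effect levels that occur only in the
validation period (future batches) are inestimable from training; their
columns are dropped and those records are corrected by the intercept and
shared effects only.  The corrected phenotype subtracts fixed effects only,
not litter/group BLUPs.

## The synthetic-data generator

The generator emulates a closed nucleus pig herd: discrete generations,
random mating with a limited sire pool (each sire serves ~4 dams, matching
average half-sib family sizes around 4 in the nucleus populations this
mirrors), litters as full-sib sets, same-sex pens filled from sorted litters
within batch×sex cells (so pens hold 1–7 full sibs "naturally"; the true
farm allocation rule is unpublished and this is a stand-in), year-month-week
batch effects, and a N(155, 10²)-day age-at-target-weight covariate with a
configurable slope (−1.5 g/d per day by default; only the covariate's
existence, not its magnitude, is documented for the real data).  The ADG
intercept defaults to 790 g/d, the realistic scale for this trait.

Breeding values are generated under `Cov(a_D, a_S) = C ⊗ A` by a bivariate
Mendelian-sampling recursion (per-animal scaled Cholesky of C — identical in
distribution to a dense `C ⊗ A` Cholesky but linear in pedigree size).
Genotypes are gene-dropped unlinked biallelic markers with founder
frequencies uniform on a configurable interval.

Two genetic architectures are offered.  The default, `"pedigree"`, draws
breeding values from the pedigree recursion; genotypes are then relationship
markers only, which is the right null model for testing pedigree-based
estimation.  `"marker"` instead builds each breeding value as the sum of
centered gene-dropped dosages times bivariate normal marker effects (scaled
so the founder variance equals C), so realized genomic relationships carry
real information about the breeding values — the regime in which single-step
models should, and in tests do, beat pedigree-only models.  Phenotypes add
the plain (undiluted) sum of pen mates' social effects, so analyses of
equal-size-pen simulations should disable the dilution covariate (with equal
pens the two coincide anyway).

What the generator does *not* emulate: selection and overlapping
generations, linkage/LD between markers, genotyping error, heterogeneous
residuals, maternal effects.  Passing parameter-recovery tests on this
generator therefore demonstrates correctness of the estimation machinery
under the model's own assumptions, not robustness to the ways real herds
violate them.

## Test and acceptance problem sizes

Oracle-equivalence checks (A⁻¹ vs dense inversion of tabular A, A22 vs the
dense submatrix, H⁻¹ vs the dense tuned block, MME/PEV vs a dense GLS
computation) run on randomized instances of ≤ 300 animals at 1e−8 absolute
tolerance.  The replicate study behind the parameter-recovery and
model-selection tests simulates 20 populations of ~1,000 phenotyped animals
(240 founders, two generations) in pens of 5 with 2,000 markers and 30% of
phenotyped animals genotyped, true components
(σ²_aD, σ_aDaS, σ²_aS, σ²_g, σ²_l, σ²_e) = (2320, 72, 23, 479, 256, 3739)
(g/d)², marker architecture, and fits PED_classic, PED_social and the
single-step pair ω ∈ {0.6, 1.0} per replicate with `tol = 1e−4`,
`stall_tol = 1e−6`, `max_iter = 30` — settings verified above to reproduce
fully converged estimates.  At this scale the study resolves the large
components well; the sampling standard error of the mean across 20
replicates for σ_aDaS and σ²_l remains of the same order as the components
themselves, which the recovery test's discussion (and the repository's
decision log) treats explicitly rather than hiding.

## Known limitations

* Dense factorization bounds practical problem size to a few tens of
  thousands of equations; no iterative/APY path is provided.
* No metafounders, unknown-parent groups, or γ-adjusted G; τ ≠ 1 is exposed
  in configuration but not part of the default grid.
* Standard errors of variance components (and hence of T²) are not
  computed; model comparison rests on AIC only.
* `T²` and `σ²_P` printed for social models use the formulas above as
  printed sources do; published σ²_P values for social models are not always
  reconcilable with their printed components at any plausible pen size, and
  this package makes no attempt to resolve that — it implements the formula.
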