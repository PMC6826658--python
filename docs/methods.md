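# Methods

This note documents the statistical machinery in `stepblup`, the
choices made where the design was open, and what the synthetic data do
and do not emulate.

## The repeatability animal model

Every analysis fits

    y = Xb + Za + Wp + e,
    a ~ N(0, K sa2),  p ~ N(0, I sp2),  e ~ N(0, I se2),

where records are single-ejaculate trait percentages. Fixed effects
are a year-season class (a concatenation of year and calendar season;
the generator simply indexes classes 0..n-1) plus two covariates, boar
age at collection (months) and the interval since the previous
collection (days). Covariates are centered at their sample means for
conditioning; reported slopes stay on the original scale. One
reference level per fixed class is dropped so X has full column rank;
empty classes are dropped with a warning, and the REML routines
additionally remove any linearly dependent X columns by rank-revealing
QR (the restricted likelihood depends only on the column space of X).
The permanent-environment term is included exactly when some boar has
two or more records.

## Relationship matrices

* **A** (dense) by the tabular recurrence; practical cap configurable
  (default 20,000 animals). **A^-1** by Henderson's rules with
  Mendelian-sampling variances `d_i = 0.5 - 0.25 (F_s + F_d)`;
  inbreeding coefficients come from a Meuwissen–Luo-style recursion
  that never forms dense A. Inbreeding is used by default; a flag
  reproduces the no-inbreeding approximation for comparison. Unknown
  parents contribute as population mean (no unknown-parent groups: the
  workflow this package models gives no evidence of them).
* **A22** is the submatrix of A for the genotyped animals, sliced from
  dense A at moderate scale or obtained from sparse solves
  `A^-1 X = E` above the cap.
* **G** (VanRaden): `Z = M - 2p` per SNP and
  `G = ZZ' / sum_i 2 p_i (1-p_i)`. `p_i` is the observed frequency of
  the counted allele, not the folded MAF — folding would break the
  `0-2p / 1-2p / 2-2p` centering for SNPs with p > 0.5. A fold flag
  exists for sensitivity checks only. Frequencies are computed after
  the missing-to-heterozygote fill by default (single-matrix workflow);
  a flag computes them before.
* **Gw = 0.9 G + 0.1 A22** by default; `H^-1` adds `Gw^-1 - A22^-1`
  into the genotyped block of `A^-1`. G and A22 inverses use a
  symmetric Cholesky with a logged `1e-8`-scaled diagonal jitter
  fallback (pure G is always singular under observed-frequency
  centering — the row sums vanish — which is precisely why the blend
  exists).

## Genotype QC

The PLINK-style chain runs in a fixed order — individual call rate
(>= 0.90), SNP call rate (>= 0.90), MAF (>= 0.01), exact
Hardy–Weinberg test (p >= 1e-5) — each step on the already-filtered
matrix, with per-step removal counts in a JSON-serialisable report.
The HWE test is the exact conditional test on heterozygote counts
(chi-square available by flag). Missing genotypes remaining after QC
are set to the heterozygote code; with realistic missing rates
(~0.1 %) this perturbs G negligibly and avoids any imputation
machinery.

## Mixed-model equations

The MME are assembled sparse and factorised dense (Cholesky) at desk
scale; prediction-error variances come from the animal-block diagonal
of the inverse coefficient matrix (computed exactly via the triangular
factor inverse, not approximated), and reliability is
`r2 = 1 - PEV / sigma_a^2`. Solutions exist for every animal in K;
unphenotyped animals are predicted through the relationship structure
alone.

## AI-REML

The restricted likelihood is evaluated through MME identities:

    -2L = n log se2 + q log sa2 + log|K| + m log sp2 + log|C| + y'Py,

with C the R^-1-weighted coefficient matrix. Score traces use

    tr(P Z K Z') = q/sa2 - tr(C^aa K^-1)/sa2^2
    tr(P W W')   = m/sp2 - tr(C^pp)/sp2^2
    tr(P)        = (n - rank X - sa2 tr(PZKZ') - sp2 tr(PWW'))/se2,

where the needed entries of C^-1 come from the inverse triangular
factor: selected entries on the sparse K^-1 pattern for the animal
trace, the diagonal for the permanent-environment trace. A dense-V
evaluation of the textbook formula is retained for n <= 500 and used
as the oracle in tests (the two paths agree to ~1e-13).

Updates are average-information Newton steps
(`AI_ij = y'P V_i P V_j P y / 2`, built from MME solves of the
`V_i P y` vectors) with an active set: a component pinned at the
variance floor with a negative score is excluded (its AI row scales as
1/theta^2 and would poison the joint step), and when a joint step
drives a component below the floor it is pinned there and the step
re-solved for the rest. If the resulting step still decreases the
likelihood the iteration falls back to an EM-REML step, which is
monotone. Convergence: relative parameter change < 1e-8 or
|delta(-2L)| < 1e-9; maximum 100 iterations, after which a
`ConvergenceError` carrying the trajectory is raised. Initial values
split var(y) as 0.3/0.2/0.5 over genetic/permanent/residual parts.
Variances are floored at `1e-8 var(y)` rather than zero so the
variance ratios stay finite; estimates near the floor are flagged
`boundary` and their SEs set to NaN. SEs come from the inverse AI
matrix at the optimum; h² and repeatability SEs by the delta method.

The two-trait extension estimates three symmetric 2x2 matrices
(genetic, permanent-environment, residual) over records that carry
both trait values, exploiting the shared design through Kronecker
structure in the coefficient matrix. Updates are AI steps with a
relative trust region (no parameter moves more than 80 % per trial),
eigenvalue projection of each 2x2 matrix onto the PSD cone (warned),
and step halving when the likelihood would decrease. Genetic
correlations are estimated pairwise — a deliberate choice over a joint
five-trait fit, which would add little at this scale and is
numerically fragile. A `fix_covariances` option holds all cross-trait
covariances at zero, in which case the model factorises and reproduces
the single-trait fits (asserted in tests). When the true correlation
is close to 1 the estimate can sit exactly on the boundary (Sa
projected to singular, rg = 1.0); this is the constrained MLE, not an
error, but it makes the delta-method SE conservative.

### Collapsed-boar REML for recovery studies

The recovery/acceptance runs estimate against `K = A_bb`, the dense
pedigree relationship submatrix of the recorded boars, instead of the
full-pedigree sparse `A^-1`. Because the restricted likelihood depends
on the relationships only through `Z A Z' = Z_b A_bb Z_b'`, the
estimates are identical to the full animal model (a unit test asserts
this to 1e-4 relative) while the equation system drops the ~1,600
unrecorded ancestors. This is an internal efficiency device; the
library path used by the pipeline keeps the full pedigree.

## Deregression

Full-data pedigree-BLUP EBVs are deregressed with parent-average
removal: lambda = (1-h2)/h2, alpha = 1/(0.5 - r2_PA),
delta = (0.5 - r2_PA)/(1 - r2_i),

    Z'Z_PA = lambda (0.5 alpha - 4) + 0.5 lambda sqrt(alpha^2 + 16/delta)
    Z'Z_i  = delta Z'Z_PA + 2 lambda (2 delta - 1),

the 2x2 system is solved for the information right-hand sides, and
`DRP = y_i / Z'Z_i` with reliability `1 - lambda/(Z'Z_i + lambda)`.
The h² entering lambda is the AI-REML estimate from the same full
dataset. Animals with an unknown parent, `r2_i <= r2_PA`, or
`r2_PA >= 0.5` are skipped with a reason code, never clamped. Analysis
weights `w = (1-h2) / ((c + (1-r2)/r2) h2)` (c = 0.5) are computed and
stored but unused: predictive abilities are plain Pearson correlations.

## Validation designs

Cross-validation partitions the genotyped animals into 5 folds
(sizes differing by at most one), repeated 20 times with repeat r
seeded `base_seed + r`. GBLUP trains on the remaining genotyped folds
with K = G; ssGBLUP trains on every non-test animal with K^-1 = H^-1.
Test-set records are masked from training in both; raw records (never
DRPs) are the response; variance components are not re-estimated per
fold. The CV standard error convention is
`sd(fold correlations) / sqrt(k * repeats)`, recorded in the output
metadata. Forward prediction trains on all but the youngest two
generations; the predictive-ability test set is the genotyped
test-generation animals holding a valid DRP (eligibility is logged).
The method comparison reports `100 (r_ss - r_G) / r_G` per trait and
the EBV/GEBV/ssGEBV pairwise correlations on the forward test set.

## The synthetic generator

The generator emulates a Duroc AI-station population: a 12-generation
pedigree with per-generation sire/dam pools drawn from the previous
generation, balanced offspring sex ratios, gene-dropped unlinked SNPs
(founder frequencies uniform on a configurable interval, missingness
injected at 0.14 % by default), polygenic true breeding values
(founders N(0, Sigma_a); descendants parent average plus Mendelian
sampling with variance `0.5 (1 - (F_s+F_d)/2) Sigma_a`), one
permanent-environment draw per boar, and zero-truncated-Poisson record
counts. Default trait parameters are the five sperm-abnormality
traits' published components, means and genetic correlations;
year-season effect SDs default to the residual SD, and age/interval
slopes to 2 %/1 % of the residual SD per month/day — values in the
range a station dataset would show; all are overridable. Records
carry both trait values (same ejaculate); permanent-environment and
residual effects are uncorrelated across traits by default since no
published values exist for them.

What the generator does **not** emulate: linkage between markers (the
analyses here never exploit an LD map), selection (matings are
random), the CASA measurement process (distributional quirks of
percentage traits near zero, e.g. CT's mean of 0.15 %, are replaced by
Gaussian residuals), seasonal record clustering, or genotyping that
targets selection candidates. Passing tests therefore demonstrate
estimator correctness under the model's own assumptions — not
robustness to non-Gaussian percentages or selection-induced bias.

Two profiles are provided: `SimulationConfig.study_scale()` (~5,300
animals over 12 generations, ~1,300 phenotyped boars with ~22.6
records each, ~1,600 genotyped animals x ~36k SNPs) matching the
population the package models, and `SimulationConfig.demo()` (a few
hundred animals, 800 SNPs) used by the example, the test suite and the
default pipeline configuration so that a complete run — QC, kinships,
REML per trait, pairwise correlations, DRPs, 5x20 cross-validation and
forward prediction for five traits — finishes in a few minutes on one
CPU. The parameter-recovery study uses an intermediate scale (~950
boars with ~20 records in a 12-generation pedigree, ~2,550 animals
total), chosen so that ten seeded replicates resolve heritability to
about ±0.01 standard error of the mean.

## Known limitations

* Dense factorisation bounds the MME at roughly 10^4 equations; no
  iterative (PCG) solver is provided.
* The bivariate REML reports delta-method SEs that are unreliable when
  a covariance matrix converges to the PSD boundary.
* Deregression assumes the Garrick information model (one parental
  average, own+progeny information); reliability approximations for
  very large systems are out of scope.
* QC order effects are auditable through the report but not
  configurable; the fixed order mirrors common PLINK practice.
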