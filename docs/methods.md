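# Methods

`pinesem` re-implements, as a tested pipeline over synthetic data, an
integrated Bayesian-network + structural-equation genomic evaluation of nine
tree traits in an open-pollinated lodgepole pine breeding population:
multitrait Bayesian mixed models under pedigree (ABLUP) and marker (GBLUP)
relationship matrices, score-based network structure learning on
decorrelated breeding values, recursive structural equation models on the
learned graph, and model comparison. This note records the models, the
defaults and the design choices, and what the synthetic experiments do and
do not establish.

## Models

**Multitrait mixed model (MTM).** For trees i = 1..q and traits j = 1..9,

    y = X beta + Z a + e,   a ~ N(0, Sigma_a ⊗ K),  e ~ N(0, R0 ⊗ I_q)

with unstructured genetic (Sigma_a) and residual (R0) trait covariances.
K is the pedigree numerator matrix A (tabular method; unknown parents are
unrelated founders, diagonal 1 + F) or the VanRaden genomic matrix
G = WW'/(2 Σ p_k(1−p_k)) built from mean-imputed dosages after the panel
filters (≤30% missing, MAF ≥ 1%). Heritability per trait is
h² = σ²_a/(σ²_a + σ²_e); genetic correlations come from Sigma_a
off-diagonals. Point estimates are posterior means of the per-sample
quantities (so the reported h² is the mean of the ratio, not the ratio of
means — the two differ by up to ~0.01 at this study's values).

**Recursive SEM.** A strictly-lower-triangular (in the causal trait order
WGR, LIMO, HT, CAR, RES, WD, T_MONO, DECL, C13) coefficient matrix Lambda
enters as (I − Λ) y_i = X'beta* + a*_i + e*_i; the reduced form is
y_i = (I − Λ)⁻¹(X'beta* + a*_i + e*_i). Free entries of Λ are fixed by the
learned DAG's sparsity. With Λ = 0 and unstructured R0* the SEM is exactly
the MTM (verified by an acceptance test). A recursive system with both
Sigma_a and R0* unstructured is not identified, so the residual covariance
offers a `diagonal` option; the recovery analyses use it, the default
remains `unstructured` to preserve the Λ = 0 equivalence.

## Gibbs sampler

One engine serves both models. The kinship is eigendecomposed once,
K = U D U'; rotating trees by U' makes the tree-effect prior diagonal
(a*_i ~ N(0, d_i Sigma_a)) while leaving the i.i.d. residual term and the
fixed-effect cross-products invariant. Updates per sweep:

1. missing phenotypes from their reduced-form conditional normal, grouped
   by missingness pattern (data augmentation);
2. fixed effects B from the matrix-normal full conditional (flat prior);
3. each child trait's row of Λ from a **partially collapsed** conditional
   with the tree effects integrated out (per-tree marginal covariance
   d_i Sigma_a + R0). The naive conditional-on-effects update random-walks
   along the Λ/Sigma_a ridge; the collapsed draw (validated against
   brute-force grid evaluation of the collapsed likelihood, agreement to
   7 digits in mean and Hessian) breaks it. Tree effects are redrawn
   immediately after (a valid blocked update);
4. tree effects per tree from batched 9×9 Cholesky solves;
5. an ancillarity–sufficiency interweaving move: the Cholesky factor of
   Sigma_a is redrawn with the whitened effects held fixed — exactly
   Gaussian in the factor, with a Metropolis correction equal to the
   prior × Jacobian ratio — sliding (a, Sigma_a) jointly along the
   genetic/residual scale ridge;
6. Sigma_a and R0 from inverse-Wishart full conditionals (or per-trait
   scaled inverse-chi-squared matching the inverse-Wishart marginal, for
   diagonal R0*).

Priors: inverse-Wishart with df = t + 2 and scale 0.5·I for both
covariances (proper, weakly informative on the standardized scale; prior
mean 0.5 per variance); flat on B; N(0, 1) on each free λ (traits are
standardized, so unit-scale coefficients are weak information).

Chain presets: `desk` 60,000 / 10,000 burn-in / thin 5 (default),
`full` 510,000 / 10,000 / 2 (the published setting; retains 250,000
samples), `cv` 8,000 / 2,000 / 4 for per-fold refits. Tree-level effects
are stored as running posterior means/SDs rather than full traces (a full
trace at the `full` preset would hold ~10⁹ values); all covariance, fixed
-effect and λ parameters keep complete retained traces.

**DIC.** Deviance is the observed-data multivariate normal likelihood
conditional on the tree effects (residual-level focus), evaluated on the
reduced-form mean and covariance. DIC = D̄ + pD with pD = D̄ − D(plug-in);
the plug-in uses posterior means of effects and coefficients and
summarizes the covariance on the precision scale (the deviance is convex
there, keeping pD non-negative). The source analysis prints
"DIC = D̄ − pD", which contradicts the standard definition it invokes; the
standard form is implemented and the printed DIC differences are treated
as arithmetic on the published table values.

## Network learning

Input is the matrix of posterior-mean GBLUP breeding values, decorrelated
by the inverse Cholesky factor of K (a* = L⁻¹â), which removes
kinship-induced row dependence while preserving the trait covariance.

Scores are decomposable and computed from sufficient statistics, so each
local score is a small Schur complement: BIC is the Gaussian penalized
log-likelihood with |parents| + 2 parameters per node (larger is better,
matching the −2-rescaled convention of standard BN software); BGe is the
Bayesian Gaussian equivalent marginal likelihood in subset-ratio form
(prior mean 0, prior parametric matrix I, imaginary sample sizes
alpha_mu = 1 and alpha_w = t + 2), which telescopes to the closed-form
normal-Wishart joint marginal on complete DAGs — used as an exact oracle in
the tests — and scores Markov-equivalent DAGs identically.

Hill climbing applies the best strictly-improving single-arc
addition/deletion/reversal; tabu search additionally accepts non-improving
moves while forbidding recent inverses, and therefore never returns a
lower score than hill climbing. Moves are enumerated lexicographically by
(parent, child, move-type): parent-major tie-breaking resolves
Markov-equivalent add ties toward the arc leaving the lower-indexed node,
which keeps v-structures reachable by greedy search (child-major
enumeration leaves the search stuck in fork-shaped local optima on 16/50
random 4-node instances vs 4/50, and 0/50 with 8 random restarts).
Exhaustive enumeration over all DAGs (543 on 4 nodes) provides the oracle.

Bootstrap model averaging resamples trees with replacement, relearns, and
reports per-arc strength (presence in either orientation) and direction
confidence (majority orientation among replicates containing the arc);
the consensus keeps arcs at strength ≥ 0.95, dropping the lowest
direction-confidence arc iteratively if majority orientations ever form a
cycle. Defaults: 5,000 replicates (published), 500 desk, 200 in the
acceptance study.

## Synthetic data generator

The generator emulates the study conditions: 52 founders across 5
provenance groups, 50 open-pollinated families of 8 (a known dam, sires
treated as distinct unrelated males — the half-sib assumption in A),
optional full-sib families, a 25,000-SNP biallelic panel gene-dropped
through the pedigree (founder frequencies uniform on [0.01, 0.5], 10%
missing completely at random), and a "sets-in-reps" trial of 5
replications × 21 sets with i.i.d. normal replication (SD 0.5) and
set-within-replication (SD 0.3) shifts on the standardized trait scale.
Per-trait record missingness follows the published record counts
(0–16.3%).

The generative truth for the nine traits is anchored to the published
estimates, interpreted self-consistently: the **reduced-form** genetic
covariance is built from the MTM-GBLUP variances and genetic correlations;
Λ is the published 12-edge GBLUP network; the structural genetic
covariance is then Sigma_a* = (I−Λ) Sigma_red (I−Λ)', and the diagonal
structural residual solves [(I−Λ)⁻¹ R0* (I−Λ)⁻ᵀ]_jj = ve_MTM,j. Under this
interpretation the structural variances of the upstream traits reproduce
the published SEM values to within ~0.05 and the implied marginal
phenotype variances are ≈1 — consistent with the standardized analysis
scale. (Reading the published SEM correlation triangle as structural-scale
correlations instead yields marginal variances up to 1.76 and makes λ and
the genetic covariance observationally near-equivalent; the published
tables do not state which scale that triangle is on.)

Default phenotypes are generated directly on the analysis scale
(continuous, ~standardized); an opt-in raw-scale mode exponentiates the
log traits, discretizes the rust score into four ordered categories and
restores field-scale means/SDs so the full preprocessing chain (log →
normal score → design adjustment → standardization) can be exercised.

What the generator does **not** emulate: linkage/LD structure along a
genome, spatial autocorrelation in the field (design effects are i.i.d.
cell shifts), residual trait correlations beyond those induced by Λ
(diagonal R0*), genotyping error, and pedigree errors. Passing tests
therefore show the estimators are correct under the stated model, not that
the model captures every feature of the field data.

## Analysis-scale choices and known limitations

* **Design adjustment.** The preprocessing module implements the two-step
  procedure (OLS with sum-to-zero factor effects, subtracted per trait).
  With ~105 set-within-rep cells against 400 trees, any within-subset
  adjustment — two-step OLS or one-step flat-prior fixed effects
  (`MtmSpec.design_factors`) — removes a ~27% dimension share and smears
  variance across kinship eigendirections, attenuating the genetic
  eigen-profile more than the residual. The recovery analyses use the
  one-step route; the original study subtracted effects estimated on the
  full multi-thousand-tree trial, which our 400-tree world cannot supply.
* **Variance-split identification.** With ~50 open-pollinated families,
  K deviates from I mainly through 0.25 half-sib blocks plus realized
  Mendelian noise; the per-trait genetic/residual split is weakly
  identified (posterior SDs ~0.15–0.2), and the unstructured-R0 MTM and
  diagonal-R0 SEM tip the split in opposite directions. Structural
  coefficients λ are far better identified than the splits: across
  repeated desk-scale studies all 12 are recovered within 2 posterior SD,
  while per-trait variance components can deviate by 1–2 SD.
* **Bootstrap edge support.** At n = 400, the weakest published effects
  (λ ≈ 0.09–0.14 and genetic correlations down to 0.04) are intrinsically
  below the 95%-bootstrap-strength detection limit from exactly
  decorrelated genetic values (7/12 edges reach it) or estimated breeding
  values (5–8/12, seed-dependent). The published near-universal 100%
  strengths evidently reflect estimation-induced dependence between
  breeding values that the published covariance tables do not encode.
* **Numerical details.** G is repaired with +1e−6 on the diagonal when its
  smallest eigenvalue is ≤0 (the sample-frequency centering always leaves
  one zero eigenvalue); kinships must be positive definite before
  fitting. Degenerate design cells are pruned by pivoted QR. HPD intervals
  are shortest-interval on sorted samples. All generators and samplers are
  reproducible from a single integer seed.

## Problem sizes used in the shipped analyses

The acceptance script runs, from scratch: the printed-table arithmetic;
the 50-dataset exhaustive-search oracle; one full GBLUP study at n = 400
with 24.8K post-filter SNPs (MTM and SEM chains of 30,000/6,000/4),
bootstrap averaging at 200 replicates, and 5-fold cross-validation with
2,500-iteration per-fold chains; a 5-trait SEM/MTM equivalence study at
n = 200 (20,000-iteration chains); and the decorrelation diagnostics at
n = 400. The acceptance tests use the `desk` 60,000-iteration preset for
the recovery study. These sizes are the package's desk-scale defaults; the
`full` preset reproduces the published chain plan.
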