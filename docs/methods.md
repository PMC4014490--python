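# Methods

## The mapping problem

In a heterogeneous stock (HS) population — an outbred cohort descended from
eight inbred founders — each animal's genome is a fine-grained mosaic of
founder chromosomes. Two features make interaction mapping hard there:
relatedness varies continuously between animals, and the space of candidate
interactions (every SNP × sex, every SNP × SNP pair) is far too large for
exhaustive frequentist testing. `gxsmap` addresses both with a sparse
Bayesian model search plus a set of supporting analyses (bootstrap
resample-model-averaging scan, kinship/REML heritability, cross-validated
variance decomposition, permutation calibration).

## Sparse-partitioning model

A model state is a partition of a small selected subset of predictors into
disjoint groups of one to three members. Predictors are SNP genotypes treated
as 3-level factors (not additive dosages) plus a distinguished sex indicator.
A group of co-grouped predictors contributes one mean per *observed joint
level* of its members — so a {SNP, sex} group fits six cell means, which is
exactly a genotype-by-sex interaction.

Likelihood and priors:

* y | β, σ² ~ N(μ1 + Xβ, σ²I), where X holds the one-hot indicators of every
  observed joint level of every group;
* level means β ~ N(0, τ²σ²I) with τ² = 0.2 by default (prior SD ≈ 0.45 on a
  standardized trait — effects larger than half an SD are not expected);
* the intercept μ is flat, and σ² carries the scale-free prior 1/σ².

Integrating μ, β and σ² analytically gives the closed-form log evidence

log m(y) = lgamma((n−1)/2) − ½log n − ((n−1)/2)·log 2π − (q/2)·log τ²
− ½log|S| − ((n−1)/2)·log(R/2),

with S = X_c′X_c + I/τ², R = y_c′y_c − y_c′X_c S⁻¹ X_c′y_c on the centred
design, q the total number of observed levels. A joint level that never
occurs contributes no column (no error); an all-constant predictor's centred
column is zero, and its |S| and (q/2)log τ² terms cancel exactly, so
degenerate predictors are evidence-neutral.

The state prior is independent inclusion with rate chosen so the expected
model size is 2, times a uniform distribution over the legal groupings of the
included set (so grouping carries no prior preference beyond legality). Legal
means: ≤10 distinct predictors, ≤2 three-way groups, and — under the
GxS-prohibited mode (`interaction_mode="snp_only"`) — sex restricted to a
singleton group.

This conjugacy is the reason the prior was built this way: for small
predictor counts every legal state can be enumerated and the posterior
computed exactly, giving an independent oracle for the sampler
(`enumerate_posterior`).

### The sampler

Metropolis-Hastings over states with four moves (weights 0.3/0.3/0.2/0.2):
add an excluded predictor as a new singleton; remove a singleton predictor;
move a predictor into another group or split it out; swap an included
predictor for an excluded one in place. Removal is restricted to singletons
so every move has a single-move reverse with a computable proposal density —
a grouped predictor leaves via split-then-remove — keeping the kernel
reversible; the test-suite checks the chain's stationary frequencies against
the enumerated posterior on a frozen instance.

Each recorded iteration is a sweep of elementary moves, one per predictor by
default. With thousands of candidate SNPs a single elementary proposal per
iteration cannot traverse the predictor set within the nominal 2000-iteration
schedule; the sweep convention keeps that schedule meaningful at any
predictor count while leaving the recorded chain length at `iterations`.
Evidence values are memoized per state within a run.

Posterior summaries are frequencies over the retained samples (default
2000 − 500 = 1500), so every reported probability is k/1500 for integer k.
Calls use a 0.2 posterior threshold; a (SNP, sex) pair above threshold is a
GxS QTL, a SNP–SNP pair a GxG QTL.

## Bootstrap RMIP scan

The comparator works on founder-ancestry dosages: at each locus an
(n × 8) dosage block, one column dropped for identifiability. Forward
selection adds, at each step, the locus with the largest residual
sum-of-squares reduction, gated by its partial F-test p-value
Bonferroni-adjusted for the number of remaining candidates
(min(1, p·L) ≤ α = 0.05). The adjustment matters: the winning candidate is
the best of all remaining loci, so a raw per-test gate fires almost surely
under the null and forward selection runs away; the adjusted gate calibrates
the scan to roughly one spurious inclusion per 1/α scans, consistent with
reading RMIP > 0.25 as a one-false-positive-per-scan threshold. Selection
stops at a 20-locus cap.

The scan is repeated on 100 bootstrap resamples of individuals; the RMIP of a
locus is its inclusion count over 100. Peaks are local maxima above 0.25,
merged within 3 Mbp (about the HS mosaic resolution); a peak's 95% CI is the
2.5th–97.5th percentile of the positions selected within the merge window
across bootstraps, widened if needed to contain the peak itself. Single-sex
scans simply restrict the sample (warning below 50 animals).

## Heritability

Kinship is the allelic correlation K = ZZ′/m with z = (g − 2p)/√(2p(1−p)),
allele frequencies taken from the sample, monomorphic (zero-variance) markers
excluded. REML for y ~ μ + g + e, cov(g) = σ²_g K, cov(e) = σ²_e I works in
the eigenbasis of K: the restricted likelihood, profiled over σ²_e, is
maximized in the ratio λ = σ²_g/σ²_e on a log₂ grid from 2⁻¹⁴ to 2¹⁴ refined
by golden-section search. Eigenvalues down to −10⁻⁸ are clipped to zero;
anything lower is rejected as non-PSD. A likelihood flat in λ (e.g. K = I,
where the two components are unidentifiable) returns h² = 0 with
`converged=False` and a warning rather than an arbitrary number. A dense
no-eigentrick REML evaluation serves as the numerical oracle in tests
(agreement to 10⁻⁶).

## Preprocessing

Order of operations: Box-Cox, then covariates, then relatedness — matching
the narrative order of the analysis this pipeline reproduces. The Box-Cox
power is chosen on the grid −2…2 by 0.1 (shift 1 − min(y) when values are
non-positive); output is standardized. Covariates are screened marginally at
α = 0.05 and the retained set regressed out jointly; rank deficiency among
retained covariates is an error naming the offending columns. Relatedness
adjustment estimates (σ²_g, σ²_e) by REML and whitens y by
(σ²_g K + σ²_e I)^(−1/2) — a GLS rotation rather than BLUP residuals, chosen
because it leaves an exactly exchangeable trait for the downstream mapper;
with K = I it reduces to standardization. Pruning clusters markers
left-to-right within each chromosome, joining a cluster when ≥99% of
(pairwise non-missing) genotype codes match the cluster's leftmost
representative; representatives are retained, which makes pruning
idempotent.

## Cross-validated GxS variance

Ten random near-equal folds. For each fold, chains are trained on the rest
under two configurations differing only in whether sex may co-group with
SNPs; prediction is the posterior-mean model average — each retained state
refit on the training tranche (conjugate ridge solution for its level means),
evaluated on the held-out animals, averaged with the state's retained
frequency as weight; joint levels unseen in training fall back to the state's
intercept. Percent variance explained is pooled over folds,
100·(1 − ΣSSE/ΣSST) with SST against the training-fold mean — pooling is more
stable than averaging per-fold R² for fold sizes near 100–200 and can go
negative (overfit models predict worse than the mean; no clamping). Both
configurations share per-fold chain seeds, so exchanging them exactly negates
the reported difference.

## Downstream statistics

* Permutation calibration: one permutation per phenotype (matching the
  headline analysis; more via a parameter), chains rerun, interaction
  probabilities ≥ 0.2 counted — the expected false-positive count.
* Cross-mapper matching: a mapper call matches an RMIP peak when chromosomes
  agree and the call position lies in the peak's 95% CI widened by 2 Mbp;
  assignment is greedy nearest-first with each peak used once.
* GxS vs single-sex scans: a GxS call is classified male-only / female-only /
  both / neither by the presence of an RMIP ≥ 0.25 peak within 5 Mbp in each
  sex's scan.
* Wilcoxon rank-sum: W is the mid-rank sum of the first group; p is exact by
  enumeration for ≤12 observations, else the tie-corrected normal
  approximation; two-sided throughout.
* Correlation: Pearson r with t = r√((n−2)/(1−r²)) on n−2 df. (The analysis
  this reproduces prints t(14) for n = 15; the standard df is n−2 = 13, which
  is what the implementation reports.)

## Synthetic data: what it emulates and what it does not

The generator breeds discrete generations of random mating from whole founder
chromosomes, crossovers Poisson with rate `recomb_per_mb` × interval length
(default 0.005/Mbp, which after the default 50 generations gives the ~3 Mb
mosaic scale). Founder alleles are drawn so the expected population MAF per
marker is uniform on a configured range (carriers = round(8p), clipped to
1–7, so no marker is monomorphic in the panel). Sexes are i.i.d. with default
male fraction 0.519. Phenotypes sum an intercept, sex effect, additive QTL,
one-sex-only GxS effects, 3×3 joint-genotype GxG terms, a polygenic component
with covariance proportional to the allelic kinship (scaled so its share of
polygenic-plus-noise variance equals `h2_polygenic`), and Gaussian noise; the
truth record reports each component's realized variance share. Options plant
≥99%-concordant duplicate markers (genotyping-error fixture for the pruning
stage, discordance capped at the configured rate by construction) and blend
Dirichlet noise into the ancestry dosages to emulate soft inferred founder
probabilities.

Not emulated: the real HS breeding pedigree and family structure (random
mating only), X-chromosome dosage compensation (all chromosomes are treated
as autosomal — a documented simplification; the real data include an X-linked
GxS locus), genotyping missingness, and mutation. Passing tests therefore
demonstrate correctness of the algorithms under a plausible HS-like
architecture, not performance claims about any particular real dataset.

## Problem sizes and numerical choices

Test and validation runs use desk-scale versions of the study conditions:
populations of 300–1900 animals, tens to thousands of markers, pedigrees of
5–20 generations, chains of 250–2000 iterations (50,000 for the
enumeration-equivalence check), 20–100 bootstraps — chosen so the full suite
completes in minutes while preserving each effect's detectability at the
planted effect sizes. Numerical guards: evidence residuals floored at 10⁻³⁰⁰
before logs; kinship eigenvalue clipping at −10⁻⁸; symmetry tolerance 10⁻¹⁰;
flat-REML detection at 10⁻⁸ log-likelihood range; all derived child seeds are
drawn from one master seed via `numpy.random.SeedSequence`, so every stage is
bit-reproducible.

## Known limitations

* Posterior probabilities inherit Monte Carlo error of order
  1/√1500 ≈ 0.026 at the default schedule; borderline calls near the 0.2
  threshold are sensitive to the seed.
* The sampler visits three-way groups rarely under the default prior;
  detecting genuine three-way interactions needs longer chains.
* The CV difference is a noisy estimator at realistic GxS effect sizes
  (~0.1–2% of variance); single-phenotype differences should be read
  qualitatively, as in the analysis this package reproduces.
* REML assumes a single genetic variance component; sex-specific genetic
  variances are out of scope.
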