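# Methods

## The cross and its constraints

An A(BC) 3-way crossbred is the offspring of a purebred line-A sire and
an F1 dam (line-B sire × line-C dam).  Its paternal gamete is pure line
A, so the line-A proportion is exactly 0.5; the maternal gamete is a
recombinant mosaic of B and C, so the dam-line proportions satisfy
b_B + b_C = 0.5 within every animal, E[b_B] = E[b_C] = 0.25 across
animals, and 0 ≤ b_B, b_C ≤ 0.5.  All estimators and the post-processing
exploit these constraints.

## Estimators

**BOA counting.**  Given a per-allele line-of-origin assignment,
b_line = (#alleles of that line) / (#assigned alleles).  With complete
assignment this equals the defining true proportion; with alleles
unassigned uniformly at random it remains unbiased.  The package does
not phase or assign origins in real data — it consumes an external
assignment, or the simulator's exact tracking.

**LR (sire-adjusted linear regression).**  Regressors are per-line
*mean allele counts* x = 2p.  Coding the regressors as counts rather
than frequencies matters: fixing b_A = 0.5 and subtracting 0.5·x_A
removes exactly the expected sire contribution (one allele per locus);
with frequency coding only half of it would be removed.  The remaining
system g\* = x_B b_B + x_C b_C + e is solved per animal by ordinary
least squares without intercept.  LR uses frequencies counted within
the purebred lines.  Raw solutions can leave [0, 0.5]; the
post-processing handles that.

**Supervised admixture (ADM).**  The standard binomial admixture
likelihood with ancestral (line) allele frequencies held fixed,
maximised per animal over the 3-simplex by EM with responsibility-
weighted allele shares.  Initialisation is the expectation
(0.5, 0.25, 0.25); iteration stops when the largest per-animal
log-likelihood change falls below 1e-7 (at most 1000 iterations);
frequencies are floored into [1e-6, 1−1e-6] to keep the likelihood
finite.  The EM log-likelihood is non-decreasing, which the tests
assert, and the fitted optimum is cross-checked against random simplex
restarts.  Because the likelihood assumes linkage equilibrium, the
pipeline runs ADM on an LD-pruned panel (default r² > 0.5, window 50,
step 10) — stringent pruning discards too many markers and degrades the
estimates, so an intermediate threshold is the default.

**Grandparent relationships (REL_GP, REL_GP_noF).**  All line-B alleles
of an A(BC) animal descend from its line-B maternal grandsire, so the
realised line-B proportion equals the genomic identity-by-descent
relationship with that grandsire (likewise C and the granddam).  As a
proxy the package computes the multi-population identity-by-state
relationship

    G_ij = Σ_m (g_im − 2p_im)(g_jm − 2p_jm)
           / sqrt(Σ_m 2p_im(1−p_im) · Σ_m 2p_jm(1−p_jm)),

with population-specific frequencies: the grandparent uses its line's
frequencies, the crossbred the blend 0.5 p_A + 0.25 p_B + 0.25 p_C.
Line frequencies for this method are estimated by per-SNP least squares
of *all* genotypes (purebred and crossbred) on expected line
proportions, g = 2Πp + e, with design rows (1,0,0), (0,1,0), (0,0,1)
and (0.5, 0.25, 0.25); solutions are clipped to [0, 1] (the behaviour
for out-of-range solutions is a package convention — they are rare and
mild on realistic panels).  REL_GP reports G_ij directly, which assumes
a non-inbred grandparent; REL_GP_noF reports G_ij / G_jj, using the
grandparent's self-relationship as an estimator of 1 + F.  Crossbreds
lacking a genotyped maternal grandparent are excluded from these
methods; the comparison pipeline restricts *all* methods to that common
cohort so the metrics are comparable.

## Post-processing

Per method and cohort, in order: (1) clip b_B, b_C to [0, 0.5];
(2) add (0.25 − cohort mean) to each dam line separately; (3) clip
again; (4) rescale each animal by 0.5/(b_B + b_C).  The order follows
the procedure the estimators are validated against; a single pass is
applied (the steps are not iterated, and the procedure is not
idempotent in general since step 4 can move the means again).  An
animal with b_B + b_C = 0 after step 3 has no information left about
the split and is set to the expectation (0.25, 0.25), with a logged
warning.  After step 4, b_C = 0.5 − b_B for every animal, which makes
every cohort-level metric computed on line C identical to the one on
line B — asserted in the tests.

## Evaluation metrics

Accuracy is the Pearson correlation between estimated and reference
line-B proportions.  Dispersion bias is the slope of regressing the
reference on the estimate — cov(ref, est)/var(est) — so 1 means
correctly scaled and values below 1 flag inflated estimate variance.
Maximum absolute error and RMSE complete the picture.  F_ST between
lines uses the Weir–Cockerham (1984) θ estimator with per-locus
components, averaged across loci as a mean of per-locus ratios (loci
with zero denominator are skipped); both the multi-population and the
pairwise form are available.

## Theoretical distribution of a dam-line proportion

The maternal gamete's B-fraction follows a two-state origin process
along the genetic map whose origin indicator at map distance d has
covariance e^(−2d)/4 (Haldane model, no interference).  Integrating
over a chromosome of length l Morgan gives the gamete-fraction
variance

    v(l) = (1/(2l²)) · (l/2 − (1 − e^(−2l))/4),

evaluated by series expansion below l = 1e-3 to avoid cancellation.
Chromosomes combine with length-squared weights,
Σ l_i² v(l_i) / (Σ l_i)², and the line proportion is half the gamete
fraction, so its variance is a quarter of that; the mean is 0.25.  For
the simulated genome (3.20 + 0.61 Morgan) this gives variance 0.01274
(SD 0.113).  The closed form equals the exact covariance integral (the
tests verify it against numerical integration and against Monte-Carlo
meiosis at 10^5 gametes); it is also the variance of
grandparent–grand-offspring genome sharing for a non-inbred
grandparent, the quantity the REL_GP methods estimate.

## The simulator

The simulator reconstructs the validation conditions rather than
replaying any particular dataset:

- **Genome**: two chromosomes of 3.20 and 0.61 Morgan (pig SSC1/SSC18
  scale) with target segregating SNP counts 4800 and 920 after
  filtering — a 60k-chip-like density.  SNP positions are uniform on
  the map.  Because drift and the joint MAF > 0.1 filter remove
  markers, the simulator oversamples positions by a factor 2.2 and
  thins evenly per chromosome to the targets after filtering.
- **Founders and LD**: founder frequencies are uniform(0.05, 0.95) with
  haplotypes sampled independently, followed by 100 generations of
  random mating at the scenario's Ne to build linkage disequilibrium.
  No mutation; recombination is Haldane (Poisson crossovers, uniform
  positions, no interference), sex-averaged map.
- **Divergence**: the three lines breed separately from the shared base
  for t generations at size Ne.  Presets: `close` (t=5, Ne=68),
  `distant` (t=20, Ne=72), `unrelated` (t=50, Ne=82).  Ne was
  calibrated so the realised mean-of-ratios Weir–Cockerham F_ST on the
  MAF-filtered panel hits the scenario targets 0.04/0.12/0.22; the
  textbook drift approximation 1−(1−1/(2Ne))^t is not used directly
  because the per-locus-averaged estimator reads below nominal drift F
  at high divergence and above it at low divergence.
- **The cross**: 25 line-B sires × 100 line-C dams produce 200 F1 dams;
  25 line-A sires × F1 dams produce 428 crossbreds (all sizes
  configurable).  Cross parents are drawn from the 1000 genotyped
  purebreds per line, so grandparent genotypes are in the panel.  An
  optional masking probability removes grandparents from the panel
  (≈0.34 reproduces cohorts where only ~44% of crossbreds have both
  grandparents genotyped); the default is 0.
- **Truth**: allele origins are tracked segment-wise through every
  cross meiosis; true proportions are computed on the same filtered
  panel the estimators see.

What the simulator does *not* emulate: selection (divergence is pure
drift), mutation, sex chromosomes, realistic site-frequency spectra
from deep coalescent history, genotyping error, and missing genotypes.
Passing tests therefore demonstrate correctness of the estimators and
the expected ordering of methods across divergence levels, not
performance guarantees on any particular livestock dataset.

## Numerical choices and conventions

- Genotypes are counts of the *first* allele listed in the (extended,
  6-column) MAP file; with a plain 4-column MAP the reference allele is
  the alphabetically first allele observed at the SNP.
- Missing genotypes are rejected at ingest; optional per-SNP
  within-line mean imputation is available behind an explicit flag.
- MAF filtering keeps SNPs with min(p, 1−p) strictly greater than the
  threshold, computed jointly over all animals.
- LD pruning removes the lower-MAF member of an offending pair,
  breaking ties towards the later index; the guaranteed contract is the
  post-condition (no surviving within-window pair above threshold), not
  agreement with any external tool's tie-breaking.
- LR raises on collinear regressors (x_B proportional to x_C across all
  SNPs); the admixture EM raises on non-finite likelihoods (prevented
  by frequency flooring); relationship scaling raises when a
  population's heterozygosity sum is zero.
- All randomness descends from a single integer seed through
  `numpy.random.SeedSequence` children; identical configuration implies
  byte-identical outputs.

## Problem sizes used in the checks

The acceptance-level tests run one full-scale replicate per scenario
(1000 purebreds/line, 428 crossbreds, ~5700 SNPs) — the package's
standard study conditions — plus a large-cohort cross (1000 crossbreds
over a reduced purebred base) for the sharpest check of the theoretical
mean and variance of the true proportions.  Monte-Carlo oracles use
10^4–10^5 gametes with standard-error-based tolerances.

## Known limitations

- The BOA assignment step itself (phasing and breed-of-origin of
  haplotypes) is out of scope; only its output format is consumed.
- 4-way crosses and crosses where one breed contributes through both
  parents are not supported: the grandparent-relationship logic assumes
  each dam line enters through exactly one maternal grandparent.
- The regression frequency estimator assumes the four design categories
  (A, B, C, ABC) cover the panel; other cross types are not modelled.
- Estimates for cohorts of one animal are technically processed but the
  centring step then forces b_B = b_C = 0.25 regardless of data.
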