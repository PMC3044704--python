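# Methods

## Model

`bayesgwa` fits the whole-genome regression

    y = X b + Σ_j Z_j u_j δ_j + e

where `y` is the vector of phenotypes for one trait, `X` the incidence
matrix of fixed effects (genetic line, measurement date, scorer, and a
centered body-weight covariate), `Z_j` the 0–2 count of the array
B allele at SNP `j`, and `e ~ N(0, σ²_e I)`. Each SNP effect is zero
with prior probability π or drawn from `N(0, σ²_u)` with a single
effect variance common to all included loci (the "Bayes C" mixture, as
opposed to locus-specific variances). Both variances carry scaled
inverse chi-square priors, `σ²_u ~ S⁻²χ²(v_u, S²_u)` and
`σ²_e ~ S⁻²χ²(v_e, S²_e)`.

Defaults: π = 0.995, v_u = 4, v_e = 10. π is fixed, not estimated.
Fixed effects have flat priors.

### Prior scale calibration

When the scales are not supplied they are derived from a heritability
prior `h²` and the phenotypic variance `V_p`:

    E[σ²_u] · (1−π)K · mean(2p(1−p)) = h² V_p
    E[σ²_e] = (1−h²) V_p

i.e. the expected number of included loci times their expected
per-locus variance contribution matches the genetic variance implied by
the heritability prior. Since a scaled inverse chi-square with df `v`
has mean `v S²/(v−2)`, each scale is its target mean times `(v−2)/v`
(df > 2 required). With h² = 0.5, V_p = 1, K = 2000, π = 0.995 and mean
2p(1−p) = 0.5 this gives E[σ²_u] = 0.1.

### Gibbs sampler

One sweep updates, in order: each fixed-effect coefficient from its
Gaussian full conditional; each locus *jointly* — the indicator δ_j is
sampled from the two-component marginal likelihood with u_j integrated
out (log Bayes factor `−½ log(C σ²_u) + ½ rhs²/(σ⁴_e C)` with
`C = Z_j'Z_j/σ²_e + 1/σ²_u`, `rhs = Z_j'r_j`), and, when included, u_j
from `N(rhs/(σ²_e C), 1/C)` — and finally both variances from their
conjugate scaled inverse chi-square conditionals. The joint
indicator/effect update avoids the poor mixing of conditioning on a
stale effect value.

A residual vector `r = y − Xb − Σ Z_j δ_j u_j` is maintained
incrementally; every 100 iterations it is re-derived from scratch, the
largest deviation is recorded as a diagnostic
(`PosteriorSummary.resid_max_dev`), and the residual is refreshed so
floating-point drift cannot accumulate. Chains of 11,000 iterations
stay below 1e−8 in practice (typically ~1e−14).

Chain control defaults to 11,000 iterations with 1,000 burn-in and no
thinning. The kept indicator trace is stored bit-packed
(`np.packbits`), so window model frequencies are computable after the
run without re-sampling. Missing genotypes are mean-imputed to `2p`
(twice the B-allele frequency) before sampling, which preserves allele
frequencies; QC retains missing calls untouched.

Random numbers are consumed at a fixed rate per scan position (one
uniform and one normal per locus, whether or not it enters), so a run
is bit-reproducible from its seed, and permuting SNP columns while
passing the matching `scan_order` reproduces the identical chain with
permuted output. This is the sampler's "seed semantics per locus
index": the visitation order, not the column order, indexes the random
stream. Exact permutation equivariance without a matching scan order is
impossible for any sequential-scan Gibbs sampler, because the full
conditional of a locus depends on which loci were updated before it
within the sweep.

Correctness of the locus update is established against an independent
oracle: exhaustive enumeration of all 2^K indicator configurations with
Gaussian marginal likelihoods (tests/oracle.py), which the sampler
matches within 0.02 on marginal inclusion probabilities and posterior
effect means at K ≤ 8 with variances fixed.

Numerical guards: the inclusion log-odds is clamped at ±35 before the
logistic transform (beyond which the probability is 0/1 to double
precision); a non-finite likelihood aborts the chain naming the locus.

## Evidence statistics

*Model frequency* — the fraction of post-burn-in iterations in which a
SNP is in the model. The *conditional* mean effect ("delta") is the
posterior mean effect divided by the model frequency, reported as 0
with a flag for SNPs never included.

*Windows* — sliding windows of 5 consecutive SNPs (step 1) within each
chromosome; windows never cross chromosome boundaries, and unmapped
SNPs form their own trailing block windowed among themselves. The
window model frequency counts an iteration if any member SNP is in the
model (hence it is bounded below by the largest member SNP frequency —
an exact union bound on the trace). The window breeding value of an
animal is its dosage-weighted sum of posterior mean effects over the
window; its across-animal sample variance (n−1 denominator; only
relative magnitudes matter) and its share of the genomic breeding-value
variance localize QTL. Candidate regions are formed by ranking windows
by variance and merging overlapping windows, each region keeping its
best window; ties break by genome order.

## Bootstrap significance and PFP

Under the null hypothesis that a window harbors no QTL, replicate
phenotypes are constructed from the fit's posterior means with the
window's SNPs excluded:

    y* = X b̂ + Σ_{j∉window} Z_j û_j + σ̂_e z,   z ~ N(0, I)

Each replicate is refitted with the same Bayes C model (the window's
SNPs stay in the refit's mixture — removing them would leave the
replicate's window statistic undefined — with fresh chain seeds derived
per replicate from a master seed) and the window's breeding-value
variance is extracted. With `m` of `N` replicates *strictly* exceeding
the observed statistic (ties count as non-exceeding, the conservative
choice), the comparison-wise p-value is the interval `(m/N, (m+1)/N)`;
one exceedance in 1,000 replicates reports 0.001 < p < 0.002. The
default is N = 100 replicates at desk scale; N = 1,000 reproduces the
reference convention and is a parameter, not a code change.

Multiple testing is summarized by the proportion of false positives

    PFP = π₀ α / (π₀ α + (1−π₀) · power)

the expected share of declared positives that are true nulls. At
π₀ = 0.99 and power 0.5 this is 0.6644 for α = 0.01 and 0.16528 for
α = 0.001.

## Quality control and population structure

Animals below 80% call rate are removed first; SNPs are then filtered
on the animal-filtered matrix in a fixed order — no call, call rate
(< 90%), GenTrain (< 0.5), MAF (< 0.05), Hardy–Weinberg (1-df χ²
goodness-of-fit p < 1e−6) — so each removed SNP has a single primary
reason. The two call-rate thresholds reflect that the operative SNP
filter is stricter (90%) than the animal filter (80%); both are
configurable. HWE is tested pooled by default with an option to
stratify by group (minimum p across groups), since line-wise testing is
a defensible alternative. Monomorphic SNPs get HWE p = 1 (no departure
testable) and are removed by the MAF filter instead. A zero threshold
disables the corresponding check.

Population structure is summarized by identity-by-state distance
(1 − shared alleles / 2·loci over jointly called loci) with
complete-linkage agglomerative clustering, cut at k clusters and
relabeled by first occurrence for determinism.

## Synthetic data generator

The generator emulates a two-line commercial-pig design: 412 + 408
animals by default, a dense panel scaled to 2,000 SNPs on 10
chromosomes at 40 kb spacing, mixture fraction 0.995 (≈10 causal SNPs),
target h² = 0.5 on a unit-variance scale, 14 measurement dates, two
scorers, and body weight 124 ± 11 kg with a 0.02/kg slope. Fixed-effect
magnitudes (line 0.3, date SD 0.2, scorer SD 0.1 phenotypic SDs) are
chosen so systematic effects are material but do not dominate the
genetic signal.

Haplotypes follow a first-order Markov copying model: with probability
ρ (default 0.8) a haplotype copies its previous-SNP allele, otherwise
it draws fresh. Two implementation details matter:

* the fresh-draw probability is adjusted so the marginal allele
  frequency tracks the per-SNP target rather than a geometric average
  of upstream targets (naive copying smooths marginals, which would
  silently erase any per-SNP frequency structure);
* adjacent-SNP r² is then ≈ ρ², decaying as ρ^(2d) with distance, and
  is monotone in ρ — checked as a property.

Line 2 samples from a pool whose frequencies are beta-perturbed around
line 1's (per-SNP marginal `Beta(pc, (1−p)c)` with
`c = (1−F)/F`, an F_ST-like magnitude, default F = 0.05). The
perturbation is driven by one shared quantile per 20-SNP segment, i.e.
it is correlated along the chromosome like drift acting on haplotypes;
independent per-SNP perturbations cannot survive the copying process's
marginal smoothing (the realized divergence collapses by a factor
≈ (1−ρ)/(1+ρ)). At the default mild divergence the two lines cluster
as one population; at F ≥ 0.3 the between-line IBS distance separates
from the within-line distance.

QTL effects are normal draws rescaled so the sample variance of true
breeding values equals h² exactly; residual variance is 1−h². Each
continuous trait is also emitted as a nine-point score by rank-binning
into equal-frequency bins, since no latent model for subjective scores
is available. The simulator writes one record per animal with a scorer
factor assigned at random; repeated records per scorer are supported by
the design-matrix builder but not emitted by default. The truth record
(QTL indices, effects, breeding values, fixed parts, residuals)
reproduces the phenotype exactly when summed — a machine-precision
generative identity used in tests.

What the generator does not emulate: pedigree/family structure beyond
the two-pool design, X-dosage differences (X is treated as autosomal),
genotyping-intensity artifacts, and trait-specific score distributions.
Passing tests therefore show the statistical machinery is correct under
a known LD architecture, not that any particular field dataset meets
the model's assumptions.

## Intermediate-optimum traits

Score traits whose optimum is the scale midpoint are split into folded
deviations: `high = max(score − optimum, 0)`,
`low = max(optimum − score, 0)`. The recoding is reversible
(`high − low + optimum` recovers the score), at most one side is
positive per animal, and each side is analyzed as its own trait.

## Problem sizes used by the test suite

The suite works at sizes chosen to make every stage measurable on a
single CPU: the enumeration oracle at K ∈ {3, 8}; QTL recovery on three
simulated replicates of the full design scale (n = 800, K = 2,000, 10
QTL, default 11,000-iteration chains), gated at a median of ≥ 8/10 true
QTL inside the top 15 merged regions across the replicates (normal
effect draws can contain near-zero effects no method recovers, so the
gate is on the median, not the minimum); bootstrap calibration on a
no-QTL dataset (n = 150, K = 250) with 50 disjoint windows × 100
replicates at shortened replicate chains (600 iterations), where the
null p-values are uniform within KS distance 0.2.

## Known limitations

* Single-chain inference by default; a two-chain model-frequency
  agreement check is a diagnostic the user runs, not a gate.
* The sampler is O(nK) per sweep; it is comfortable at tens of
  thousands of SNPs and hundreds of animals, but it is not engineered
  for biobank scale.
* Haplotype phasing and block discovery are inputs (the simulator
  provides truth phase); no EM/HMM phasing is included.
* PFP assumes a single, externally supplied power value for all tested
  windows.
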