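# Methods

## The inference problem

Two sister species ("coll" and "pied" in the code, after the collared and
pied flycatcher) diverged from a common ancestral population and may have
exchanged migrants during different epochs.  Given biallelic genotypes at
a few hundred short, effectively unlinked noncoding loci — each observed
through a per-individual, per-site callability mask derived from sequencing
coverage — the task is to choose among candidate divergence histories and
to estimate the parameters of the winning history.  Likelihoods are
intractable at this scale, so everything runs through simulation-based
(ABC) machinery.

## Demographic models and priors

Sixteen models: {isolation, constant migration, recent migration, ancient
migration, recent+ancient migration} × {constant size, exponential size
change since the last glacial maximum (LGM), exponential size change since
the split}, plus a recent-unidirectional-migration variant (RUMASC).
Migration follows the backwards ms convention (m_ij = fraction of
population i made of migrants from j per generation; scaled M = 4N₀m,
N₀ = 10⁴).  Size change is parameterised by the ratio x of the size at the
onset of change to the current size, with an exponential trajectory
N(t) = N_current · x^(t/onset) between onset and present; x = 1 exactly
reduces to the constant-size model, making nested models identical by
construction.

Priors are uniform, log₁₀ for sizes, size ratios and M, linear for times
and per-site rates.  The default bounds are the study's published
ranges for the recent-migration/ancient-size-change (RMASC) model;
scenarios whose epoch parameters have no published table reuse those
bounds, except the ancient-migration epoch boundary Tm_anc ~ U(25 000,
500 000) generations, placed beyond the recent-migration range so that
recent+ancient models always contain an isolation gap.  The Gamma shape α
for per-locus rate heterogeneity has prior U(1, 5) (its printed bounds are
corrupted in the source PDF) and is treated as a nuisance parameter: drawn
per dataset, never estimated.

Corners of the joint prior in which an epoch would extend past the split
(e.g. recent migration switched on 25 kya with a split 10 kya) are
rejected and redrawn, so the effective joint prior is the uniform prior
truncated to self-consistent histories.  The same truncated prior is used
for reference tables, pseudo-observed truths and posterior grids, so the
truncation cannot bias calibration.  For the *RSC models this also
truncates T_split above the LGM onset.

The LGM onset is a scaling constant (21 000 generations ≈ 21 ky at the
1 yr generation time used throughout), configurable via
`ScalingConvention`.

## Simulation

Each locus is an independent neutral coalescent sample (msprime, Hudson
model) with recombination, 10 diploid individuals per species, and
infinite-sites binary mutations on a continuous genome — the ms-family
setup.  Per-locus mutation and recombination rates are
Gamma(α, α/mean)-distributed; the recombination mean is the locus's local
rate estimate rescaled by the dataset-level draw relative to the
genome-wide mean 5.3×10⁻⁸, preserving the relative recombination
landscape.

Reference tables need hundreds of thousands of tiny loci, and the public
`sim_ancestry` entry point spends most of its time in per-call Python
setup.  The locus engine therefore builds the low-level simulator directly
from cached, pre-converted demography ingredients and small allocation
blocks; with the same seed its output is byte-identical to the public API
(asserted in the test suite), at roughly five times the throughput.  If
the private interface disappears in a future msprime, the engine falls
back to the public path automatically.

Rows of a reference table are seeded by counter-based splitting
(SeedSequence spawn keys (model, row, attempt)), so any row can be
regenerated in isolation and parallel or resumed runs produce identical
content.  A row whose dataset has no computable statistics (for example no
segregating sites anywhere) is logged and redrawn with a fresh attempt
key; this discards a vanishing fraction of the lowest-diversity prior
corner, the same datasets on which every statistic the pipeline uses would
be undefined.

## Missing data: mask transplant and haploidization

The observed-data filter is: a genotype call needs ≥3 reads; a site is
assayable for a species if ≥7 of its 10 individuals are callable; a locus
is kept only if ≤30% of its sites fail the joint (both-species) rule.
Simulated data are pushed through the *same* masks: each individual×site
cell flagged missing loses both alleles, then each remaining diploid
genotype is collapsed to one uniformly chosen allele (haploidization — the
guard against miscalled heterozygotes at 5× coverage).  Observed and
simulated data share one code path, so any bias the filter induces
affects both sides of the ABC comparison identically; this
mask-transplant symmetry is the load-bearing design decision of the whole
pipeline.

The synthetic coverage model draws per-cell depths from a negative
binomial with mean 5 and variance mean·(1 + dispersion), dispersion 0.5
(shape = mean/dispersion = 10).  This over-dispersion level reproduces the
study's reported ≈80% jointly callable sites under the 3-read/7-individual
filter; the locus-level 30% rule then rejects (not edits) failing loci.
"Locus missing fraction" is the fraction of sites failing the joint
assayability rule, matching the study's site-level framing.  What the
generator does not emulate: base-calling error, mapping bias, linked-site
correlation in coverage, or inter-locus spacing on a physical genome
(synthetic loci are independent by construction).  Tests passing on these
data therefore certify the statistical machinery, not robustness to
artefacts of real sequencing.

## Summary statistics

Per locus: nucleotide diversity π per species and pooled (unbiased
per-site heterozygosity 2p̂q̂·n/(n−1) with the per-site called sample size
n, divided by the number of assayable sites including monomorphic ones);
Tajima's D per species (constants at the per-locus modal called sample
size; undefined below modal size 4 or without segregating assayable
sites); Hudson's F_ST = 1 − H_w/H_b with within/between heterozygosities
summed over sites before the ratio (ratio of averages — more stable on
sparse loci than averaging per-site ratios).  Dataset-level vector: mean
and sample variance (n−1) across loci of each statistic, plus the
proportions of shared, fixed and private SNPs pooled over all jointly
assayable SNP sites ("fixed" = monomorphic for different alleles in these
samples).  Loci where a statistic is undefined are excluded from that
statistic's mean/variance with a logged count.  The 16-entry vector order
is versioned; observed and simulated vectors must carry the same manifest
version.

Pooled π is computed on the combined 20-haplotype sample at jointly
assayable sites (the alternative — averaging the two species' values —
is a one-liner on the per-locus output if wanted).

## Estimation (retention + ABC-GLM)

Statistics are standardised and projected by partial least squares (PLS)
fitted on the full reference table against the estimation-scale
parameters; the number of components is chosen from cross-validated RMSEP
curves (`choose_components`).  Euclidean distance in PLS space ranks the
table; the nearest `count` rows are retained (boundary ties broken by row
seed, making retention invariant to table row order).

The GLM s = c₀ + Cθ + ε is fitted by OLS *in the PLS component space* —
the same low-dimensional statistics used for retention.  (Fitting it on
all 16 raw statistics demonstrably undercovers: a 16-dimensional Gaussian
with a covariance estimated from a few hundred retained rows is
overconfident.)  The posterior of parameter j on a regular grid over its
prior support is

  p(θ_j | s_obs) ∝ [ mean over retained draws i of
      N(s_obs; c₀ + Cθ_i with θ_ij→g, Σ) ] × π_trunc(g)

where π_trunc is the truncated prior — the smoothed histogram
(Silverman-bandwidth Gaussian kernel) of the retained draws of θ_j.  The
final marginal is smoothed with a one-grid-step Gaussian kernel with
*reflection* at the prior bounds, so that density at the bounds is not
artificially depressed.  Grid default 512 cells.  The residual covariance
is ridged by 10⁻⁸·trace/dim when its condition number exceeds 10¹²
(logged).  Mode = argmax cell; HPDIs are the bounding interval of the
smallest cell set holding the target mass, flagged when that set is
non-contiguous.

This nuisance-integration (averaging over retained draws) is one
defensible reading of the GLM adjustment used by ABC toolkits; it is
validated here by self-consistency — noiseless-linear collapse to truth,
the C = 0 limit returning the truncated prior, a conjugate-normal oracle
(KL < 10⁻³), and end-to-end coverage — not by bit-for-bit agreement with
any external implementation.

The model-fit P-value is the fraction of retained simulations whose
statistics are less likely than the observation under the fitted GLM
(likelihood = the same retained-average Gaussian).  It is exactly uniform
under the true model in the weak-retention limit; at 2.5% retention it is
conservative (biased toward 1, never toward false rejection), because the
observation sits at the centre of its own retained neighbourhood.  Its
job — flagging models that cannot produce data like the observation with
P ≈ 0 — is unaffected.

## Model choice

Marginal densities (retained-average GLM likelihood of the observation)
are computed per model in a shared statistic space: untransformed
statistics with one member of each pair correlated above |r| = 0.95 on
the reference table greedily removed (earlier statistic in the manifest
wins).  Retention counts are forced equal across models so Bayes factors
are comparable.  Posterior probabilities assume equal model priors.  The
hierarchical procedure compares models within each migration scenario,
then the scenario winners against each other; models whose fit P-value
falls below 0.01 are inadmissible.  Robustness modes: flat comparison of
all admissible models, the alternative nesting by size dynamics, and
re-runs with alternative ("sub-optimal") prior ranges for the focal model.
Power = probability that the true model wins by Bayes factor on
pseudo-observed data, estimated from seeded confusion matrices.

## Validation

For each pseudo-observed dataset (truth drawn from the priors), the
posterior CDF at the truth — computed from the same smoothed grid used
for HPDIs — yields one quantile per parameter; uniformity is tested by
Kolmogorov–Smirnov with Bonferroni correction across the model's
parameters.  Because an estimator that returns the prior is perfectly
calibrated yet useless, coverage is paired with the per-parameter R² of
parameters regressed on the PLS components (≤0.10 flagged low-power) and
the RMSE of the posterior mode on the estimation scale.

## Problem sizes

The package defaults mirror the study conditions (267 loci × 2 000 bp,
10 + 10 diploid individuals, 5× mean coverage); the full pipeline is
exercised at a desk scale chosen to keep a laptop run comfortable — the
test suite at 20 loci × 500 bp with 2×10⁴ reference simulations, 500
retained, 3 PLS components and 100 pseudo-observed coverage runs; the
acceptance script at 12 000 simulations, 300 retained and 60 coverage
runs — alongside study-scale runs of the cheap components (mask
generation, single-dataset simulation and statistics).

## Known limitations

- The GLM is local-linear; strongly curved parameter–statistic relations
  (a split time spanning two decades on a linear prior) keep a residual
  undercoverage that retention size does not remove.  The coverage tests
  report it rather than hide it.
- No linkage-disequilibrium statistics; loci are treated as exchangeable.
- Bayes factors inherit the marginal-density estimator's sensitivity to
  prior ranges; the prior-sensitivity rerun is the guard, not a fix.
- F_ST is Hudson's 1 − H_w/H_b (ratio of averages); published values
  computed under other F_ST conventions are not directly comparable.
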