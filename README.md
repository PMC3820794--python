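# divabc

Approximate Bayesian Computation (ABC) inference of the divergence history
of two closely related species — modelled on the collared flycatcher /
pied flycatcher system — from a few hundred short noncoding loci with
realistic, coverage-driven missing data.

## Who this is for

Population geneticists who want a tested, end-to-end reference
implementation of the classic "full ABC" divergence pipeline: coalescent
simulation under a family of isolation-with-migration models, summary
statistics that honour per-individual callability masks, supervised (PLS)
dimension reduction, GLM post-sampling adjustment, Bayes-factor model
choice, and the calibration battery (posterior-quantile coverage, R²,
RMSE, power) that tells you whether any of it can be trusted.  The raw
study data are not distributable, so a first-class synthetic-data module
generates study-shaped datasets with known truth; every code path that
touches "observed" data is the same one that touches simulated data.

## The model family

Sixteen two-population histories: five gene-flow scenarios — isolation
(I), constant migration (CM), recent migration (RM, after the last glacial
maximum), ancient migration (AM), recent+ancient with an isolation gap
(RAM) — crossed with three population-size dynamics — constant (CS),
exponential change since the LGM (RSC), exponential change since the split
(ASC) — plus RUMASC (recent unidirectional migration, pied→collared, with
ancient size change).  Parameters follow the ms convention: sizes N/N₀,
times T/4N₀, migration M = 4N₀·m_ij with m_ij the fraction of population
*i* replaced by migrants from *j* per generation, N₀ = 10⁴.  Priors are
uniform, mostly on a log₁₀ scale.

Estimation is ABC-GLM: from a reference table of simulated
(θ, s) pairs, the simulations nearest the observation in PLS space are
retained; an ordinary least-squares fit s = c₀ + Cθ + ε on the retained
rows gives a Gaussian likelihood N(s_obs; c₀ + Cθ, Σ), and the posterior
of each parameter on its prior grid is the retained-average likelihood
times the truncated prior.  Model choice compares retained-average
marginal densities (Bayes factors) on decorrelated untransformed
statistics, hierarchically within and then across scenarios.

## Worked example

Generate a synthetic "observed" dataset with known truth, build a small
reference table, and estimate under the true model:

```bash
divabc synth --model ICS --loci 20 --length 500 --seed 5 --outdir obs/
divabc simulate --model ICS --n-sims 4000 --seed 6 \
    --masks obs/masks.rle.txt --out table.tsv
divabc estimate --table table.tsv --stats obs/observed_stats.tsv \
    --model ICS --count 100 --components 3 --outdir est/
```

The estimate step prints (this exact run):

```
parameter         mode   hpdi50_low  hpdi50_high   hpdi90_low  hpdi90_high ...
   N_coll 5.711426e+00 5.516602e+00 5.868164e+00 5.291016e+00 6.000000e+00
   N_pied 5.007031e+00 4.857813e+00 5.154687e+00 4.556250e+00 5.200000e+00
    N_anc 4.853027e+00 4.699219e+00 5.021484e+00 4.500000e+00 5.252930e+00
  T_split 3.667480e+05 2.304297e+05 4.740625e+05 1.221484e+05 7.080273e+05
       mu 1.003906e-09 1.000000e-09 2.398438e-09 1.000000e-09 4.203125e-09
        r 7.805371e-08 2.613672e-08 9.419922e-08 1.434180e-08 1.000000e-07
```

Sizes are reported on their log₁₀ prior scale (the estimation scale),
times in years, rates per site per generation.  The mode is the peak of
the smoothed grid posterior; HPDI columns bound the 50/90/95%
highest-posterior-density intervals.  The truth recorded in
`obs/truth.json` for this seed is log₁₀ N_coll = 5.708, log₁₀ N_pied =
5.046, T_split = 293 ky, μ = 1.22×10⁻⁹: the two well-identified sizes are
recovered almost exactly, the split time sits inside its 50% interval,
and the weakly identified recombination rate stays close to its prior.
The companion `fit_ICS.json` holds the log marginal density and the
model-fit P-value (the fraction of retained simulations less likely than
the observation — near zero means the model cannot produce data like
yours; here 1.0), and `density_ICS.tsv` the full grids.

`divabc choose` ranks several models by posterior probability, and
`divabc validate` runs the coverage battery for one model against a
reference table.

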