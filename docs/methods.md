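# Methods

## Models

Pathology burden `u_i(t)` (arbitrary load units; time in months) on `N`
brain regions evolves on a directed structural connectome `W`, where
`W[i, j]` is the projection strength from region `j` to region `i`.
Transport uses the out-degree graph Laplacian

    L = -W + diag(out-strengths),      out-strength_i = sum_k W[k, i],

whose zero column sums make pure diffusion conserve total burden.  Three
nested models are implemented:

- **DIFF** `du/dt = -rho L u` — passive spread at rate `rho` (per month).
- **DIFF-R** adds Fisher–KPP logistic growth `alpha u_i (beta_i - u_i)`
  with a global aggregation timescale `alpha` and a regional carrying
  capacity (*rise parameter*) `beta_i`.
- **DIFF-RF** additionally consumes the carrying capacity at a regional
  *fall rate* `gamma_i >= 0`: `dbeta_i/dt = -gamma_i u_i`.  `beta_i` then
  denotes the initial condition `beta_i(0)`.  `beta_i(t)` may go negative;
  that is what drives burden back toward zero and produces rise-and-fall
  trajectories.

Transport direction is a model choice: anterograde (Laplacian of `W`),
retrograde (`W^T`), bidirectional (both operators, each with its own
rate), or a spatial control built from a symmetric distance kernel on
region centroids (inverse distance by default; an exponential kernel
`exp(-d/lambda)` is available behind the `length_scale` option, since the
exact kernel used with real data is not standardised).

The logistic term is the large-healthy-pool reduction of the heterodimer
model of prion-like conversion; `simulate_heterodimer` exists so the
reduction can be verified numerically (the reduction requires the healthy
pool to relax fast, `k1 >> alpha*beta`, and production near the conversion
threshold).

Integration uses LSODA (adaptive step, stiffness-switching) with a
numba-compiled right-hand side; defaults `rtol=1e-6`, `atol=1e-9` keep
solver error far below observation noise while staying fast.  Negative
excursions are never clipped (the equations are smooth and the likelihood
is evaluated on the raw solution); excursions beyond `-10*atol` are logged.

## Observation model and priors

Replicate-level observations follow `y_ijt ~ Normal(u_i(t), sigma^2)` with
one shared noise scale.  Default priors: half-normals `N+(0, 0.1)` on the
rate parameters (`rho`, `alpha`, DIFF-RF `beta_i`, `gamma_i`), `N(0, 1)`
on DIFF-R's `beta_i` (which may be negative), `N+(0, 0.1)` on `sigma`,
`N+(0, 1)` on the seed initial value `u0` — except DIFF, which gets
`rho ~ N+(50, 10)` and `u0 ~ N+(0, 50)`: mass-conserving diffusion must
start with all the burden it will ever distribute, so its initial-value
prior is deliberately much wider.

`default_priors(..., scale=...)` exposes the half-normal scale of the rate
block.  The 0.1 default is the canonical weakly-informative choice for
fitting data whose parameter scales are unknown.  Parameter-recovery
studies instead pass a scale commensurate with the planted truth
(`scale=1`): a recovery test is a check of the likelihood, solver and
sampler, and deliberately mis-scaled priors would turn it into a test of
shrinkage instead.

An `empirical_prior` helper moment-matches a truncated normal to posterior
draws, supporting the carry-forward design in which one experiment's
global-parameter posteriors become the priors of the next.

## Inference

Positivity-constrained parameters are log-transformed.  Fitting proceeds
in three stages:

1. **Mode finding** — staged multi-start L-BFGS: a data-informed start
   (per-region peak burden as the carrying-capacity initialisation, small
   fall rates where the final burden sits well below the peak) and the
   prior means; global parameters are optimised first with the regional
   block frozen, then all parameters jointly.
2. **Laplace preconditioning** — a central finite-difference Hessian at
   the mode defines whitened coordinates in which the posterior is
   approximately isotropic.
3. **Ensemble MCMC** — an affine-invariant ensemble sampler (emcee) with
   differential-evolution moves runs in the whitened space, initialised at
   the Laplace approximation itself (unit-scale Gaussian in whitened
   coordinates, with stuck walkers shrunk toward the mode) so the ensemble
   already spans the posterior's soft directions.  `chains`, `warmup` and
   `samples` follow the usual MCMC convention (defaults 4/1000/1000);
   walkers are partitioned into `chains` groups whose post-warmup
   trajectories form pseudo-chains for the split Gelman–Rubin statistic,
   and `chains*samples` draws are retained.  `target_accept` applies to
   gradient-based (NUTS-style) samplers and is accepted for interface
   parity; the ensemble sampler ignores it.

Pointwise log-likelihoods are recomputed for every retained draw and
stored; they feed WAIC and the paired WAIC standard errors.  The MAP
estimate is the retained draw with the highest log-prior + log-likelihood,
which keeps it reproducible and free of a second optimiser pass.

**Posterior-update filter.**  A parameter counts as *updated* when a
one-sample Kolmogorov–Smirnov test of its pooled posterior draws against
the analytic prior CDF gives p < 0.001.  Because MCMC draws are
autocorrelated, the KS statistic is computed on all pooled draws but its
p-value is evaluated at the parameter's effective sample size (arviz ESS);
at the nominal draw count the test is anti-conservative and flags
parameters the data never touched.  Downstream biological analyses use
only regions whose `beta_i` and `gamma_i` both updated and whose
posterior-mean `beta_i` is positive.

**A note on identifiability.**  At desk scale the DIFF-RF likelihood has a
soft ridge trading the global `alpha` against the regional `beta_i`
(roughly preserving the products `alpha*beta_i`): trajectories constrain
the rise *rate* tightly but the factor split only weakly unless the grid
resolves the early rise curvature.  Posterior marginals along such ridges
concentrate where the ridge has the most conditional volume, so
single-parameter intervals for `alpha` can be misleadingly tight when the
dynamics are slow relative to the sampling grid.  The synthetic defaults
place the rise time (~`1/(alpha*beta)`) inside the densely sampled early
window, where the factorisation is identified.

## Model comparison

WAIC is `-2 (lppd - p_waic)` with `p_waic` the summed pointwise variance
(ddof=1) of the log-likelihood over draws; pointwise contributions are
kept so differences between models carry a paired standard error
(`sqrt(n * var(d_i))`), and models within 2 paired SEs of the best are
flagged as overlapping.  AIC/BIC are evaluated at the MAP draw; free
parameter counts are 3 for DIFF, 4+N for DIFF-R, 4+2N for DIFF-RF (plus
one for the second bidirectional rate).  Predictive agreement uses R^2
from regression through the origin — algebraically the squared uncentred
correlation `(Sxy)^2/(Sxx Syy)`, reported pooled, per timepoint, and in
log10 space with non-positive pairs dropped and counted.  Out-of-sample
evaluation refits without the final timepoint and scores the held-out
observations with the same statistic.  Null models rewire the connectome
(weight-multiset shuffle by default; a degree-preserving double-edge-swap
variant behind a flag) or relocate the seed set uniformly among non-seed
regions.

## Vulnerability axis

Over selected regions, each gene's expression is regressed (OLS, with
intercept — expression is not centred) on the standardized `z(beta)`,
`z(gamma)`.  PCA on the mean-centred — not variance-scaled, since both
coordinates are coefficients in the same units — gene-coefficient cloud
gives PC1 loadings `(c1, c2)`, sign-fixed so `c2 >= 0`, and the regional
scalar `eta = c1 z(beta) + c2 z(gamma)`.  Genes ranked by Pearson
correlation with `eta` feed pre-ranked GSEA: weighted Kolmogorov–Smirnov
running sum (hit increments `|r|^p / sum_hits |r|^p`, miss decrements
`1/(N - N_h)`), ES the extremum of larger magnitude (ties toward the
positive side), gene-label permutation null, NES = ES / mean |null ES| of
matching sign, add-one permutation p-values, BH FDR across sets.  Pathway
categories (metabolism, protein homeostasis, synaptic function,
neurodegenerative disease, other) come from an editable keyword table;
category over-representation uses two-sided Fisher tests with BH
correction and Haldane-corrected log2 odds ratios.  Axes from two datasets
are compared by loading cosine/angle and by gene-level correlation of the
per-gene axis correlations (Pearson r, with-intercept OLS slope, sign
agreement) over shared genes.

## Cell-type composition

Regional counts per neurotransmitter class distribute each annotated
cluster's cells over structures by its spatial frequencies, walking
contributions up a child-to-parent ontology until a target region is hit
(cells reaching a root outside the target set are dropped with a warning;
totals are otherwise conserved).  Fractions are closed to the simplex and
CLR-transformed; zeros are handled by multiplicative replacement with a
pseudocount of half the smallest nonzero fraction followed by
renormalisation (the literature default; configurable, as is the
inclusion of non-neuronal classes in the closure).  Associations with
`eta` are Spearman correlations with a hemisphere-paired permutation null:
predictors are shared by the two hemispheres of a region, so permutations
shuffle values across regions with both hemispheres moving together;
two-sided p-values use the add-one estimator over 10,000 permutations and
BH correction across classes.  The monoaminergic score is the mean CLR
component of the dopaminergic, noradrenergic, serotonergic and
histaminergic classes.

## Synthetic studies

`make_study` derives every component from one master seed (bit-for-bit
reproducible):

- **Connectome** — two mirrored hemispheres (default 20 regions each)
  sharing one intra-hemispheric wiring diagram (edge density 0.25,
  log-normal weights), sparser/weaker commissural edges, weak connectivity
  guaranteed constructively, and mirrored 3-D centroids.  `W` is
  normalised to unit mean out-strength so `rho` is the sole diffusion
  timescale, as with normalised tracer-derived matrices.
- **Pathology** — one ipsilateral seed region (a three-seed variant mimics
  hippocampal designs) observed at 0.1/0.2/0.3/0.5/1/3/6/9 months with 3
  replicates and i.i.d. Gaussian noise, kept negative when it falls below
  zero.  True parameters: `rho ~ U(0.3, 0.7)`, `alpha ~ U(1.8, 2.4)`, 60%
  of base regions grow (`beta ~ U(0.4, 1.1)`, shared by hemisphere mirror
  pairs), 60% of those fall (`gamma ~ U(0.1, 0.9)`); non-falling regions
  get a small positive rate (`U(0.005, 0.03)`) because exact zeros lie
  outside the half-normal support.  The rise time `1/(alpha*beta)` of
  0.4–1.4 months thereby falls inside the densely sampled 0.1–1 month
  window, which is what makes the `alpha`/`beta` factorisation (and not
  just the product) identifiable — with slower dynamics the profile
  likelihood of `alpha` is flat over a wide range.  Noise sigma defaults
  to 0.01, about 1–3% of peak burden — the regime in which
  replicate-averaged regional load curves are quantitatively
  interpretable; larger noise mainly shrinks the set of filter-passing
  regions and widens the soft ridge.
- **Expression** — per-gene coefficient pairs drawn from a 2-D Gaussian
  elongated (anisotropy 10) along a planted unit axis, by default the
  direction (-0.37, 0.93); expression = intercept + a z(beta) + b z(gamma)
  + noise, generated per base region and duplicated across hemispheres.
- **Cell types** — Dirichlet compositions whose monoaminergic
  concentrations scale with `exp(coupling * standardized eta)`
  (coupling 3 by default; 0 gives the exchangeable null).
- **Gene sets** — random sets plus planted sets sampling genes
  preferentially from one tail of the axis-correlation ranking.

What the generator does *not* emulate: spatial autocorrelation of
expression, region-size-dependent noise, the increase of replicate
variance at late timepoints, staining/registration artefacts, and any
realistic gene–gene correlation structure.  Passing recovery tests
therefore demonstrates that the estimation machinery is correct under the
model's own assumptions, not that the models are adequate for real
histology.

## Problem sizes

Default test and acceptance problem sizes — 16–40 regions, 8 timepoints,
3 replicates, a few hundred to 2,000 genes, sampler settings of a few
hundred warmup steps and roughly a thousand retained draws — are chosen so
the full pipeline runs in minutes on one CPU while every qualitative
conclusion (model ordering, null-model ordering, axis recovery,
composition association) is already stable at that scale.

## Known limitations

- The ensemble sampler explores ridge-shaped posteriors more slowly than a
  well-tuned gradient-based sampler would; the Laplace preconditioning
  mitigates but does not remove this.
- Split-R-hat on walker groups of a single interacting ensemble is a
  weaker diagnostic than independent chains.
- AIC/BIC at the MAP draw (rather than a separately optimised MLE) can be
  slightly conservative.
- The degree-preserving rewiring uses a fixed swap budget (10x edge
  count), not an exact uniform sample from the degree-constrained graph
  ensemble.
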