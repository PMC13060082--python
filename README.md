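# risefall

Network dynamical modelling of prion-like protein pathology, for
researchers who quantify misfolded-protein burden (e.g. α-synuclein after
preformed-fibril seeding) across anatomically defined brain regions over
time and want to ask: *how* does pathology spread and evolve, and *which
regional biology* shapes its trajectory?

## The models

Regional burden `u_i(t)` evolves on the directed structural connectome
`W` (`W[i,j]` = projection strength j → i) through the out-degree graph
Laplacian `L = -W + diag(out-strengths)`:

| model   | dynamics                                                | regional parameters |
|---------|---------------------------------------------------------|---------------------|
| DIFF    | `u̇ = -ρ L u`                                            | none |
| DIFF-R  | `u̇ = -ρ L u + α u (β - u)`                               | rise `β_i` |
| DIFF-RF | `u̇ = -ρ L u + α u (β(t) - u)`, `β̇_i = -γ_i u_i`          | rise `β_i`, fall `γ_i ≥ 0` |

DIFF spreads passively; DIFF-R adds Fisher–KPP logistic growth toward a
regional carrying capacity; DIFF-RF lets accumulated burden consume that
capacity, producing the rise-and-fall trajectories seen in longitudinal
histology.  Transport can be retrograde (`Wᵀ`, the default), anterograde,
bidirectional, or a Euclidean-distance control.

Parameters are estimated by Bayesian MCMC under a Gaussian observation
model `y_ijt ~ N(u_i(t), σ²)`, models are compared with WAIC (plus AIC /
BIC / MSE and origin-constrained R²), and the inferred regional `(β, γ)`
landscape is related to gene expression and cell-type composition: per-gene
regressions on `z(β), z(γ)`, PCA of the coefficient cloud yielding the
vulnerability axis `η = c₁ z(β) + c₂ z(γ)`, pre-ranked GSEA along gene–η
correlations, and CLR-compositional Spearman tests with hemisphere-paired
permutation nulls.

## Worked example

Everything below runs on a synthetic study (no downloads); `make_study`
generates a mirrored two-hemisphere connectome, rise-and-fall pathology
with replicate noise, expression with a planted gene-coefficient axis, and
axis-coupled cell-type compositions from one master seed.

```python
from risefall import make_study
from risefall.model import (PathologySpreadModel, VulnerabilityAxisModel,
                            CompositionAssociation)

study = make_study(rng_seed=7, n_regions_per_hemisphere=8, n_genes=500)
seeds = [study.connectome.region_ids[i] for i in study.true_params.seeds]

model = PathologySpreadModel(study.observations, study.connectome,
                             kind="diff_rf", transport="retrograde",
                             seeds=seeds)
res = model.fit(chains=4, warmup=500, samples=250, rng_seed=1)
print(res.summary())
```

```
PathologySpreadModel DIFF-RF | transport=retrograde | regions=16 | observations=384
chains=4 warmup=500 samples=250 walkers=74
max R-hat = 1.0508 (1 parameter(s) above 1.05)
WAIC = -2393.56 (p_waic = 21.6), AIC = -2359.73, BIC = -2217.51, MSE = 1.038e-04

parameter             mean          sd        2.5%       97.5%    R-hat
rho                 0.3324      0.0067      0.3204      0.3457    1.025
alpha               2.1772      0.0311      2.1259      2.2462    1.034
u0                  0.5036      0.0040      0.4961      0.5111    1.051
sigma               0.0105      0.0003      0.0097      0.0111    1.025
... plus 32 regional parameters (see regional_posterior_means())
```

`rho` is the transport rate (per month) along retrograde connections,
`alpha` the aggregation timescale, `u0` the seeded initial burden and
`sigma` the replicate noise — all tightly recovered (this study was
generated with rho = 0.336, alpha = 2.10, u0 = 0.5, sigma = 0.01).
Downstream, the vulnerability axis:

```python
vr = VulnerabilityAxisModel.from_results(res, study.expression).fit()
print(vr.summary())
```

```
VulnerabilityAxis over 16 selected regions, 500 genes
PC1 loadings (c1, c2) = (-0.351, +0.936), variance explained = 89.5%
eta = - 0.351 z(beta) + 0.936 z(gamma)
```

The study planted the axis direction (-0.37, 0.93); PC1 of the fitted
gene-coefficient cloud recovers it to a cosine of 0.9998, with variance
explained in the high-anisotropy regime.  Cell-type composition:

```python
base = [r.rsplit("_", 1)[0] for r in vr.regions]
ca = CompositionAssociation(study.celltypes, vr.axis.eta, base)
print(ca.fit(n_perm=2000, rng_seed=2).summary())
```

```
Cell-type composition vs vulnerability axis (Spearman, hemisphere-paired permutation)
                  rho      p      q
predictor
glutamatergic -0.9349 0.0010 0.0070
gabaergic     -0.8403 0.0105 0.0336
dopaminergic   0.7574 0.0230 0.0336
noradrenergic  0.6509 0.0825 0.0962
serotonergic   0.8047 0.0145 0.0336
histaminergic  0.4024 0.3213 0.3213
other         -0.7456 0.0240 0.0336
monoaminergic score: rho = 0.899, p = 0.0010
```

Regions high on the axis (stronger fall, weaker rise) carry larger
monoaminergic fractions — the planted coupling, detected at the
permutation floor p = 1/(1+2000)·2 ≈ 0.001.

A command-line pipeline wraps the same library
(`risefall synth | fit | compare | nulls | loto | axis | gsea | celltype |
report`); see `risefall --help`.

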