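# symptomnet

Network analysis of ordinal symptom data with two complementary estimators:

1. **An undirected Gaussian graphical model (GGM).** Polychoric correlations
   among the ordinal items are regularized with the graphical LASSO; the
   penalty λ is tuned by the Extended Bayesian Information Criterion
   (EBIC, hyperparameter γ, default 0.5). Edges are regularized partial
   correlations. The package computes betweenness, closeness and strength
   centrality (raw and z-scored), bootstrap 95% confidence intervals for
   every edge weight, a bootstrapped node-pair centrality difference test,
   the case-dropping **CS-coefficient** for centrality stability, and
   restricted-variance diagnostics (SD-vs-strength and skewness-vs-strength
   correlations).
2. **A directed acyclic graph (DAG / Bayesian network).** Structure is
   learned by hill climbing on a linear-Gaussian BIC with random restarts,
   then stabilized by bootstrap model averaging: per edge, the fraction of
   bootstrap networks containing it (*strength*) and the fraction pointing
   the depicted way (*direction probability*). Edges are retained above the
   Scutari–Nagarajan statistically-driven threshold, and each retained edge
   is annotated with its BIC importance (score loss if removed).

The intended users are researchers modelling psychopathology (or any small
battery of ordinal ratings) as a network of interacting components — e.g. 17
posttraumatic stress symptoms rated 0–3 for ~180 participants. Because such
clinical datasets are rarely shareable, the package ships a synthetic-data
module that generates ordinal datasets with *known* ground truth (sparse
latent GGM or linear-Gaussian DAG, skewed marginals, injected missingness)
so every stage of the pipeline is testable end to end.

## The models in brief

For items assumed to discretize a latent multivariate normal, the GGM edge
weights are the off-diagonal entries of the standardized precision matrix:
`w_ij = -Θ_ij / sqrt(Θ_ii Θ_jj)`. The estimator maximizes

    log det Θ − tr(S Θ) − λ Σ_{i≠j} |Θ_ij|

over a descending λ path, where `S` is the polychoric correlation matrix,
and picks the λ minimizing `EBIC = −2ℓ(Θ) + E log n + 4 E γ log p` with `E`
the edge count. The DAG branch scores a graph `G` by
`Σ_i [max loglik(x_i | parents_i) − (k_i/2) log n]`, `k_i = |parents_i| + 2`,
and averages 10,000 (configurable) bootstrap structure searches.

## Worked example

```python
import symptomnet as sn

# a study-shaped synthetic dataset: 17 symptoms, n=179, 14 incomplete rows
ds, truth = sn.csa_ptsd_preset(seed=2)

res = sn.GaussianGraphicalModel(ds).fit()
print(res.summary())
```

```
Gaussian Graphical Model (polychoric + EBIC-glasso)
=======================================================
nodes:            17
observations:     179 (incomplete rows: 14)
pair policy:      pairwise
gamma (EBIC):     0.5
lambda selected:  0.0895
edges selected:   58 of 136

z-scored centrality (betweenness / closeness / strength):
  intrusion   +2.26   +1.32   +1.54
  dreams      -0.22   +0.15   +0.27
  ...
```

58 of the 136 possible edges survive regularization at the EBIC-selected
λ = 0.09; the z-scores say how many SDs each symptom's centrality sits above
or below the network average. The directed branch and the comparison:

```python
bres = sn.BayesianNetworkModel(ds, sn.SearchConfig(B=500, seed=1)).fit()
print(bres.summary())          # averaged DAG, edge strengths/directions/BIC

rep = sn.run_comparison(ds, search_cfg=sn.SearchConfig(B=500, seed=1))
print(rep)
# ComparisonReport(dag_edge_count=29, ggm_edge_count=59, shared_pair_count=28,
#                  mean_abs_weight_shared=0.167, ..., mean_abs_weight_ggm_only=0.083, ...)
```

The DAG is much sparser than the GGM, its edges are (almost) all also GGM
edges, and those shared pairs carry clearly larger absolute partial
correlations than the GGM-only pairs — the two methods agree about which
connections matter. Stability analyses hang off the results object:

```python
res.bootstrap_edges(B=1000, seed=0)   # per-edge 95% percentile CIs
res.cs_coefficient(seed=0)            # CS-coefficient per centrality metric
res.variance_diagnostics()            # SD/skewness vs strength correlations
```

A CS-coefficient below 0.25 means centrality orderings do not survive
dropping even a quarter of the sample and should not be interpreted.

There is also a thin CLI (`symptomnet simulate | ggm | dag | compare |
report`, with `--show-config` printing every default).

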