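# Methods

## Data model and harmonization

The unit of analysis is a participants × symptoms matrix of ordinal
severity codes. Two source scales are supported: an interviewer rating on
0–3 and a self-report questionnaire on 1–5. The questionnaire is mapped
onto the interview scale by 1→0, 2→1, 3→2 and {4,5}→3; the map collapses
the two most extreme questionnaire points, so it is many-to-one and has no
inverse at the top of the scale. After harmonization every dataset has
L = 4 levels. Missing cells are empty CSV cells or the token `NA` — never a
numeric sentinel, which could collide with a valid code. Listwise deletion
(used by the DAG branch, which requires complete rows) preserves row order;
the undirected branch keeps all rows and works pairwise by default, since
dropping a whole participant for one missing item wastes 16 valid ratings.

Descriptives use the n−1 SD and the adjusted Fisher–Pearson skewness
(`scipy.stats.skew(bias=False)`), the common default of spreadsheet and
statistics packages; constant columns are flagged degenerate rather than
silently given skewness 0.

## Synthetic data: what it emulates and what it does not

Real symptom datasets of this kind are rarely shareable, so the generator
is a first-class module. It emulates: 17 items on 4 levels, n ≈ 180, a
sparse latent dependence structure (either a latent-Gaussian GGM or a
linear-Gaussian DAG), right-skewed marginals for roughly half the items
(cut-points at the 70/85/95 latent percent points; symmetric items use
25/50/75), and a handful of rows with one missing cell each (14 of 179 in
the `csa_ptsd` preset, so listwise deletion leaves 165 — the shape of the
motivating study design). Ground-truth GGMs start from a precision matrix
with unit diagonal and −w on sampled edges; if the smallest eigenvalue
falls below 0.05 the diagonal is inflated, which records slightly shrunken
implied partials. Ground-truth DAGs draw edges in the upper triangle of a
random node permutation (acyclic by construction) with unit noise SDs.

What it does **not** emulate: real item-content correlations, instrument
effects (the optional source column is never used in estimation),
non-Gaussian latent dependence (only the Gaussian copula), or
missing-not-at-random patterns (injected missingness is uniform). Passing
recovery tests therefore demonstrates correctness of the estimators under
their own assumptions, not robustness to real clinical data pathologies.

A second preset, `weak_signal_preset`, keeps the same shape but uses edge
weights of 0.12–0.22 so that, at n = 179, centrality orderings are mostly
sampling noise. It is the regime used to demonstrate what the
case-dropping analysis looks like when centralities are *not*
interpretable.

## Polychoric correlations

Estimation is two-step: thresholds from the inverse-normal of each
variable's cumulative category proportions, then a 1-D profile-likelihood
maximization for each pair's latent correlation (bounded Brent on
[−0.999, 0.999], xatol 1e−7). Full joint ML buys little at p = 17 and
costs an order of magnitude in the bootstrap loops. Rectangle
probabilities use a vectorized Drezner–Wesolowsky/Genz bivariate normal
CDF, validated against scipy's integrator to ~5e−7 over the full
correlation range including ±0.999. Near-empty cells are floored at 1e−12
inside the log-likelihood (continuity handling; cells with zero observed
count contribute nothing regardless). Estimates are clipped to
|ρ| ≤ 0.999 so duplicated or perfectly concordant items cannot produce a
singular matrix.

Pairwise-complete estimation is the default (thresholds from each
variable's own margin, tables from rows complete on the pair); `listwise`
is used when parity with the complete-case DAG branch is wanted. An
indefinite pairwise assembly is projected to the nearest correlation
matrix (Higham alternating projections via statsmodels `corr_nearest`,
eigenvalue clipping as a fallback); the projection is recorded in the
output metadata because it changes the input to everything downstream.

## Regularized partial-correlation network

The graphical LASSO is solved by block coordinate descent (each column
update a lasso regression), compiled with numba and warm-started along a
descending log-spaced λ path — 100 points from λ_max (the largest absolute
off-diagonal correlation, where the network is exactly empty) down to
0.01·λ_max. Only off-diagonal precision entries are penalized, so λ = 0
reproduces S⁻¹ exactly. Solutions are verified against the KKT
stationarity conditions (residual < 1e−4 in tests); partial correlations
below 1e−10 are treated as structural zeros when counting edges.

λ is selected by EBIC with γ = 0.5 by default (γ = 0 is the plain BIC; the
closer γ is to 0.5 the sparser the selected model). Two evaluation modes
exist:

* **default** — the log-likelihood is evaluated at the penalized estimate
  itself, the convention of the R ecosystem this pipeline mirrors;
* **refit=True** — each candidate support along the path is refitted as a
  support-constrained (unpenalized) MLE and the EBIC evaluated there.

The distinction matters at large n: with the penalized likelihood, the
shrinkage of strong true edges makes smaller λ look better and the
selected model carries weak spurious edges (we measure false-discovery
proportions of 0.3–0.5 at n = 5000 even when the *exact* latent
correlation matrix is supplied). The refit mode recovers the true support
cleanly in most configurations and is the recommended setting when support
recovery, rather than regularized point estimation, is the goal. The
default remains no-refit for parity with the original pipeline.

## Centrality and stability

Shortest-path indices use edge length 1/|w|; strength is Σ|w|; closeness
is the inverse *sum* of distances (not the mean); betweenness counts
shortest-path membership over unordered pairs with equal fractional credit
for ties. Unreachable pairs contribute infinite distance and give the
affected nodes closeness 0, with a disconnection flag — a case the
original analyses never face but subsample re-estimates frequently do.
All three indices are validated against an exhaustive path-enumeration
oracle on networks up to p = 8. z-scores use the n−1 SD across nodes.

Bootstrap procedures re-run the *entire* pipeline (polychoric →
EBIC-glasso) per resample: 95% percentile CIs per edge; a node-pair
centrality difference test (significant when the 95% CI of the difference
excludes 0, no multiplicity correction, matching the source convention);
and the case-dropping CS-coefficient — the largest drop proportion at
which ≥ 95% of subsample-vs-full centrality correlations reach 0.70.
Defaults: drop grid {.10, .25, .40, .55, .70, .75}, 250 subsamples per
level, 10,000 edge-CI resamples (tests and the acceptance script use
desk-scale values: 25–50 subsamples per level, 500–1000 resamples, a
30-point λ path — sizes chosen so the full suite re-runs in minutes while
leaving the bootstrap distributions stable enough for the qualitative
claims being tested). Degenerate resamples (a constant column) are redrawn
up to a budget and counted. The restricted-variance diagnostics are plain
two-tailed Pearson correlations of SD and skewness against strength, with
t-based p on p−2 degrees of freedom.

## Bayesian network branch

Structure learning treats the 0–3 codes as metric — the same assumption
the GGM makes — and uses the linear-Gaussian node-wise BIC,
`Σ_i [loglik_i − (k_i/2) log n]` with `k_i = |parents| + 2` (coefficients,
intercept, residual variance); higher is better. All regressions reduce to
solves against one cached cross-product matrix, so a node score is O(k³)
regardless of n. The discrete multinomial score is a documented
alternative we do not implement; at 4 levels and n ≈ 165 its parameter
counts explode.

Hill climbing starts from the empty graph, takes the best strictly
improving add/delete/reverse move, and preserves acyclicity (reachability
by boolean matrix squaring). Candidate moves are visited in a *seeded
random order per climb*: with a score-equivalent Gaussian BIC the two
orientations of a Markov-equivalent pair tie exactly, and a fixed
enumeration order would resolve every such tie identically — bootstrap
direction probabilities would then report certainty (1.0) about directions
that are unidentifiable in principle. Randomized tie-breaking lets the
averaged direction probability sit near 0.5 for unidentifiable pairs while
remaining bit-reproducible under a fixed seed. Random restarts (default
10, 5 perturbation moves each) re-climb from a perturbed optimum;
per-resample climbs inside the bootstrap run without restarts
(`bootstrap_restarts = 0`), which keeps 10,000-resample runs tractable and
mirrors common model-averaging practice.

Averaging: per unordered pair, strength = fraction of bootstrap networks
containing the edge; direction counts are tallied among the containing
networks only (the standard model-averaging convention — the alternative,
counting over all networks, is noted as an open choice). Retention uses
the Scutari–Nagarajan threshold: t* minimizes the L1 distance between the
empirical strength CDF and the ideal two-point CDF with mass t at 0 and
1−t at 1 (computed in closed form as a segment-length weighted median, and
checked against a dense grid oracle); the cut-point is the t*-quantile of
the strengths, edges strictly above it retained (inclusively when t* = 0,
where the ideal CDF declares every edge significant). Orientation follows
the majority direction; an exact 50/50 split is broken by lexicographic
node-label order and flagged. If majority orientation creates a cycle —
possible since each bootstrap network is acyclic but their average need
not be — the cycle edge with the lowest direction probability is reversed
(once) or dropped, and every repair is logged. BIC edge importance is the
score loss when a retained edge is deleted, reported as a magnitude; it
drives edge thickness in one of the two renderings (the other uses
direction probability).

## Determinism

Every stochastic stage takes an explicit seed and uses its own
`numpy.random.Generator`; no global RNG state is touched. Two runs with
the same config hash produce byte-identical artifacts on one platform
(asserted in tests); across platforms, differences are confined to
floating-point tie regions of the discrete selections (edge in/out at the
EBIC boundary, hill-climbing move ties), which is why seeds, config hashes
and library versions are embedded in every output directory.

## Known limitations

* The GGM assumes the clinical phenomena underlying the ordinal ratings
  are metric and jointly Gaussian on the latent scale.
* The DAG branch cannot represent feedback loops; a low direction
  probability on a retained edge is the only visible trace of a possible
  2-cycle, and longer cycles leave none.
* Polychoric matrices from pairwise-complete data need not be positive
  semi-definite; the recorded projection is a repair, not a model.
* EBIC selection without refit over-selects at large n (quantified above);
  with n ≈ 179 and 136 candidate edges, *all* conclusions about individual
  edges and centralities should be read jointly with the stability report.
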