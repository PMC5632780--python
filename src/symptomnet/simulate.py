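"""Synthetic ordinal symptom data with known ground truth.

Two generating families mirror the two estimation branches:

* :class:`GroundTruthGGM` — a sparse latent Gaussian graphical model.  A
  precision matrix with unit diagonal and ``-w`` on sampled edges is made
  positive definite (diagonal inflation if needed); latent draws come from
  the implied multivariate normal.
* :class:`GroundTruthDAG` — a linear-Gaussian structural model over a random
  topological order; latents are simulated parent-first and standardized by
  their analytic marginal SD.

In both cases each latent variable is discretized by per-variable increasing
thresholds into ordinal codes ``0..L-1``.  Skewed marginals are produced by
placing the cut-points high in the latent distribution (e.g. at the 70/85/95
percent points), which concentrates mass in the lowest category.

The ``csa_ptsd`` preset emulates the shape of a 17-symptom posttraumatic
stress dataset: n = 179 adults, 4 ordinal levels, a sparse positive
dependence structure, a mix of symmetric and right-skewed items, and 14 rows
containing at least one missing value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import norm

from .datasets import SymptomDataset, SourceScale

PTSD_LABELS = [
    "intrusion", "dreams", "flash", "upset", "physior", "avoidth",
    "avoidact", "amnesia", "lossint", "distant", "numb", "future",
    "sleep", "anger", "concen", "hyper", "startle",
]

#: cut-points giving roughly symmetric 4-level marginals
SYMMETRIC_CUTS = norm.ppf([0.25, 0.50, 0.75])
#: cut-points giving strongly right-skewed marginals
SKEWED_CUTS = norm.ppf([0.70, 0.85, 0.95])


@dataclass
class GroundTruthGGM:
    """Latent Gaussian graphical model: precision matrix + discretization cuts."""

    precision: np.ndarray
    thresholds: list[np.ndarray]
    seed: int | None = None

    def __post_init__(self) -> None:
        P = np.asarray(self.precision, float)
        if not np.allclose(P, P.T):
            raise ValueError("precision must be symmetric")
        if np.linalg.eigvalsh(P).min() <= 0:
            raise ValueError("precision must be positive definite")
        for cuts in self.thresholds:
            if np.any(np.diff(cuts) <= 0):
                raise ValueError("thresholds must be strictly increasing")

    @property
    def p(self) -> int:
        return self.precision.shape[0]

    @property
    def partials(self) -> np.ndarray:
        """Implied partial correlations: −Θ_ij / √(Θ_ii Θ_jj), zero diagonal."""
        d = np.sqrt(np.diag(self.precision))
        part = -self.precision / np.outer(d, d)
        np.fill_diagonal(part, 0.0)
        return part

    def latent_correlation(self) -> np.ndarray:
        """Marginal correlation matrix of the latent normal."""
        cov = np.linalg.inv(self.precision)
        d = np.sqrt(np.diag(cov))
        return cov / np.outer(d, d)

    def edge_set(self, tol: float = 1e-12) -> set[tuple[int, int]]:
        part = self.partials
        p = self.p
        return {(i, j) for i in range(p) for j in range(i + 1, p)
                if abs(part[i, j]) > tol}

    def to_json(self, path: str | Path) -> None:
        obj = {
            "kind": "ggm",
            "precision": self.precision.tolist(),
            "thresholds": [c.tolist() for c in self.thresholds],
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(obj, indent=1))


@dataclass
class GroundTruthDAG:
    """Linear-Gaussian structural model on an acyclic adjacency."""

    adjacency: np.ndarray  # (p, p) 0/1; adjacency[i, j] = 1 means i -> j
    coefficients: np.ndarray  # same shape; weight of i -> j
    noise_sd: np.ndarray  # (p,)
    thresholds: list[np.ndarray]
    seed: int | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if topological_order(A) is None:
            raise ValueError("adjacency contains a cycle")
        if np.any(np.asarray(self.noise_sd) <= 0):
            raise ValueError("noise_sd must be positive")
        for cuts in self.thresholds:
            if np.any(np.diff(cuts) <= 0):
                raise ValueError("thresholds must be strictly increasing")

    @property
    def p(self) -> int:
        return self.adjacency.shape[0]

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in zip(*np.nonzero(self.adjacency))}

    def latent_covariance(self) -> np.ndarray:
        """Analytic covariance of the latents: M diag(σ²) Mᵀ with M = (I−Aᵀ)⁻¹."""
        A = self.coefficients * self.adjacency
        M = np.linalg.inv(np.eye(self.p) - A.T)
        return M @ np.diag(np.asarray(self.noise_sd) ** 2) @ M.T

    def latent_correlation(self) -> np.ndarray:
        cov = self.latent_covariance()
        d = np.sqrt(np.diag(cov))
        return cov / np.outer(d, d)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "kind": "dag",
            "adjacency": np.asarray(self.adjacency, int).tolist(),
            "coefficients": np.asarray(self.coefficients, float).tolist(),
            "noise_sd": np.asarray(self.noise_sd, float).tolist(),
            "thresholds": [c.tolist() for c in self.thresholds],
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(obj, indent=1))


def topological_order(adjacency: np.ndarray) -> list[int] | None:
    """Kahn's algorithm; None if the graph is cyclic."""
    A = np.asarray(adjacency, bool).copy()
    p = A.shape[0]
    indeg = A.sum(axis=0).astype(int)
    queue = [i for i in range(p) if indeg[i] == 0]
    order: list[int] = []
    while queue:
        i = queue.pop(0)
        order.append(i)
        for j in np.nonzero(A[i])[0]:
            A[i, j] = False
            indeg[j] -= 1
            if indeg[j] == 0:
                queue.append(int(j))
    return order if len(order) == p else None


def _make_thresholds(p: int, kind: str, rng: np.random.Generator) -> list[np.ndarray]:
    if kind == "symmetric":
        return [SYMMETRIC_CUTS.copy() for _ in range(p)]
    if kind == "skewed":
        return [SKEWED_CUTS.copy() for _ in range(p)]
    if kind == "mixed":
        # roughly half symmetric, half right-skewed, shuffled
        kinds = np.array(["symmetric"] * (p - p // 2) + ["skewed"] * (p // 2))
        rng.shuffle(kinds)
        return [SYMMETRIC_CUTS.copy() if k == "symmetric" else SKEWED_CUTS.copy()
                for k in kinds]
    raise ValueError(f"unknown threshold kind {kind!r}")


def random_ggm(
    p: int,
    edge_density: float,
    weight_range: tuple[float, float] = (0.25, 0.4),
    seed: int = 0,
    thresholds: str = "mixed",
    negative_fraction: float = 0.0,
    min_eigenvalue: float = 0.05,
) -> GroundTruthGGM:
    """Sample a sparse positive-definite precision matrix.

    Edges are Bernoulli(``edge_density``) on unordered pairs with magnitudes
    uniform in ``weight_range``; the precision starts as I − W and, if its
    smallest eigenvalue falls below ``min_eigenvalue``, the diagonal is
    inflated (diagonal dominance repair), which shrinks the implied partials.
    """
    if p < 2:
        raise ValueError("p must be >= 2")
    if not 0 <= edge_density <= 1:
        raise ValueError("edge_density must lie in [0, 1]")
    lo, hi = weight_range
    if not (0 <= lo <= hi < 1):
        raise ValueError("weight_range must satisfy 0 <= lo <= hi < 1")
    rng = np.random.default_rng(seed)
    W = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < edge_density:
                w = rng.uniform(lo, hi)
                if rng.random() < negative_fraction:
                    w = -w
                W[i, j] = W[j, i] = w
    P = np.eye(p) - W
    lam_min = np.linalg.eigvalsh(P).min()
    if lam_min < min_eigenvalue:
        P += (min_eigenvalue - lam_min) * np.eye(p)
    cuts = _make_thresholds(p, thresholds, rng)
    return GroundTruthGGM(P, cuts, seed=seed)


def random_dag(
    p: int,
    edge_prob: float,
    coeff_range: tuple[float, float] = (0.5, 1.0),
    seed: int = 0,
    thresholds: str = "mixed",
    negative_fraction: float = 0.0,
) -> GroundTruthDAG:
    """Sample a random DAG, acyclic by construction.

    A random permutation of the nodes fixes a topological order; each pair
    (earlier → later) receives an edge with probability ``edge_prob`` and a
    coefficient drawn uniformly from ``coeff_range``.
    """
    if not 0 <= edge_prob <= 1:
        raise ValueError("edge_prob must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(p)
    A = np.zeros((p, p), dtype=int)
    C = np.zeros((p, p))
    for a in range(p):
        for b in range(a + 1, p):
            if rng.random() < edge_prob:
                i, j = order[a], order[b]
                A[i, j] = 1
                c = rng.uniform(*coeff_range)
                if rng.random() < negative_fraction:
                    c = -c
                C[i, j] = c
    cuts = _make_thresholds(p, thresholds, rng)
    return GroundTruthDAG(A, C, np.ones(p), cuts, seed=seed)


def sample_ordinal(
    truth: GroundTruthGGM | GroundTruthDAG,
    n: int,
    seed: int = 0,
    labels: list[str] | None = None,
) -> SymptomDataset:
    """Draw latents from the implied multivariate normal and discretize.

    GGM: covariance is the inverse precision, rescaled to unit variances so
    the thresholds act on standard-normal marginals.  DAG: simulate in
    topological order, then standardize each column by its analytic SD.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    p = truth.p
    if isinstance(truth, GroundTruthGGM):
        cov = np.linalg.inv(truth.precision)
        d = np.sqrt(np.diag(cov))
        corr = cov / np.outer(d, d)
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise ValueError("implied covariance not positive definite")
        Z = rng.multivariate_normal(np.zeros(p), corr, size=n, method="cholesky")
    else:
        order = topological_order(truth.adjacency)
        assert order is not None
        A = truth.coefficients * truth.adjacency
        eps = rng.normal(size=(n, p)) * np.asarray(truth.noise_sd)
        Z = np.zeros((n, p))
        for j in order:
            parents = np.nonzero(truth.adjacency[:, j])[0]
            Z[:, j] = Z[:, parents] @ A[parents, j] + eps[:, j]
        sd = np.sqrt(np.diag(truth.latent_covariance()))
        Z = Z / sd
    values = np.empty((n, p))
    for j in range(p):
        values[:, j] = np.searchsorted(truth.thresholds[j], Z[:, j])
    if labels is None:
        labels = PTSD_LABELS[:p] if p <= len(PTSD_LABELS) else [f"s{j}" for j in range(p)]
    L = max(len(c) for c in truth.thresholds) + 1
    return SymptomDataset(values, labels, n_levels=L, source_scale=SourceScale.PSS_0_3)


def inject_missing(ds: SymptomDataset, n_rows: int, seed: int = 0) -> SymptomDataset:
    """Blank one uniformly chosen cell in each of ``n_rows`` distinct rows."""
    if n_rows > ds.n:
        raise ValueError(f"n_rows={n_rows} exceeds dataset rows n={ds.n}")
    rng = np.random.default_rng(seed)
    values = ds.values.copy()
    rows = rng.choice(ds.n, size=n_rows, replace=False)
    cols = rng.integers(0, ds.p, size=n_rows)
    values[rows, cols] = np.nan
    return SymptomDataset(values, ds.node_labels, ds.n_levels, ds.source_scale)


def weak_signal_preset(
    seed: int = 0,
    n: int = 179,
) -> tuple[SymptomDataset, GroundTruthGGM]:
    """Small-sample, weak-dependence emulation for instability studies.

    Same shape as ``csa_ptsd_preset`` (17 items, 4 levels) but with edge
    weights low enough that, at n = 179, centrality orderings are driven
    largely by sampling noise — the regime in which case-dropping
    stability analysis is expected to flag the centralities as unstable.
    """
    rng = np.random.default_rng(seed)
    s_truth, s_sample = rng.integers(0, 2**31 - 1, size=2)
    truth = random_ggm(17, 0.15, (0.12, 0.22), seed=int(s_truth))
    ds = sample_ordinal(truth, n, seed=int(s_sample), labels=PTSD_LABELS)
    return ds, truth


def csa_ptsd_preset(
    seed: int = 0,
    n: int = 179,
    n_missing_rows: int = 14,
    edge_density: float = 0.15,
    weight_range: tuple[float, float] = (0.25, 0.4),
) -> tuple[SymptomDataset, GroundTruthGGM]:
    """The default emulation of the study-shaped dataset.

    17 symptoms on 4 levels, a sparse positive latent GGM, mixed
    symmetric/right-skewed marginals, and 14 of the 179 rows carrying at
    least one missing cell.  Emulates shape, not the study's actual values.
    """
    rng = np.random.default_rng(seed)
    s_truth, s_sample, s_miss = rng.integers(0, 2**31 - 1, size=3)
    truth = random_ggm(17, edge_density, weight_range, seed=int(s_truth))
    ds = sample_ordinal(truth, n, seed=int(s_sample), labels=PTSD_LABELS)
    ds = inject_missing(ds, n_missing_rows, seed=int(s_miss))
    return ds, truth
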