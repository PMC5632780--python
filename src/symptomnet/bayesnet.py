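"""Bayesian-network branch: BIC hill-climbing, bootstrap model averaging.

Structure learning treats the ordinal codes as metric and scores a DAG by
the linear-Gaussian node-wise decomposition

    score(G) = sum_i [ max log-lik of node i | parents(i) - (k_i / 2) log n ]

with k_i = |parents| + 2 (regression coefficients + intercept + residual
variance); higher is better.  Search is greedy hill climbing over
add/delete/reverse single-edge moves (acyclicity preserved, deterministic
lexicographic tie-breaking), with random restarts that perturb the current
optimum and re-climb.

Within each climb the candidate moves are visited in a seeded random order,
so exact score ties (the two orientations of a Markov-equivalent pair score
identically under a Gaussian BIC) are broken differently across bootstrap
resamples and the averaged direction probability honestly reflects
orientation unidentifiability instead of an index-order artifact.

Stability comes from nonparametric bootstrap model averaging: a network is
learned on each row-resample; per unordered pair the *edge strength* is the
fraction of bootstrap networks containing the edge in either direction, and
the *direction probability* is the fraction of those that point the
depicted way.  Edges are retained above the Scutari–Nagarajan
statistically-driven threshold (the t*-quantile of the strengths, t*
minimizing the L1 distance between the empirical strength CDF and an ideal
two-point 0/1 CDF).  Retained edges are oriented by majority direction; an
exact 50/50 split is broken by lexicographic node-label order and flagged.
If majority orientation ever produces a cycle, the cycle edge with the
lowest direction probability is reversed (or dropped) until the graph is
acyclic; every repair is logged.

Per-edge BIC importance is the score loss when the edge is deleted from the
averaged network — the "how damaging would removal be" annotation used for
edge thickness in one of the two standard renderings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import SymptomDataset
from .simulate import topological_order


class CyclicGraphError(ValueError):
    pass


@dataclass
class SearchConfig:
    """Hill-climbing and bootstrap-averaging settings.

    ``restarts``/``perturbations`` govern the single best-network search;
    per-resample climbs inside the bootstrap use ``bootstrap_restarts``
    (default 0, i.e. one plain greedy climb per resample).  The direction
    rule is the majority fraction needed to depict an edge's direction.
    """

    restarts: int = 10
    perturbations: int = 5
    B: int = 10_000
    direction_rule: float = 0.51
    seed: int = 0
    bootstrap_restarts: int = 0

    def __post_init__(self) -> None:
        if self.restarts < 0 or self.B < 1:
            raise ValueError("restarts must be >= 0 and B >= 1")
        if not 0.5 < self.direction_rule <= 1:
            raise ValueError("direction_rule must lie in (0.5, 1]")

    def to_dict(self) -> dict:
        return {
            "restarts": self.restarts, "perturbations": self.perturbations,
            "B": self.B, "direction_rule": self.direction_rule,
            "seed": self.seed, "bootstrap_restarts": self.bootstrap_restarts,
        }


class GaussianBicScorer:
    """Cached node-wise linear-Gaussian BIC components for one dataset.

    All regressions reduce to solves against one precomputed augmented
    cross-product matrix, so a node score costs O(k^3) in the number of
    parents regardless of n.
    """

    def __init__(self, data: np.ndarray):
        X = np.asarray(data, float)
        if np.isnan(X).any():
            raise ValueError("scoring requires complete data (no missing cells)")
        self.n, self.p = X.shape
        Z = np.column_stack([np.ones(self.n), X])
        self.M = Z.T @ Z
        self._cache: dict[tuple[int, frozenset[int]], float] = {}

    def node_score(self, i: int, parents: frozenset[int]) -> float:
        key = (i, parents)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        idx = [0] + [1 + j for j in sorted(parents)]
        Syy = self.M[1 + i, 1 + i]
        Sxy = self.M[idx, 1 + i]
        Sxx = self.M[np.ix_(idx, idx)]
        try:
            beta = np.linalg.solve(Sxx, Sxy)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular parent design for node {i} with parents {sorted(parents)}"
            ) from exc
        rss = float(Syy - Sxy @ beta)
        rss = max(rss, 1e-12 * max(Syy, 1.0))
        n = self.n
        loglik = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)
        k = len(parents) + 2
        val = loglik - 0.5 * k * np.log(n)
        self._cache[key] = val
        return val


def _parents(adj: np.ndarray, j: int) -> frozenset[int]:
    return frozenset(int(i) for i in np.nonzero(adj[:, j])[0])


def bic_score(adjacency: np.ndarray, data: np.ndarray | GaussianBicScorer) -> float:
    """Total linear-Gaussian BIC score of a DAG (higher is better)."""
    adj = np.asarray(adjacency, bool)
    if topological_order(adj) is None:
        raise CyclicGraphError("graph contains a cycle")
    scorer = data if isinstance(data, GaussianBicScorer) else GaussianBicScorer(data)
    return sum(scorer.node_score(j, _parents(adj, j)) for j in range(adj.shape[0]))


def _creates_cycle(adj: np.ndarray, i: int, j: int) -> bool:
    """Would adding i -> j close a cycle (i.e. is i reachable from j)?"""
    p = adj.shape[0]
    stack = [j]
    seen = np.zeros(p, bool)
    while stack:
        u = stack.pop()
        if u == i:
            return True
        if seen[u]:
            continue
        seen[u] = True
        stack.extend(int(v) for v in np.nonzero(adj[u])[0] if not seen[v])
    return False


def _closure(adj: np.ndarray) -> np.ndarray:
    """Boolean reachability matrix (paths of length >= 1) by squaring."""
    R = np.asarray(adj, bool).copy()
    while True:
        R2 = R | (R @ R)
        if (R2 == R).all():
            return R
        R = R2


def _climb(adj: np.ndarray, scorer: GaussianBicScorer,
           rng: np.random.Generator | None = None) -> float:
    """Greedy best-move ascent in place; returns the final score.

    Candidate moves are visited in a per-climb random (seeded) order, so
    exact score ties — e.g. the two orientations of a Markov-equivalent
    pair — are broken at random rather than by index order.  Under a fixed
    seed the climb is still fully deterministic.
    """
    p = adj.shape[0]
    node_scores = np.array(
        [scorer.node_score(j, _parents(adj, j)) for j in range(p)]
    )
    pairs = [(i, j) for i in range(p) for j in range(p) if i != j]
    if rng is not None:
        rng.shuffle(pairs)
    while True:
        best_gain = 0.0
        best_move = None
        reach = _closure(adj)  # adding i->j closes a cycle iff reach[j, i]
        for i, j in pairs:
            if adj[i, j]:
                # delete i -> j
                pa = _parents(adj, j) - {i}
                gain = scorer.node_score(j, pa) - node_scores[j]
                if gain > best_gain + 1e-12:
                    best_gain, best_move = gain, ("del", i, j)
                # reverse i -> j (delete + add j -> i)
                adj[i, j] = False
                ok = not _creates_cycle(adj, j, i)
                adj[i, j] = True
                if ok:
                    pa_i = _parents(adj, i) | {j}
                    gain = (
                        scorer.node_score(j, pa)
                        - node_scores[j]
                        + scorer.node_score(i, pa_i)
                        - node_scores[i]
                    )
                    if gain > best_gain + 1e-12:
                        best_gain, best_move = gain, ("rev", i, j)
            elif not adj[j, i] and not reach[j, i]:
                # add i -> j
                pa = _parents(adj, j) | {i}
                gain = scorer.node_score(j, pa) - node_scores[j]
                if gain > best_gain + 1e-12:
                    best_gain, best_move = gain, ("add", i, j)
        if best_move is None:
            return float(node_scores.sum())
        op, i, j = best_move
        if op == "add":
            adj[i, j] = True
        elif op == "del":
            adj[i, j] = False
        else:
            adj[i, j] = False
            adj[j, i] = True
            node_scores[i] = scorer.node_score(i, _parents(adj, i))
        node_scores[j] = scorer.node_score(j, _parents(adj, j))


def _perturb(adj: np.ndarray, n_moves: int, rng: np.random.Generator) -> None:
    """Apply random valid add/delete/reverse moves in place."""
    p = adj.shape[0]
    for _ in range(n_moves):
        for _attempt in range(20):
            i, j = rng.integers(0, p, size=2)
            if i == j:
                continue
            if adj[i, j]:
                if rng.random() < 0.5:
                    adj[i, j] = False
                    break
                adj[i, j] = False
                if _creates_cycle(adj, j, i):
                    adj[i, j] = True
                    continue
                adj[j, i] = True
                break
            if not adj[j, i] and not _creates_cycle(adj, i, j):
                adj[i, j] = True
                break


def hill_climb(
    data: np.ndarray | SymptomDataset,
    cfg: SearchConfig | None = None,
    restarts: int | None = None,
) -> np.ndarray:
    """Learn a DAG by greedy BIC hill climbing with random restarts.

    Starts from the empty graph; after each local optimum the best graph is
    perturbed by random valid moves and re-climbed.  Deterministic under a
    fixed config seed.  Returns a boolean (p, p) adjacency.
    """
    cfg = cfg or SearchConfig()
    if isinstance(data, SymptomDataset):
        data = data.values
    scorer = GaussianBicScorer(data)
    p = scorer.p
    if scorer.n <= p + 2:
        raise ValueError("too few rows for the implied maximum in-degree")
    rng = np.random.default_rng(cfg.seed)
    adj = np.zeros((p, p), bool)
    best_score = _climb(adj, scorer, rng)
    best_adj = adj.copy()
    n_restarts = cfg.restarts if restarts is None else restarts
    for _ in range(n_restarts):
        adj = best_adj.copy()
        _perturb(adj, cfg.perturbations, rng)
        score = _climb(adj, scorer, rng)
        if score > best_score + 1e-12:
            best_score = score
            best_adj = adj.copy()
    return best_adj


def bootstrap_dags(
    data: np.ndarray | SymptomDataset,
    cfg: SearchConfig | None = None,
) -> tuple[dict[tuple[int, int], float], dict[tuple[int, int], int]]:
    """Row-resample B times, learn a DAG per resample, tally edges.

    Returns (edge_strength, direction_counts): per unordered pair (i < j),
    the fraction of bootstrap networks containing the edge in either
    direction; per ordered pair, the count of networks containing that
    direction.  The accounting identity ``counts[(i,j)] + counts[(j,i)] ==
    strength[(i,j)] * B`` holds exactly.
    """
    cfg = cfg or SearchConfig()
    if isinstance(data, SymptomDataset):
        data = data.values
    if np.isnan(data).any():
        raise ValueError("bootstrap_dags requires complete data")
    n, p = data.shape
    rng = np.random.default_rng(cfg.seed)
    pair_counts: dict[tuple[int, int], int] = {}
    dir_counts: dict[tuple[int, int], int] = {}
    produced = failures = 0
    while produced < cfg.B:
        rows = rng.integers(0, n, size=n)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            adj = hill_climb(
                data[rows],
                SearchConfig(
                    restarts=cfg.bootstrap_restarts,
                    perturbations=cfg.perturbations,
                    B=1, direction_rule=cfg.direction_rule, seed=sub_seed,
                ),
            )
        except np.linalg.LinAlgError:
            failures += 1
            if failures > cfg.B:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        produced += 1
        for i, j in zip(*np.nonzero(adj)):
            i, j = int(i), int(j)
            a, b = (i, j) if i < j else (j, i)
            pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
            dir_counts[(i, j)] = dir_counts.get((i, j), 0) + 1
    strengths = {k: v / cfg.B for k, v in pair_counts.items()}
    return strengths, dir_counts


def sn_optimal_t(strengths: np.ndarray) -> float:
    """t* minimizing the L1 distance between the empirical strength CDF and
    the ideal two-point CDF (mass t at 0, 1-t at 1) over [0, 1].

    The distance is integral |Fhat(x) - t| dx on [0, 1); the minimizer is a
    weighted median of the Fhat step values with segment-length weights.
    """
    s = np.sort(np.clip(np.asarray(strengths, float), 0.0, 1.0))
    m = s.size
    if m == 0:
        raise ValueError("need at least one strength")
    # step function Fhat on [0,1): knots at unique strengths
    knots = np.concatenate(([0.0], np.unique(s), [1.0]))
    fvals = []
    widths = []
    for a, b in zip(knots[:-1], knots[1:]):
        if b <= a:
            continue
        fvals.append(np.searchsorted(s, a, side="right") / m)
        widths.append(b - a)
    fvals = np.asarray(fvals)
    widths = np.asarray(widths)
    order = np.argsort(fvals)
    fvals, widths = fvals[order], widths[order]
    cum = np.cumsum(widths)
    half = cum[-1] / 2
    return float(fvals[np.searchsorted(cum, half)])


def sn_threshold(strengths) -> tuple[float, float]:
    """Scutari–Nagarajan retention cut-point.

    Returns (cutpoint, t_star): the cut-point is the t*-quantile of the
    strengths; edges strictly above it are retained (when t* = 0 the ideal
    CDF declares every edge significant, so retention is inclusive at the
    cut-point).
    """
    s = np.asarray(list(strengths) if not isinstance(strengths, np.ndarray)
                   else strengths, float)
    t_star = sn_optimal_t(s)
    cut = float(np.quantile(s, t_star))
    return cut, t_star


@dataclass
class DirectedModel:
    """Bootstrap-averaged DAG with per-edge strength/direction/BIC annotations."""

    adjacency: np.ndarray
    labels: list[str]
    edge_strength: dict[tuple[int, int], float]  # per unordered pair (i < j)
    direction_prob: dict[tuple[int, int], float]  # per retained directed edge
    threshold: float
    t_star: float = np.nan
    edge_bic: dict[tuple[int, int], float] = field(default_factory=dict)
    tie_breaks: list[tuple[int, int]] = field(default_factory=list)
    repairs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if topological_order(self.adjacency) is None:
            raise CyclicGraphError("averaged network must be acyclic")

    @property
    def p(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.asarray(self.adjacency, bool).sum())

    def edges(self) -> list[tuple[int, int]]:
        return [(int(i), int(j)) for i, j in zip(*np.nonzero(self.adjacency))]

    def edge_pairs(self) -> set[tuple[str, str]]:
        """Unordered label pairs of retained edges (for GGM comparison)."""
        out = set()
        for i, j in self.edges():
            a, b = sorted((self.labels[i], self.labels[j]))
            out.add((a, b))
        return out

    def edge_list(self) -> pd.DataFrame:
        rows = []
        for i, j in self.edges():
            a, b = (i, j) if i < j else (j, i)
            rows.append({
                "from": self.labels[i],
                "to": self.labels[j],
                "strength": self.edge_strength.get((a, b), np.nan),
                "direction_prob": self.direction_prob.get((i, j), np.nan),
                "bic_importance": self.edge_bic.get((i, j), np.nan),
            })
        return pd.DataFrame(
            rows, columns=["from", "to", "strength", "direction_prob",
                           "bic_importance"],
        )

    def to_dot(self, thickness: str = "direction_prob") -> str:
        """Graphviz DOT; edge penwidth scales with direction probability or
        BIC importance (the two standard renderings)."""
        vals = {}
        for i, j in self.edges():
            if thickness == "direction_prob":
                vals[(i, j)] = self.direction_prob.get((i, j), 0.5)
            else:
                vals[(i, j)] = self.edge_bic.get((i, j), 1.0)
        vmax = max(vals.values()) if vals else 1.0
        lines = ["digraph symptoms {"]
        for lab in self.labels:
            lines.append(f'  "{lab}";')
        for (i, j), v in vals.items():
            w = 0.5 + 4.5 * (v / vmax if vmax > 0 else 0.0)
            lines.append(
                f'  "{self.labels[i]}" -> "{self.labels[j]}" [penwidth={w:.2f}];'
            )
        lines.append("}")
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "labels": self.labels,
            "adjacency": np.asarray(self.adjacency, int).tolist(),
            "threshold": self.threshold,
            "t_star": self.t_star,
            "edge_strength": {f"{a},{b}": v for (a, b), v in self.edge_strength.items()},
            "direction_prob": {f"{i},{j}": v for (i, j), v in self.direction_prob.items()},
            "edge_bic": {f"{i},{j}": v for (i, j), v in self.edge_bic.items()},
            "tie_breaks": self.tie_breaks,
            "repairs": self.repairs,
        }
        Path(path).write_text(json.dumps(obj, indent=1))


def _find_cycle(adj: np.ndarray) -> list[tuple[int, int]] | None:
    """One directed cycle as an edge list, or None."""
    p = adj.shape[0]
    color = np.zeros(p, int)  # 0 white, 1 grey, 2 black
    stack_path: list[int] = []

    def dfs(u: int) -> list[tuple[int, int]] | None:
        color[u] = 1
        stack_path.append(u)
        for v in np.nonzero(adj[u])[0]:
            v = int(v)
            if color[v] == 1:
                k = stack_path.index(v)
                cyc = stack_path[k:] + [v]
                return list(zip(cyc[:-1], cyc[1:]))
            if color[v] == 0:
                found = dfs(v)
                if found is not None:
                    return found
        stack_path.pop()
        color[u] = 2
        return None

    for s in range(p):
        if color[s] == 0:
            found = dfs(s)
            if found is not None:
                return found
    return None


def averaged_network(
    strengths: dict[tuple[int, int], float],
    direction_counts: dict[tuple[int, int], int],
    cfg: SearchConfig,
    labels: list[str],
) -> DirectedModel:
    """Retain, orient and (if needed) acyclify the bootstrap-averaged DAG."""
    p = len(labels)
    svals = np.array(list(strengths.values())) if strengths else np.array([0.0])
    cut, t_star = sn_threshold(svals)
    adj = np.zeros((p, p), bool)
    dir_prob: dict[tuple[int, int], float] = {}
    tie_breaks: list[tuple[int, int]] = []
    for (a, b), s in sorted(strengths.items()):
        retained = s > cut or (t_star == 0.0 and s >= cut)
        if not retained:
            continue
        n_ab = direction_counts.get((a, b), 0)
        n_ba = direction_counts.get((b, a), 0)
        total = n_ab + n_ba
        if total == 0:
            continue
        frac_ab = n_ab / total
        if frac_ab > 0.5:
            i, j, prob = a, b, frac_ab
        elif frac_ab < 0.5:
            i, j, prob = b, a, 1 - frac_ab
        else:  # exact 50/50: lexicographic label order, flagged
            i, j = (a, b) if labels[a] <= labels[b] else (b, a)
            prob = 0.5
            tie_breaks.append((i, j))
        adj[i, j] = True
        dir_prob[(i, j)] = prob
    repairs: list[str] = []
    guard = 0
    while (cycle := _find_cycle(adj)) is not None:
        guard += 1
        if guard > p * p:
            raise CyclicGraphError("cycle repair did not terminate")
        # weakest-direction edge in the cycle
        i, j = min(cycle, key=lambda e: dir_prob.get(e, 0.5))
        prob = dir_prob.pop((i, j))
        adj[i, j] = False
        # try reversing the weakest edge once; if it was itself born of a
        # reversal (or the reverse edge exists) drop it instead
        already_reversed = any(
            r.startswith(f"reversed {labels[j]}->{labels[i]}") for r in repairs
        )
        if adj[j, i] or already_reversed:
            repairs.append(f"dropped {labels[i]}->{labels[j]}")
        else:
            adj[j, i] = True
            dir_prob[(j, i)] = 1 - prob
            repairs.append(
                f"reversed {labels[i]}->{labels[j]} (direction_prob {prob:.3f})"
            )
    return DirectedModel(
        adj, list(labels), dict(strengths), dir_prob, cut, t_star,
        tie_breaks=tie_breaks, repairs=repairs,
    )


def edge_bic_importance(
    model: DirectedModel, data: np.ndarray | SymptomDataset
) -> dict[tuple[int, int], float]:
    """Per retained edge: |score(G) - score(G without the edge)|.

    Updates ``model.edge_bic`` in place and returns it.  Asking for an
    absent pair is a domain error (raised by dict lookup downstream).
    """
    if isinstance(data, SymptomDataset):
        data = data.values
    scorer = GaussianBicScorer(data)
    full = bic_score(model.adjacency, scorer)
    out = {}
    for i, j in model.edges():
        adj = np.asarray(model.adjacency, bool).copy()
        adj[i, j] = False
        out[(i, j)] = abs(full - bic_score(adj, scorer))
    model.edge_bic = out
    return out
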