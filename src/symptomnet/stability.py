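"""Robustness analyses for the regularized partial-correlation network.

Three bootstrap procedures, mirroring common practice for psychometric
networks:

* edge-weight accuracy — nonparametric row resampling; the full polychoric
  → EBIC-glasso pipeline is re-run per resample and 95% percentile
  confidence intervals are formed per edge;
* centrality difference test — for each node pair and metric, the bootstrap
  distribution of the centrality difference; a difference is significant
  when its 95% percentile CI excludes zero (no multiplicity correction,
  matching the source ecosystem's convention);
* case-dropping stability (CS-coefficient) — subsamples without replacement
  at increasing drop proportions; the CS-coefficient is the largest drop
  proportion at which at least 95% of subsample centralities correlate at
  least 0.70 with the full-sample centralities.  Values above .50 indicate
  stable centralities; .25 is the usual minimum for interpretation.

Plus the restricted-variance diagnostics: Pearson correlations of SD and of
skewness against strength centrality, testing whether differential item
variability drives apparent centrality.
"""

from __future__ import annotations

import json
import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .centrality import METRICS, node_centrality
from .datasets import DescriptiveTable, SymptomDataset
from .glasso import GlassoConfig, WeightedNetwork, ebic_glasso
from .polychoric import DegenerateVariableError, polychoric_matrix

DEFAULT_DROP_GRID = (0.10, 0.25, 0.40, 0.55, 0.70, 0.75)
CS_COR_THRESHOLD = 0.70
CS_PROBABILITY = 0.95


class BootstrapError(RuntimeError):
    pass


@contextmanager
def _quiet():
    """Silence per-resample disconnection warnings inside bootstrap loops."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


def fit_network(ds: SymptomDataset, cfg: GlassoConfig | None = None,
                pair_policy: str = "pairwise") -> WeightedNetwork:
    """Full-pipeline fit: polychoric matrix then EBIC-glasso."""
    S = polychoric_matrix(ds, pair_policy=pair_policy)
    return ebic_glasso(S, n=int(np.median(S.pair_n)), cfg=cfg)


def _subset(ds: SymptomDataset, rows: np.ndarray) -> SymptomDataset:
    return SymptomDataset(ds.values[rows], ds.node_labels, ds.n_levels,
                          ds.source_scale)


def _bootstrap_networks(
    ds: SymptomDataset, cfg: GlassoConfig, B: int, seed: int,
    failure_counter: list[int] | None = None,
) -> Iterator[WeightedNetwork]:
    """Yield B networks fit to row-resamples; degenerate draws are redrawn.

    Redraw budget is B extra attempts in total; exhausting it raises.  If
    given, ``failure_counter[0]`` accumulates the number of redraws.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    if ds.n < 2 or np.all(np.nanstd(ds.values, axis=0) == 0):
        raise BootstrapError("degenerate dataset: resampling cannot vary")
    rng = np.random.default_rng(seed)
    produced = failures = 0
    while produced < B:
        rows = rng.integers(0, ds.n, size=ds.n)
        try:
            net = fit_network(_subset(ds, rows), cfg)
        except (DegenerateVariableError, np.linalg.LinAlgError):
            failures += 1
            if failure_counter is not None:
                failure_counter[0] = failures
            if failures > B:
                raise BootstrapError(
                    f"{failures} degenerate resamples; giving up"
                ) from None
            continue
        yield net
        produced += 1


def bootstrap_edges(
    ds: SymptomDataset,
    cfg: GlassoConfig | None = None,
    B: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Percentile 95% CIs per edge from B row-resamples.

    Returns one row per unordered node pair with the full-sample point
    estimate, the 2.5%/97.5% bootstrap quantiles, and a flag for CIs that
    exclude zero.  The number of discarded degenerate resamples is stored
    in ``DataFrame.attrs['n_failures']``.
    """
    cfg = cfg or GlassoConfig()
    if ds.n < 2 or np.all(np.nanstd(ds.values, axis=0) == 0):
        raise BootstrapError("degenerate dataset: resampling cannot vary")
    full = fit_network(ds, cfg)
    p = full.p
    iu = np.triu_indices(p, 1)
    draws = np.empty((B, iu[0].size))
    counter = [0]
    for b, net in enumerate(_bootstrap_networks(ds, cfg, B, seed, counter)):
        draws[b] = net.weights[iu]
    n_failures = counter[0]
    lower = np.quantile(draws, 0.025, axis=0)
    upper = np.quantile(draws, 0.975, axis=0)
    est = full.weights[iu]
    out = pd.DataFrame({
        "node_a": [full.labels[i] for i in iu[0]],
        "node_b": [full.labels[j] for j in iu[1]],
        "estimate": est,
        "lower": lower,
        "upper": upper,
    })
    out["nonzero"] = (out["lower"] > 0) | (out["upper"] < 0)
    out.attrs["n_failures"] = n_failures
    out.attrs["B"] = B
    return out


def centrality_difference_test(
    ds: SymptomDataset,
    cfg: GlassoConfig | None = None,
    B: int = 1000,
    seed: int = 0,
    metrics: Sequence[str] = METRICS,
) -> dict[str, pd.DataFrame]:
    """Bootstrapped node-pair centrality difference test.

    For each metric, returns a symmetric hollow boolean matrix: True where
    the 95% percentile CI of the bootstrap centrality difference excludes
    zero.
    """
    cfg = cfg or GlassoConfig()
    labels = list(ds.node_labels)
    p = len(labels)
    cents = {m: np.empty((B, p)) for m in metrics}
    with _quiet():
        for b, net in enumerate(_bootstrap_networks(ds, cfg, B, seed)):
            tab = node_centrality(net)
            for m in metrics:
                cents[m][b] = tab[m].to_numpy()
    out = {}
    for m in metrics:
        sig = np.zeros((p, p), dtype=bool)
        for i in range(p):
            for j in range(i + 1, p):
                diff = cents[m][:, i] - cents[m][:, j]
                lo, hi = np.quantile(diff, [0.025, 0.975])
                sig[i, j] = sig[j, i] = (lo > 0) or (hi < 0)
        out[m] = pd.DataFrame(sig, index=labels, columns=labels)
    return out


def cs_from_correlations(
    corr_by_drop: dict[float, np.ndarray],
    threshold: float = CS_COR_THRESHOLD,
    probability: float = CS_PROBABILITY,
) -> float:
    """CS-coefficient from per-drop-level correlation samples.

    The largest drop proportion at which at least ``probability`` of the
    correlations reach ``threshold``; 0.0 if no level qualifies.
    """
    best = 0.0
    for drop in sorted(corr_by_drop):
        corrs = np.asarray(corr_by_drop[drop], float)
        corrs = corrs[~np.isnan(corrs)]
        if corrs.size == 0:
            continue
        if np.mean(corrs >= threshold) >= probability:
            best = max(best, float(drop))
    return best


def cs_coefficient(
    ds: SymptomDataset,
    cfg: GlassoConfig | None = None,
    metrics: Sequence[str] = METRICS,
    drop_grid: Sequence[float] = DEFAULT_DROP_GRID,
    B_per_drop: int = 250,
    seed: int = 0,
    threshold: float = CS_COR_THRESHOLD,
) -> dict[str, float]:
    """Case-dropping bootstrap CS-coefficient per centrality metric.

    At each drop proportion, ``B_per_drop`` subsamples (without
    replacement) are re-estimated end to end and their node centralities
    correlated with the full-sample centralities across nodes.  Subsamples
    on which estimation degenerates are discarded and counted.
    """
    drop_grid = sorted(drop_grid)
    if any(not 0 < d < 1 for d in drop_grid):
        raise ValueError("drop proportions must lie in (0, 1)")
    if B_per_drop < 20:
        raise ValueError("B_per_drop must be >= 20")
    cfg = cfg or GlassoConfig()
    rng = np.random.default_rng(seed)
    full = node_centrality(fit_network(ds, cfg))
    full_vals = {m: full[m].to_numpy() for m in metrics}
    corr_by_drop: dict[str, dict[float, np.ndarray]] = {m: {} for m in metrics}
    for drop in drop_grid:
        m_rows = int(round((1 - drop) * ds.n))
        if m_rows < 3:
            for m in metrics:
                corr_by_drop[m][drop] = np.array([])
            continue
        corrs = {m: [] for m in metrics}
        for _ in range(B_per_drop):
            rows = rng.choice(ds.n, size=m_rows, replace=False)
            try:
                with _quiet():
                    sub = node_centrality(fit_network(_subset(ds, rows), cfg))
            except (DegenerateVariableError, np.linalg.LinAlgError):
                continue
            for m in metrics:
                x, y = full_vals[m], sub[m].to_numpy()
                if np.std(x) == 0 or np.std(y) == 0:
                    corrs[m].append(np.nan)
                else:
                    corrs[m].append(float(np.corrcoef(x, y)[0, 1]))
        for m in metrics:
            corr_by_drop[m][drop] = np.asarray(corrs[m])
    return {
        m: cs_from_correlations(corr_by_drop[m], threshold=threshold)
        for m in metrics
    }


def variance_diagnostics(
    desc: DescriptiveTable, cent
) -> dict[str, tuple[float, float]]:
    """Pearson r (with two-tailed t-based p) of SD and skewness vs strength.

    A strong positive SD–strength correlation would suggest that apparent
    centrality merely tracks item variability (restricted range artefact).
    """
    strength = cent["strength"].to_numpy()
    sd = desc.sd.to_numpy()
    skew = desc.skewness.to_numpy()
    if strength.size < 3:
        raise ValueError("need at least 3 nodes")
    out = {}
    for name, x in (("sd_vs_strength", sd), ("skewness_vs_strength", skew)):
        if np.std(x) == 0 or np.std(strength) == 0:
            raise ValueError(f"zero variance in {name} inputs")
        r, pval = stats.pearsonr(x, strength)
        out[name] = (float(r), float(pval))
    return out


@dataclass
class StabilityReport:
    """Bundle of the robustness outputs for one fitted GGM."""

    edge_ci: pd.DataFrame = field(repr=False)
    cs: dict[str, float] = field(default_factory=dict)
    diff_test: dict[str, pd.DataFrame] = field(default_factory=dict, repr=False)
    diagnostics: dict[str, tuple[float, float]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def n_reliable_edges(self) -> int:
        return int(self.edge_ci["nonzero"].sum())

    def to_json(self, path: str | Path) -> None:
        obj = {
            "cs": self.cs,
            "diagnostics": {k: list(v) for k, v in self.diagnostics.items()},
            "n_reliable_edges": self.n_reliable_edges,
            "edge_ci": self.edge_ci.to_dict(orient="records"),
            "diff_test": {
                m: df.to_numpy().tolist() for m, df in self.diff_test.items()
            },
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(obj, indent=1))
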