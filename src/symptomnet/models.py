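"""Model/Results front-end for the two network estimators.

Mirrors the familiar estimation idiom: build a model object from data,
call ``fit()``, get a results object carrying the estimates, their
bootstrap uncertainties and a ``summary()`` table.

>>> ds, truth = csa_ptsd_preset(seed=1)          # doctest: +SKIP
>>> res = GaussianGraphicalModel(ds).fit()       # doctest: +SKIP
>>> print(res.summary())                         # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path

import numpy as np
import pandas as pd

from .bayesnet import (
    DirectedModel,
    SearchConfig,
    averaged_network,
    bootstrap_dags,
    edge_bic_importance,
)
from .centrality import CentralityTable, node_centrality
from .datasets import (
    DescriptiveTable,
    SourceScale,
    SymptomDataset,
    describe,
    listwise_complete,
    load_dataset,
)
from .glasso import GlassoConfig, WeightedNetwork, ebic_glasso
from .polychoric import CorrelationMatrix, polychoric_matrix
from .simulate import csa_ptsd_preset
from .stability import (
    DEFAULT_DROP_GRID,
    StabilityReport,
    bootstrap_edges,
    centrality_difference_test,
    cs_coefficient,
    variance_diagnostics,
)


def _as_dataset(data) -> SymptomDataset:
    if isinstance(data, SymptomDataset):
        return data
    if isinstance(data, pd.DataFrame):
        return SymptomDataset(data.to_numpy(dtype=float), [str(c) for c in data.columns])
    raise TypeError("data must be a SymptomDataset or DataFrame of ordinal codes")


class GaussianGraphicalModel:
    """Regularized partial-correlation network model of ordinal symptom data."""

    def __init__(self, data, config: GlassoConfig | None = None,
                 pair_policy: str = "pairwise"):
        self.data = _as_dataset(data)
        self.config = config or GlassoConfig()
        self.pair_policy = pair_policy

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "GaussianGraphicalModel":
        return cls(df, **kwargs)

    @classmethod
    def from_csv(cls, path, scale: SourceScale | str = SourceScale.PSS_0_3,
                 **kwargs) -> "GaussianGraphicalModel":
        return cls(load_dataset(path, scale), **kwargs)

    def fit(self) -> "GGMResults":
        corr = polychoric_matrix(self.data, pair_policy=self.pair_policy)
        net = ebic_glasso(corr, n=int(np.median(corr.pair_n)), cfg=self.config)
        return GGMResults(self, corr, net)


@dataclass
class GGMResults:
    """Fitted GGM: edge weights, selection path, centrality, stability."""

    model: GaussianGraphicalModel
    corr: CorrelationMatrix = field(repr=False)
    network: WeightedNetwork = field(repr=False)

    @property
    def weights(self) -> pd.DataFrame:
        return self.network.to_frame()

    @property
    def lambda_selected(self) -> float:
        return self.network.lambda_selected

    @property
    def n_edges(self) -> int:
        return self.network.n_edges

    @property
    def ebic_path(self) -> pd.DataFrame:
        return self.network.ebic_path

    @cached_property
    def centrality(self) -> CentralityTable:
        return node_centrality(self.network)

    @cached_property
    def descriptives(self) -> DescriptiveTable:
        return describe(self.model.data)

    def bootstrap_edges(self, B: int = 10_000, seed: int = 0) -> pd.DataFrame:
        return bootstrap_edges(self.model.data, self.model.config, B=B, seed=seed)

    def difference_test(self, B: int = 1000, seed: int = 0):
        return centrality_difference_test(self.model.data, self.model.config,
                                          B=B, seed=seed)

    def cs_coefficient(self, drop_grid=DEFAULT_DROP_GRID, B_per_drop: int = 250,
                       seed: int = 0) -> dict[str, float]:
        return cs_coefficient(self.model.data, self.model.config,
                              drop_grid=drop_grid, B_per_drop=B_per_drop, seed=seed)

    def variance_diagnostics(self) -> dict[str, tuple[float, float]]:
        return variance_diagnostics(self.descriptives, self.centrality)

    def stability(self, B_edges: int = 1000, B_diff: int = 500,
                  B_per_drop: int = 250, drop_grid=DEFAULT_DROP_GRID,
                  seed: int = 0) -> StabilityReport:
        return StabilityReport(
            self.bootstrap_edges(B=B_edges, seed=seed),
            self.cs_coefficient(drop_grid=drop_grid, B_per_drop=B_per_drop,
                                seed=seed + 2),
            self.difference_test(B=B_diff, seed=seed + 1),
            self.variance_diagnostics(),
        )

    def summary(self) -> str:
        ds = self.model.data
        lines = [
            "Gaussian Graphical Model (polychoric + EBIC-glasso)",
            "=" * 55,
            f"nodes:            {self.network.p}",
            f"observations:     {ds.n} (incomplete rows: {ds.n_incomplete_rows})",
            f"pair policy:      {self.corr.pair_policy}"
            + (" [PSD projection applied]" if self.corr.projected else ""),
            f"gamma (EBIC):     {self.model.config.gamma}",
            f"lambda selected:  {self.lambda_selected:.4f}",
            f"edges selected:   {self.n_edges} of {self.network.p * (self.network.p - 1) // 2}",
            "",
            "z-scored centrality (betweenness / closeness / strength):",
        ]
        tab = self.centrality.table
        for lab in tab.index:
            lines.append(
                f"  {lab:<10s} {tab.loc[lab, 'z_betweenness']:+6.2f}  "
                f"{tab.loc[lab, 'z_closeness']:+6.2f}  "
                f"{tab.loc[lab, 'z_strength']:+6.2f}"
            )
        return "\n".join(lines)

    def plot_network(self, ax=None, seed: int = 0):
        """Force-directed plot; edge width ∝ |weight|, green +, red −."""
        import matplotlib.pyplot as plt
        import networkx as nx

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 7))
        G = nx.Graph()
        G.add_nodes_from(self.network.labels)
        for _, row in self.network.edge_list().iterrows():
            G.add_edge(row["node_a"], row["node_b"], weight=row["weight"])
        pos = nx.spring_layout(G, seed=seed, weight=None)
        widths = [6 * abs(G[u][v]["weight"]) for u, v in G.edges()]
        colors = ["seagreen" if G[u][v]["weight"] > 0 else "firebrick"
                  for u, v in G.edges()]
        nx.draw_networkx(G, pos, ax=ax, node_color="lightsteelblue",
                         width=widths, edge_color=colors, font_size=8)
        ax.set_axis_off()
        return ax

    def plot_centrality(self, ax=None):
        """z-scored centrality profile per node, one line per metric."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 7))
        tab = self.centrality.table
        y = np.arange(len(tab.index))
        for m in ("betweenness", "closeness", "strength"):
            ax.plot(tab[f"z_{m}"], y, marker="o", label=m)
        ax.set_yticks(y, tab.index)
        ax.set_xlabel("z-score")
        ax.legend()
        ax.invert_yaxis()
        return ax


class BayesianNetworkModel:
    """Bootstrap-averaged DAG model of ordinal symptom data.

    Listwise deletion is applied internally: structure learning requires
    complete rows.
    """

    def __init__(self, data, config: SearchConfig | None = None):
        self.data = _as_dataset(data)
        self.config = config or SearchConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "BayesianNetworkModel":
        return cls(df, **kwargs)

    @classmethod
    def from_csv(cls, path, scale: SourceScale | str = SourceScale.PSS_0_3,
                 **kwargs) -> "BayesianNetworkModel":
        return cls(load_dataset(path, scale), **kwargs)

    def fit(self) -> "BayesianNetworkResults":
        complete = listwise_complete(self.data)
        strengths, dir_counts = bootstrap_dags(complete.values, self.config)
        model = averaged_network(strengths, dir_counts, self.config,
                                 list(self.data.node_labels))
        edge_bic_importance(model, complete.values)
        return BayesianNetworkResults(self, model, complete.n)


@dataclass
class BayesianNetworkResults:
    """Fitted averaged DAG with strength/direction/BIC edge annotations."""

    model: BayesianNetworkModel
    dag: DirectedModel = field(repr=False)
    n_used: int = 0

    @property
    def n_edges(self) -> int:
        return self.dag.n_edges

    def edge_list(self) -> pd.DataFrame:
        return self.dag.edge_list()

    def summary(self) -> str:
        lines = [
            "Bayesian network (BIC hill climbing, bootstrap-averaged DAG)",
            "=" * 60,
            f"nodes:              {self.dag.p}",
            f"complete rows used: {self.n_used} of {self.model.data.n}",
            f"bootstraps:         {self.model.config.B}",
            f"retention cutpoint: {self.dag.threshold:.3f} (t* = {self.dag.t_star:.3f})",
            f"edges retained:     {self.n_edges}",
            f"cycle repairs:      {len(self.dag.repairs)}",
            "",
            "edge                    strength  dir.prob  BIC importance",
        ]
        for _, r in self.edge_list().iterrows():
            lines.append(
                f"  {r['from']:>9s} -> {r['to']:<9s} {r['strength']:7.3f}  "
                f"{r['direction_prob']:7.3f}  {r['bic_importance']:10.2f}"
            )
        return "\n".join(lines)

    def plot(self, thickness: str = "direction_prob", ax=None, seed: int = 0):
        """DAG drawing; edge width ∝ direction probability or BIC importance."""
        import matplotlib.pyplot as plt
        import networkx as nx

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 7))
        G = nx.DiGraph()
        G.add_nodes_from(self.dag.labels)
        vals = {}
        for i, j in self.dag.edges():
            u, v = self.dag.labels[i], self.dag.labels[j]
            val = (self.dag.direction_prob.get((i, j), 0.5)
                   if thickness == "direction_prob"
                   else self.dag.edge_bic.get((i, j), 1.0))
            G.add_edge(u, v)
            vals[(u, v)] = val
        vmax = max(vals.values()) if vals else 1.0
        pos = nx.spring_layout(G, seed=seed)
        widths = [0.5 + 4.5 * vals[e] / vmax for e in G.edges()]
        nx.draw_networkx(G, pos, ax=ax, node_color="lightsteelblue",
                         width=widths, font_size=8, arrows=True)
        ax.set_axis_off()
        return ax
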