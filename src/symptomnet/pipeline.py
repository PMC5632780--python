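"""End-to-end orchestration and the GGM-vs-DAG comparison.

``run_ggm_branch`` chains polychoric estimation, EBIC-glasso, centrality
and the bootstrap/stability analyses; ``run_dag_branch`` applies listwise
deletion, bootstrap model averaging and BIC edge annotation;
``compare_networks`` partitions the GGM's edges into those shared with the
DAG skeleton and those absent from it and summarizes the absolute edge
weights of each group.  For a like-for-like comparison the GGM is
re-estimated on the listwise-complete subset (the same rows the DAG used).

Every artifact directory gets a ``metadata.json`` embedding the config
hash and seeds, and every CSV/DOT file carries the hash in a leading
comment line, so identically configured runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
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
from .datasets import SymptomDataset, describe, listwise_complete
from .glasso import GlassoConfig, WeightedNetwork, ebic_glasso
from .polychoric import polychoric_matrix
from .stability import (
    DEFAULT_DROP_GRID,
    StabilityReport,
    bootstrap_edges,
    centrality_difference_test,
    cs_coefficient,
    fit_network,
    variance_diagnostics,
)

log = logging.getLogger("symptomnet")


def config_hash(*configs: dict) -> str:
    blob = json.dumps(list(configs), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, chash: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={chash}\n")
        df.to_csv(fh, index=index)


def run_ggm_branch(
    ds: SymptomDataset,
    cfg: GlassoConfig | None = None,
    out_dir: str | Path | None = None,
    seed: int = 0,
    B_edges: int = 1000,
    B_diff: int = 500,
    B_per_drop: int = 250,
    drop_grid=DEFAULT_DROP_GRID,
    pair_policy: str = "pairwise",
) -> tuple[WeightedNetwork, CentralityTable, StabilityReport]:
    """Polychoric → EBIC-glasso → centrality → full stability suite."""
    cfg = cfg or GlassoConfig()
    meta = {
        "glasso": cfg.to_dict(), "seed": seed, "B_edges": B_edges,
        "B_diff": B_diff, "B_per_drop": B_per_drop,
        "drop_grid": list(drop_grid), "pair_policy": pair_policy,
    }
    chash = config_hash(meta)
    log.info("ggm: rows_in=%d incomplete=%d", ds.n, ds.n_incomplete_rows)
    S = polychoric_matrix(ds, pair_policy=pair_policy)
    net = ebic_glasso(S, n=int(np.median(S.pair_n)), cfg=cfg)
    log.info("ggm: edges=%d lambda=%.4f", net.n_edges, net.lambda_selected)
    cent = node_centrality(net)
    desc = describe(ds)
    edge_ci = bootstrap_edges(ds, cfg, B=B_edges, seed=seed)
    diff = centrality_difference_test(ds, cfg, B=B_diff, seed=seed + 1)
    cs = cs_coefficient(ds, cfg, drop_grid=drop_grid,
                        B_per_drop=B_per_drop, seed=seed + 2)
    try:
        diag = variance_diagnostics(desc, cent)
    except ValueError as exc:  # e.g. empty network -> zero-variance strength
        log.warning("ggm: variance diagnostics unavailable (%s)", exc)
        diag = {"sd_vs_strength": (float("nan"), float("nan")),
                "skewness_vs_strength": (float("nan"), float("nan"))}
    report = StabilityReport(edge_ci, cs, diff, diag,
                             metadata={**meta, "config_hash": chash})
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        _write_csv(S.to_frame(), out / "polychoric.csv", chash, index=True)
        _write_csv(net.to_frame(), out / "network.csv", chash, index=True)
        _write_csv(net.edge_list(), out / "edges.csv", chash)
        _write_csv(net.ebic_path, out / "ebic_path.csv", chash)
        _write_csv(cent.table, out / "centrality.csv", chash, index=True)
        report.to_json(out / "stability.json")
        (out / "metadata.json").write_text(json.dumps(
            {**meta, "config_hash": chash, "lambda_selected": net.lambda_selected,
             "n_edges": net.n_edges, "correlation": S.metadata()},
            indent=1))
    return net, cent, report


def run_dag_branch(
    ds: SymptomDataset,
    cfg: SearchConfig | None = None,
    out_dir: str | Path | None = None,
) -> DirectedModel:
    """Listwise-complete → bootstrap hill climbing → averaged DAG + BIC."""
    cfg = cfg or SearchConfig()
    complete = listwise_complete(ds)
    log.info("dag: rows_in=%d complete=%d", ds.n, complete.n)
    strengths, dir_counts = bootstrap_dags(complete.values, cfg)
    model = averaged_network(strengths, dir_counts, cfg, list(ds.node_labels))
    edge_bic_importance(model, complete.values)
    log.info("dag: edges=%d threshold=%.3f repairs=%d",
             model.n_edges, model.threshold, len(model.repairs))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        chash = config_hash(cfg.to_dict())
        _write_csv(model.edge_list(), out / "dag_edges.csv", chash)
        for mode in ("direction_prob", "bic"):
            (out / f"dag_{mode}.dot").write_text(
                f"// config_hash={chash}\n" + model.to_dot(thickness=mode)
            )
        model.to_json(out / "dag.json")
        (out / "metadata.json").write_text(json.dumps(
            {**cfg.to_dict(), "config_hash": chash, "n_rows_used": complete.n,
             "n_edges": model.n_edges, "threshold": model.threshold},
            indent=1))
    return model


@dataclass
class ComparisonReport:
    """Edge-level agreement between the GGM and the DAG skeleton."""

    dag_edge_count: int
    ggm_edge_count: int
    shared_pair_count: int
    mean_abs_weight_shared: float
    sd_abs_weight_shared: float
    mean_abs_weight_ggm_only: float
    sd_abs_weight_ggm_only: float
    n_ggm_only_positive: int
    n_ggm_only_negative: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))


def compare_networks(ggm: WeightedNetwork, dag: DirectedModel) -> ComparisonReport:
    """Partition GGM edges by DAG-skeleton membership and summarize weights."""
    if set(ggm.labels) != set(dag.labels):
        raise ValueError("node label sets differ between the two networks")
    dag_pairs = dag.edge_pairs()
    idx = {lab: i for i, lab in enumerate(ggm.labels)}
    shared_w, only_w = [], []
    for a, b in ggm.edge_pairs():
        w = ggm.weights[idx[a], idx[b]]
        if tuple(sorted((a, b))) in dag_pairs:
            shared_w.append(w)
        else:
            only_w.append(w)
    shared = np.abs(shared_w) if shared_w else np.array([])
    only = np.asarray(only_w) if only_w else np.array([])
    return ComparisonReport(
        dag_edge_count=dag.n_edges,
        ggm_edge_count=ggm.n_edges,
        shared_pair_count=len(shared_w),
        mean_abs_weight_shared=float(shared.mean()) if shared.size else np.nan,
        sd_abs_weight_shared=float(shared.std(ddof=1)) if shared.size > 1 else np.nan,
        mean_abs_weight_ggm_only=float(np.abs(only).mean()) if only.size else np.nan,
        sd_abs_weight_ggm_only=float(np.abs(only).std(ddof=1)) if only.size > 1 else np.nan,
        n_ggm_only_positive=int((only > 0).sum()),
        n_ggm_only_negative=int((only < 0).sum()),
    )


def run_comparison(
    ds: SymptomDataset,
    glasso_cfg: GlassoConfig | None = None,
    search_cfg: SearchConfig | None = None,
    out_dir: str | Path | None = None,
) -> ComparisonReport:
    """DAG branch plus a GGM re-estimated on the listwise-complete rows.

    Using the same complete-case rows for both networks makes the edge-set
    comparison like-for-like.
    """
    complete = listwise_complete(ds)
    ggm = fit_network(complete, glasso_cfg, pair_policy="listwise")
    dag = run_dag_branch(ds, search_cfg, out_dir=out_dir)
    report = compare_networks(ggm, dag)
    if out_dir is not None:
        report.to_json(Path(out_dir) / "comparison.json")
    return report
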