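"""Keystone-taxon detection from per-node centralities.

Keystones are the union of the top-5 nodes by HITS hub score and the top-5
by (unnormalised) betweenness centrality; the keystone with the highest
degree is the core taxon.  A per-keystone Spearman correlation against a
paired AVD-difference series links network position to community stability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core_data import DifferenceTable

log = logging.getLogger(__name__)

__all__ = ["KeystoneReport", "node_metrics", "keystones", "keystone_avd_correlation"]


@dataclass
class KeystoneReport:
    keystone: list[str]  # 5..10 node ids, sorted
    core: str
    hub_top: list[str]
    betweenness_top: list[str]
    metrics: pd.DataFrame = field(repr=False)
    correlations: pd.DataFrame | None = None


def _hub_scores(g: nx.Graph, tol: float = 1e-8, max_iter: int = 10_000) -> pd.Series:
    """HITS hub scores, max-normalised to [0, 1].

    For an undirected graph the hub vector is the principal eigenvector of
    the adjacency matrix; computed by power iteration to ``tol``.
    """
    nodes = sorted(g.nodes)
    if g.number_of_edges() == 0:
        return pd.Series(0.0, index=nodes)
    a = nx.to_numpy_array(g, nodelist=nodes, weight=None)
    x = np.full(len(nodes), 1.0 / len(nodes))
    for _ in range(max_iter):
        y = a @ x
        norm = y.max()
        if norm == 0:
            return pd.Series(0.0, index=nodes)
        y /= norm
        if np.abs(y - x).sum() < tol:
            x = y
            break
        x = y
    else:  # pragma: no cover - convergence guard
        log.warning("hub power iteration hit max_iter=%d", max_iter)
    return pd.Series(x / x.max(), index=nodes)


def node_metrics(g: nx.Graph) -> pd.DataFrame:
    """Degree, unnormalised betweenness, hub score and closeness per node.

    Betweenness uses the undirected convention (each unordered pair counted
    once).  Closeness is computed within each node's connected component.
    """
    if g.number_of_nodes() < 2:
        raise ValueError("node metrics need at least 2 nodes")
    betw = nx.betweenness_centrality(g, normalized=False)
    close = nx.closeness_centrality(g)
    hub = _hub_scores(g)
    out = pd.DataFrame(
        {
            "degree": pd.Series(dict(g.degree())),
            "betweenness": pd.Series(betw),
            "hub": hub,
            "closeness": pd.Series(close),
        }
    ).loc[sorted(g.nodes)]
    out.index.name = "node"
    return out


def _top(metrics: pd.DataFrame, by: str, n: int) -> list[str]:
    df = metrics.reset_index(names="node")
    df = df.sort_values([by, "degree", "node"], ascending=[False, False, True], kind="mergesort")
    return list(df["node"].iloc[:n])


def keystones(metrics: pd.DataFrame, n_top: int = 5) -> KeystoneReport:
    """Union of top-``n_top`` hub and top-``n_top`` betweenness nodes.

    Ties break by (metric desc, degree desc, id asc).  The core taxon is the
    keystone with the highest degree; degree ties go to the higher
    betweenness, then lexicographic id.
    """
    if len(metrics) < n_top:
        log.warning("only %d nodes; keystone lists truncated", len(metrics))
        n_top = len(metrics)
    hub_top = _top(metrics, "hub", n_top)
    betw_top = _top(metrics, "betweenness", n_top)
    keyset = sorted(set(hub_top) | set(betw_top))
    sub = metrics.loc[keyset].reset_index(names="node")
    sub = sub.sort_values(
        ["degree", "betweenness", "node"], ascending=[False, False, True], kind="mergesort"
    )
    core = str(sub["node"].iloc[0])
    return KeystoneReport(
        keystone=keyset, core=core, hub_top=hub_top, betweenness_top=betw_top,
        metrics=metrics.loc[keyset],
    )


def keystone_avd_correlation(
    dt: DifferenceTable, taxa, avd_series: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Spearman rho/p of each taxon's D-value series against an AVD series.

    ``avd_series`` is indexed by pair label (see
    :func:`bacstab.avd.paired_avd_series`).  Constant series are flagged with
    NaN; ``significant`` is False at p >= ``alpha`` (reported, not dropped).
    """
    y = avd_series.reindex(dt.labels).to_numpy(dtype=float)
    if len(y) < 5 or np.isnan(y).any():
        raise ValueError("AVD series must cover >= 5 pairs of the difference table")
    rows = {}
    for taxon in taxa:
        if taxon not in dt.data.index:
            raise KeyError(f"taxon {taxon!r} absent from difference table")
        x = dt.data.loc[taxon].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows[taxon] = dict(rho=np.nan, p=np.nan, significant=False)
            continue
        res = stats.spearmanr(x, y)
        rows[taxon] = dict(
            rho=float(res.statistic), p=float(res.pvalue),
            significant=bool(res.pvalue < alpha),
        )
    out = pd.DataFrame(rows).T
    out.index.name = "taxon"
    return out
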