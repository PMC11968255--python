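"""Signed co-occurrence networks from thresholded Spearman correlation.

Edges connect entity pairs whose Spearman rho exceeds a magnitude threshold
(strictly, |rho| > r_min) at p < p_max (two-sided, t-approximation).  The
resulting simple undirected graph keeps rho as the edge weight and its sign
as an attribute; whole-network topology (avgK, avgCC, APD, modularity,
graph density, negative-edge ratio) is computed on the unweighted skeleton.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats, special

log = logging.getLogger(__name__)

__all__ = [
    "AssociationMatrix",
    "TopologySummary",
    "spearman_matrix",
    "build_network",
    "detect_modules",
    "topology",
    "average_path_distance",
    "module_composition",
]


@dataclass
class AssociationMatrix:
    """Pairwise Spearman correlations with two-sided p-values.

    Zero-variance entities get NaN rho/p against all partners.
    """

    entities: list[str]
    rho: np.ndarray
    p: np.ndarray
    n_obs: int


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    avg_k: float
    avg_cc: float
    apd: float  # NaN for edgeless graphs (undefined, flagged)
    modularity_q: float
    gd: float
    negative_ratio: float
    n_modules: int = 0
    connected: bool = True

    def as_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "avgK": self.avg_k,
            "avgCC": self.avg_cc,
            "APD": self.apd,
            "modularity": self.modularity_q,
            "GD": self.gd,
            "negative_ratio": self.negative_ratio,
            "n_modules": self.n_modules,
            "connected": self.connected,
        }


def spearman_matrix(m: pd.DataFrame, min_obs: int = 5) -> AssociationMatrix:
    """All-pairs Spearman rho/p for a (entities x observations) frame.

    Ties receive average ranks; p-values use the usual t-distribution
    approximation on n-2 degrees of freedom (|rho| = 1 maps to p = 0).
    Fewer than ``min_obs`` observations is an error: the p-values would be
    meaningless at the thresholds used downstream.
    """
    values = m.to_numpy(dtype=float)
    n_ent, n_obs = values.shape
    if n_obs < min_obs:
        raise ValueError(f"need at least {min_obs} observations, got {n_obs}")
    ranks = stats.rankdata(values, axis=1)
    sd = ranks.std(axis=1)
    constant = sd == 0
    if constant.any():
        log.warning("%d zero-variance entities flagged (NaN correlations)", int(constant.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    rho = np.clip(rho, -1.0, 1.0)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t2 = rho * rho * (n_obs - 2) / (1.0 - rho * rho)
        p = special.betainc(0.5 * (n_obs - 2), 0.5, 1.0 / (1.0 + t2 / (n_obs - 2)))
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    p[np.isnan(rho)] = np.nan
    np.fill_diagonal(p, 0.0)
    return AssociationMatrix(entities=list(m.index), rho=rho, p=p, n_obs=n_obs)


def spearman_pvalue_permutation(x, y, n_perm: int = 10000, seed: int = 0) -> float:
    """Permutation two-sided p for one pair; preferable below ~10 observations."""
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    obs = abs(stats.spearmanr(x, y).statistic)
    hits = sum(
        abs(stats.spearmanr(x, rng.permutation(y)).statistic) >= obs - 1e-12
        for _ in range(n_perm)
    )
    return (hits + 1) / (n_perm + 1)


def build_network(
    a: AssociationMatrix,
    r_min: float = 0.6,
    p_max: float = 0.01,
    keep_isolated: bool = True,
    node_attrs: pd.DataFrame | None = None,
    fdr: bool = False,
) -> nx.Graph:
    """Threshold an association matrix into a signed co-occurrence graph.

    Edge (u, v) exists iff |rho| > r_min (strict) and p < p_max (strict).
    Isolated entities stay in the graph unless ``keep_isolated`` is False.
    With ``fdr=True`` the p threshold is applied to Benjamini-Hochberg
    adjusted pairwise p-values instead of raw ones (off by default: the
    construction rule is a fixed raw-p threshold).
    """
    if not (0 < r_min <= 1) or not (0 < p_max <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    g = nx.Graph()
    ids = a.entities
    order = np.argsort(np.asarray(ids, dtype=object))
    rho, p = a.rho, a.p
    if fdr:
        p = _bh_adjust_symmetric(p)
    n = len(ids)
    with np.errstate(invalid="ignore"):
        mask = (np.abs(rho) > r_min) & (p < p_max)
    mask &= ~np.isnan(rho)
    np.fill_diagonal(mask, False)
    # node order deterministic by id regardless of entity order
    for i in order:
        g.add_node(ids[i])
    ii, jj = np.where(np.triu(mask, k=1))
    for i, j in zip(ii, jj):
        u, v = sorted((ids[i], ids[j]))
        w = float(rho[i, j])
        g.add_edge(u, v, weight=w, rho=w, p=float(p[i, j]), sign="+" if w > 0 else "-")
    if node_attrs is not None:
        for col in node_attrs.columns:
            vals = node_attrs[col]
            for node in g.nodes:
                if node in vals.index:
                    g.nodes[node][col] = vals.loc[node]
    if not keep_isolated:
        isolated = [v for v, d in g.degree() if d == 0]
        if isolated:
            log.info("dropping %d isolated nodes", len(isolated))
        g.remove_nodes_from(isolated)
    return g


def _bh_adjust_symmetric(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjustment over the upper-triangle p-values."""
    from statsmodels.stats.multitest import multipletests

    n = p.shape[0]
    iu = np.triu_indices(n, k=1)
    raw = p[iu]
    adj = np.full_like(raw, np.nan)
    ok = ~np.isnan(raw)
    if ok.any():
        adj[ok] = multipletests(raw[ok], method="fdr_bh")[1]
    out = np.zeros_like(p)
    out[iu] = adj
    out = out + out.T
    return out


def detect_modules(g: nx.Graph, seed: int = 0, resolution: float = 1.0):
    """Seeded Louvain partition of the unweighted graph.

    Returns (node -> module id, Newman-Girvan modularity Q of the partition).
    Modules are labelled 1, 2, ... by decreasing size (ties by smallest
    member id) for deterministic output.
    """
    if g.number_of_edges() < 1:
        raise ValueError("module detection needs at least one edge")
    comms = nx.community.louvain_communities(g, weight=None, resolution=resolution, seed=seed)
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    q = nx.community.modularity(g, comms, weight=None, resolution=resolution)
    partition = {node: i + 1 for i, c in enumerate(comms) for node in sorted(c)}
    return partition, float(q)


def average_path_distance(g: nx.Graph) -> tuple[float, bool]:
    """Mean unweighted shortest-path length over connected node pairs.

    Returns (APD, connected flag); NaN when the graph has no connected pair.
    Disconnected pairs are skipped, not infinity-padded.
    """
    total = 0.0
    n_pairs = 0
    for comp in nx.connected_components(g):
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for _, dists in nx.shortest_path_length(sub):
            total += sum(dists.values())
            n_pairs += len(dists) - 1
    if n_pairs == 0:
        return float("nan"), nx.is_connected(g) if g.number_of_nodes() else False
    # each unordered pair counted twice above
    return total / n_pairs, nx.is_connected(g)


def topology(g: nx.Graph, seed: int = 0, partition=None) -> TopologySummary:
    """Whole-network topology on the unweighted skeleton."""
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("topology needs at least 2 nodes")
    m = g.number_of_edges()
    avg_k = 2.0 * m / n
    gd = 2.0 * m / (n * (n - 1))
    avg_cc = nx.average_clustering(g) if m else 0.0
    apd, connected = average_path_distance(g)
    if m >= 1:
        if partition is None:
            partition, q = detect_modules(g, seed=seed)
        else:
            groups: dict[int, set] = {}
            for node, mod in partition.items():
                groups.setdefault(mod, set()).add(node)
            q = float(nx.community.modularity(g, list(groups.values()), weight=None))
        n_modules = len(set(partition.values()))
    else:
        q, n_modules = float("nan"), 0
    neg = sum(1 for _, _, d in g.edges(data=True) if d.get("weight", 1) < 0)
    negative_ratio = neg / m if m else float("nan")
    if m and math.isnan(apd):
        log.info("edgeless/fragmented graph: APD undefined")
    return TopologySummary(
        n_nodes=n, n_edges=m, avg_k=avg_k, avg_cc=avg_cc, apd=apd,
        modularity_q=q, gd=gd, negative_ratio=negative_ratio,
        n_modules=n_modules, connected=connected,
    )


def module_composition(g: nx.Graph, partition: dict, phylum: pd.Series | None = None) -> pd.DataFrame:
    """Per-module node share of the network and per-phylum node fractions."""
    n = g.number_of_nodes()
    rows = []
    modules = sorted(set(partition.values()))
    for mod in modules:
        members = sorted(node for node, m in partition.items() if m == mod)
        row = {"module": mod, "n_nodes": len(members), "share": len(members) / n}
        if phylum is not None:
            cats = pd.Series(
                [phylum.loc[x] if x in phylum.index else "unclassified" for x in members]
            )
            for cat, frac in (cats.value_counts(normalize=True)).items():
                row[f"frac_{cat}"] = float(frac)
        rows.append(row)
    out = pd.DataFrame(rows).set_index("module").fillna(0.0)
    return out


def export_edge_list(g: nx.Graph, path) -> None:
    """Edge-list TSV: u, v, rho, p, sign."""
    rows = [
        {"u": u, "v": v, "rho": d.get("rho", d.get("weight")), "p": d.get("p"), "sign": d.get("sign")}
        for u, v, d in sorted(g.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["u", "v", "rho", "p", "sign"]).to_csv(path, sep="\t", index=False)


def export_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)
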