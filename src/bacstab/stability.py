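"""Network and community stability: robustness, vulnerability, cohesion.

Three complementary views of stability:

* **Robustness** — the proportion of taxa that survive removal of a fraction
  of nodes (uniformly at random, or targeting the highest-degree nodes
  first), counting secondary extinctions: a node that loses all of its links
  is counted as lost too.
* **Vulnerability** — each node's relative contribution to global efficiency,
  V_i = (E(G) - E(G - i)) / E(G); the network's vulnerability is the maximum
  over nodes.  Global efficiency is the mean inverse shortest-path length
  over all node pairs (disconnected pairs contribute 0).
* **Cohesion** — an abundance-weighted, null-model-corrected sum of pairwise
  correlations: each taxon's connectedness is the mean positive (resp.
  negative) null-corrected Spearman rho to all partners, and per-sample
  cohesion weights connectedness by relative abundance.  The null shuffles
  each taxon's values independently across samples, preserving marginals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core_data import AbundanceTable

log = logging.getLogger(__name__)

__all__ = [
    "RobustnessCurve",
    "VulnerabilityResult",
    "CohesionResult",
    "global_efficiency",
    "vulnerability",
    "robustness",
    "robustness_auc",
    "null_corrected_correlation",
    "cohesion",
]

DEFAULT_FRACTIONS = tuple(np.round(np.arange(0.0, 0.951, 0.05), 2))


@dataclass
class RobustnessCurve:
    strategy: str  # "random" | "targeted_degree"
    curve: pd.DataFrame  # columns: fraction, mean, sd
    n_reps: int
    seed: int


@dataclass
class VulnerabilityResult:
    per_node: pd.Series
    network: float  # max over nodes
    efficiency: float


@dataclass
class CohesionResult:
    connectedness: pd.DataFrame  # index taxon: positive, negative
    samples: pd.DataFrame  # index sample: positive, negative, total
    n_shuffles: int
    seed: int
    excluded_taxa: list[str]
    method: str = "spearman"


def global_efficiency(g: nx.Graph) -> float:
    """Mean of 1/d(u, v) over all unordered node pairs (0 if disconnected)."""
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    total = 0.0
    for _, dists in nx.shortest_path_length(g):
        total += sum(1.0 / d for d in dists.values() if d > 0)
    return total / (n * (n - 1))


def vulnerability(g: nx.Graph) -> VulnerabilityResult:
    """Per-node V_i = (E(G) - E(G - i)) / E(G) and the network maximum."""
    if g.number_of_nodes() < 3:
        raise ValueError("vulnerability needs at least 3 nodes")
    e0 = global_efficiency(g)
    if e0 == 0:
        raise ValueError("global efficiency is 0; vulnerability undefined")
    per = {}
    for node in sorted(g.nodes):
        h = g.copy()
        h.remove_node(node)
        per[node] = (e0 - global_efficiency(h)) / e0
    per_node = pd.Series(per, name="vulnerability")
    return VulnerabilityResult(per_node=per_node, network=float(per_node.max()), efficiency=e0)


def _surviving_fraction(adj: np.ndarray, had_edges: np.ndarray, removed: np.ndarray) -> float:
    """Fraction of nodes surviving removal plus secondary extinction.

    Nodes isolated in the original graph never count as secondary
    extinctions; only nodes that lose all their links do.
    """
    n = adj.shape[0]
    alive = ~removed
    while True:
        deg = adj[:, alive].sum(axis=1)
        dead = alive & had_edges & (deg == 0)
        if not dead.any():
            break
        alive &= ~dead
    return alive.sum() / n


def robustness(
    g: nx.Graph,
    strategy: str = "random",
    fractions=DEFAULT_FRACTIONS,
    n_reps: int = 100,
    seed: int = 0,
    secondary_extinction: bool = True,
) -> RobustnessCurve:
    """Remaining-taxa curve under node removal with secondary extinction.

    At each fraction f, ceil(f * N) nodes are removed — uniformly at random
    (averaged over ``n_reps`` seeded repetitions) or by descending degree
    with lexicographic id tie-break (deterministic, n_reps forced to 1) —
    then nodes left without any edge are iteratively dropped.
    """
    if strategy not in ("random", "targeted_degree"):
        raise ValueError(f"unknown strategy {strategy!r}")
    nodes = sorted(g.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("empty graph")
    fractions = [float(f) for f in fractions]
    if any(f < 0 or f >= 1 for f in fractions):
        raise ValueError("fractions must lie in [0, 1)")
    adj = nx.to_numpy_array(g, nodelist=nodes, weight=None).astype(bool)
    had_edges = adj.any(axis=1)
    if strategy == "targeted_degree":
        n_reps = 1
        deg = adj.sum(axis=1)
        order = sorted(range(n), key=lambda i: (-deg[i], nodes[i]))
        orders = [np.asarray(order)]
    else:
        rng = np.random.default_rng(seed)
        orders = [rng.permutation(n) for _ in range(n_reps)]
    rows = []
    for f in fractions:
        m = math.ceil(f * n)
        vals = []
        for order in orders:
            removed = np.zeros(n, dtype=bool)
            removed[order[:m]] = True
            if secondary_extinction:
                vals.append(_surviving_fraction(adj, had_edges, removed))
            else:
                vals.append((~removed).sum() / n)
        rows.append(
            {"fraction": f, "mean": float(np.mean(vals)),
             "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0}
        )
    return RobustnessCurve(strategy=strategy, curve=pd.DataFrame(rows), n_reps=n_reps, seed=seed)


def robustness_auc(curve: RobustnessCurve) -> float:
    """Area under the remaining-proportion curve (trapezoid over fractions)."""
    c = curve.curve
    return float(np.trapezoid(c["mean"], c["fraction"]))


def _rank_corr(values: np.ndarray, method: str) -> np.ndarray:
    if method == "spearman":
        values = stats.rankdata(values, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values)
    return np.clip(r, -1.0, 1.0)


def null_corrected_correlation(
    values: np.ndarray, n_shuffles: int = 500, seed: int = 0, method: str = "spearman"
) -> np.ndarray:
    """Observed minus null-mean pairwise correlation (taxa x samples input).

    The null permutes each taxon's values independently across samples
    (fresh seeded permutation per taxon per iteration), preserving each
    taxon's marginal distribution while destroying alignment.
    """
    if n_shuffles < 50:
        raise ValueError("need n_shuffles >= 50 for a usable null")
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    obs = _rank_corr(values, method)
    rng = np.random.default_rng(seed)
    null_sum = np.zeros_like(obs)
    for _ in range(n_shuffles):
        perm = np.argsort(rng.random((m, n)), axis=1)
        shuffled = np.take_along_axis(values, perm, axis=1)
        null_sum += _rank_corr(shuffled, method)
    corrected = obs - null_sum / n_shuffles
    np.fill_diagonal(corrected, 0.0)
    return corrected


def cohesion(
    t: AbundanceTable,
    n_shuffles: int = 500,
    seed: int = 0,
    method: str = "spearman",
    partner_threshold: float = 0.0,
) -> CohesionResult:
    """Per-sample positive/negative/total cohesion with per-taxon connectedness.

    Connectedness averages the positive (resp. negative) null-corrected
    correlations over all m-1 partners (zeros included); per-sample cohesion
    is the relative-abundance-weighted sum over taxa, and total cohesion is
    positive + |negative|.  Constant taxa are flagged and excluded.  A
    nonzero ``partner_threshold`` restricts connectedness to partners with
    |corrected rho| above it (threshold-filtered variant).
    """
    if t.mode != "relative":
        raise ValueError("cohesion expects a relative-abundance table (use to_relative)")
    if t.data.shape[1] < 5:
        raise ValueError("cohesion needs at least 5 samples")
    values = t.data.to_numpy(dtype=float)
    taxa = np.asarray(t.taxa, dtype=object)
    variable = values.std(axis=1) > 0
    excluded = list(taxa[~variable])
    if excluded:
        log.warning("cohesion: %d constant taxa excluded", len(excluded))
    sub = values[variable]
    corrected = null_corrected_correlation(sub, n_shuffles=n_shuffles, seed=seed, method=method)
    if partner_threshold > 0:
        corrected = np.where(np.abs(corrected) > partner_threshold, corrected, 0.0)
    m = corrected.shape[0]
    if m < 2:
        raise ValueError("cohesion needs at least 2 variable taxa")
    pos = np.where(corrected > 0, corrected, 0.0).sum(axis=1) / (m - 1)
    neg = np.where(corrected < 0, corrected, 0.0).sum(axis=1) / (m - 1)
    connectedness = pd.DataFrame(
        {"positive": pos, "negative": neg}, index=pd.Index(taxa[variable], name="taxon")
    )
    c_pos = sub.T @ pos
    c_neg = sub.T @ neg
    samples = pd.DataFrame(
        {"positive": c_pos, "negative": c_neg, "total": c_pos + np.abs(c_neg)},
        index=pd.Index(t.samples, name="sample_id"),
    )
    return CohesionResult(
        connectedness=connectedness, samples=samples, n_shuffles=n_shuffles,
        seed=seed, excluded_taxa=excluded, method=method,
    )
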