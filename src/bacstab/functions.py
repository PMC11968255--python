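"""KEGG KO functional-trait tables, classification, networks and regressions.

Function read tables (KO level 2 or level 3) travel through the same D-value
machinery as taxa; functional co-occurrence networks use the stricter
|rho| > 0.75, p < 0.01 rule.  Functions are classified as *broad* (widely
shared housekeeping metabolism) or *specialized* (taxonomically restricted,
e.g. nitrogen/sulfur metabolism, atrazine degradation) from a shipped,
editable YAML list.  Ordinary least squares of AVD on function D-abundance
reports each function's direction of effect on stability (a positive slope
means enhancing the function raises AVD, i.e. destabilises), and a seeded
permutation importance ranks candidate drivers.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import netbuild
from .core_data import AbundanceTable, DifferenceTable, SampleDesign, d_values

log = logging.getLogger(__name__)

__all__ = [
    "FunctionTable",
    "FunctionClassLists",
    "load_class_lists",
    "classify_functions",
    "functional_network",
    "function_avd_regression",
    "permutation_importance",
]


@dataclass
class FunctionTable:
    """Function-by-sample read counts at one KO level, with class labels."""

    data: pd.DataFrame  # function name index x samples
    level: int  # 2 or 3
    classes: pd.Series | None = field(default=None, repr=False)  # broad|specialized|unclassified

    def __post_init__(self) -> None:
        if self.level not in (2, 3):
            raise ValueError("KO level must be 2 or 3")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate function names")
        if (self.data.to_numpy(dtype=float) < 0).any():
            raise ValueError("negative function reads")

    @property
    def functions(self) -> list[str]:
        return list(self.data.index)

    def as_abundance_table(self) -> AbundanceTable:
        return AbundanceTable(self.data, mode="counts" if _integral(self.data) else "relative")


def _integral(df: pd.DataFrame) -> bool:
    v = df.to_numpy(dtype=float)
    return bool(np.allclose(v, np.round(v)))


@dataclass(frozen=True)
class FunctionClassLists:
    broad_l2: tuple[str, ...]
    broad_l3: tuple[str, ...]
    specialized_l3: tuple[str, ...]

    def __post_init__(self) -> None:
        lower = lambda xs: {x.lower() for x in xs}
        sets = [lower(self.broad_l2), lower(self.broad_l3), lower(self.specialized_l3)]
        if len(sets[0] | sets[1] | sets[2]) != sum(map(len, sets)):
            raise ValueError("class lists must be disjoint")

    def classify(self, name: str, level: int) -> str:
        key = name.strip().lower()
        if level == 2:
            return "broad" if key in {x.lower() for x in self.broad_l2} else "unclassified"
        if key in {x.lower() for x in self.broad_l3}:
            return "broad"
        if key in {x.lower() for x in self.specialized_l3}:
            return "specialized"
        return "unclassified"


def load_class_lists(path=None) -> FunctionClassLists:
    """Load the broad/specialized lists (package default or a user YAML)."""
    if path is None:
        text = resources.files("bacstab.data").joinpath("function_classes.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return FunctionClassLists(
        broad_l2=tuple(raw["broad_l2"]),
        broad_l3=tuple(raw["broad_l3"]),
        specialized_l3=tuple(raw["specialized_l3"]),
    )


def read_function_table(path, level: int) -> FunctionTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return FunctionTable(df, level=level)


def classify_functions(ft: FunctionTable, lists: FunctionClassLists | None = None) -> FunctionTable:
    """Populate the class column; unknown names become 'unclassified'."""
    lists = lists or load_class_lists()
    classes = pd.Series(
        {name: lists.classify(name, ft.level) for name in ft.functions}, name="class"
    )
    unknown = int((classes == "unclassified").sum())
    if unknown:
        log.info("classify_functions: %d of %d functions unclassified", unknown, len(classes))
    return replace(ft, classes=classes)


def functional_network(
    ft: FunctionTable,
    design: SampleDesign,
    r_min: float = 0.75,
    p_max: float = 0.01,
    keep_isolated: bool = False,
    seed: int = 0,
):
    """Functional co-occurrence network on per-pair D-values of read fractions.

    Returns (graph, TopologySummary, core_functions) where the core
    functions are the nodes of maximal degree (all ties reported).
    """
    rel = ft.data.div(ft.data.sum(axis=0), axis=1)
    abt = AbundanceTable(rel, mode="relative")
    dt = d_values(abt, design)
    assoc = netbuild.spearman_matrix(dt.data)
    attrs = ft.classes.to_frame("class") if ft.classes is not None else None
    g = netbuild.build_network(assoc, r_min=r_min, p_max=p_max,
                               keep_isolated=keep_isolated, node_attrs=attrs)
    if g.number_of_nodes() < 2:
        return g, None, []
    topo = netbuild.topology(g, seed=seed)
    degrees = dict(g.degree())
    if degrees:
        kmax = max(degrees.values())
        core = sorted(n for n, k in degrees.items() if k == kmax and kmax > 0)
    else:
        core = []
    return g, topo, core


def function_avd_regression(dt: DifferenceTable, avd_series: pd.Series) -> pd.DataFrame:
    """OLS of AVD on each function's D-value series.

    Positive slope = enhancing the function decreases stability (raises
    AVD).  Constant functions are flagged with NaN.
    """
    y = avd_series.reindex(dt.labels).to_numpy(dtype=float)
    if len(y) < 5 or np.isnan(y).any():
        raise ValueError("AVD series must cover >= 5 pairs of the difference table")
    rows = {}
    for fn in dt.entities:
        x = dt.data.loc[fn].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows[fn] = dict(slope=np.nan, intercept=np.nan, r=np.nan, p=np.nan)
            continue
        lr = stats.linregress(x, y)
        rows[fn] = dict(slope=lr.slope, intercept=lr.intercept, r=lr.rvalue, p=lr.pvalue)
    out = pd.DataFrame(rows).T
    out.index.name = "function"
    out["destabilizing"] = (out["slope"] > 0) & (out["p"] < 0.05)
    return out


def permutation_importance(
    dt: DifferenceTable | pd.DataFrame,
    avd_series: pd.Series,
    n_perm: int = 100,
    seed: int = 0,
    ridge: float = 1e-8,
) -> pd.Series:
    """Permutation importance of each function for a linear AVD model.

    Fits least squares of AVD on all candidate function D-series jointly;
    the importance of function j is the mean increase in residual sum of
    squares when column j is permuted (seeded), normalised to sum to 100%.
    Near-singular designs fall back to a ridge-regularised solve.
    """
    x_frame = dt.data if isinstance(dt, DifferenceTable) else dt
    names = list(x_frame.index)
    if len(names) < 1:
        raise ValueError("need at least one candidate function")
    x = x_frame.to_numpy(dtype=float).T  # observations x functions
    y = avd_series.reindex(list(x_frame.columns)).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("AVD series must cover every observation column")
    xd = np.column_stack([np.ones(len(y)), x])
    gram = xd.T @ xd
    try:
        beta = np.linalg.solve(gram, xd.T @ y)
        if np.linalg.cond(gram) > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        log.warning("collinear design; using ridge-regularised fit (lambda=%g)", ridge)
        beta = np.linalg.solve(gram + ridge * np.eye(gram.shape[0]), xd.T @ y)
    rss0 = float(((y - xd @ beta) ** 2).sum())
    raw = np.zeros(len(names))
    for j, name in enumerate(names):
        # per-column stream keyed by name, so the ranking is invariant to
        # predictor order
        rng = np.random.default_rng([seed, zlib.crc32(str(name).encode())])
        inc = 0.0
        for _ in range(n_perm):
            xp = xd.copy()
            xp[:, j + 1] = rng.permutation(xp[:, j + 1])
            inc += float(((y - xp @ beta) ** 2).sum()) - rss0
        raw[j] = inc / n_perm
    raw = np.clip(raw, 0.0, None)
    if raw.sum() == 0:
        raw[:] = 1.0
    out = pd.Series(100.0 * raw / raw.sum(), index=pd.Index(names, name="function"),
                    name="importance_pct")
    return out.sort_values(ascending=False, kind="mergesort")
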