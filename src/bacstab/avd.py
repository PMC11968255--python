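"""Average variation degree (AVD): a replicate-group community stability index.

For each taxon *i* within a group of *k* replicate samples, the variation
degree of sample *s* is the standardised deviation

    a_i(s) = (x_i(s) - xbar_i) / delta_i,

with ``delta_i`` the (sample, ddof=1 by default) standard deviation across the
group.  AVD pools the absolute variation degrees over the *n* taxa with
``delta_i > 0``:

    AVD = sum_i sum_s |a_i(s)| / (k * n).

Lower AVD means the replicates agree better, i.e. a more stable community.
Taxa with zero within-group variance are excluded from both the numerator and
*n* (the ratio is undefined at delta = 0) and reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import AbundanceTable, DifferenceTable, SampleDesign

__all__ = [
    "AVDResult",
    "variation_degree",
    "avd",
    "avd_by_group",
    "sample_variation_series",
    "paired_avd_series",
    "avd_vs_diversity",
]


@dataclass
class AVDResult:
    group_id: str
    avd: float
    k: int
    n: int
    per_taxon: pd.DataFrame  # index taxon: mean, sd, mean_abs_a
    excluded_taxa: list[str]
    ddof: int = 1

    def recompute(self) -> float:
        """Re-evaluate AVD from the per-taxon records (consistency check)."""
        return float(self.per_taxon["mean_abs_a"].sum() * self.k / (self.k * self.n))


def variation_degree(x, ddof: int = 1):
    """Per-sample standardised deviations of one taxon across a group.

    Returns an array of (x - mean)/sd, or ``None`` when the group variance is
    zero (the degree is undefined there, flagged rather than zero-filled).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("variation degree needs at least 2 samples")
    sd = x.std(ddof=ddof)
    if sd == 0:
        return None
    return (x - x.mean()) / sd


def avd(t: AbundanceTable, group, group_id: str = "", ddof: int = 1) -> AVDResult:
    """AVD of one replicate group (columns ``group`` of table ``t``)."""
    group = list(group)
    if len(group) < 2:
        raise ValueError("AVD needs a group of k >= 2 samples")
    x = t.data[group].to_numpy(dtype=float)
    k = x.shape[1]
    means = x.mean(axis=1)
    sds = x.std(axis=1, ddof=ddof)
    usable = sds > 0
    if not usable.any():
        raise ValueError(f"group {group_id!r}: no taxa with nonzero variance")
    a = np.abs(x[usable] - means[usable, None]) / sds[usable, None]
    n = int(usable.sum())
    value = float(a.sum() / (k * n))
    per_taxon = pd.DataFrame(
        {
            "mean": means[usable],
            "sd": sds[usable],
            "mean_abs_a": a.mean(axis=1),
        },
        index=pd.Index(np.asarray(t.taxa, dtype=object)[usable], name="taxon"),
    )
    excluded = list(np.asarray(t.taxa, dtype=object)[~usable])
    return AVDResult(group_id=group_id, avd=value, k=k, n=n,
                     per_taxon=per_taxon, excluded_taxa=excluded, ddof=ddof)


def avd_by_group(t: AbundanceTable, design: SampleDesign, ddof: int = 1) -> list[AVDResult]:
    """AVD per (site, stage) replicate group and per whole site.

    The per-stage groups are the collection units (k = 9 replicates); the
    site-level values (k = 36) mirror site-wise stability comparisons.
    """
    results = [avd(t, ids, group_id=gid, ddof=ddof) for gid, ids in design.groups().items()]
    for site in sorted(set(design.frame["site"])):
        results.append(avd(t, design.samples(site=site), group_id=site, ddof=ddof))
    return results


def sample_variation_series(t: AbundanceTable, group, ddof: int = 1) -> pd.Series:
    """Per-sample mean absolute variation degree within a replicate group.

    For sample j the value is mean_i |a_i(j)| over the taxa with nonzero
    within-group variance — the per-sample slice of the AVD sum, so the
    group AVD is exactly the mean of this series.  It serves as a
    per-sample instability score: a disturbed replicate contributes large
    standardised deviations across many taxa at once.
    """
    group = list(group)
    if len(group) < 2:
        raise ValueError("variation series needs a group of k >= 2 samples")
    x = t.data[group].to_numpy(dtype=float)
    sds = x.std(axis=1, ddof=ddof)
    usable = sds > 0
    if not usable.any():
        raise ValueError("no taxa with nonzero variance in group")
    z = np.abs(x[usable] - x[usable].mean(axis=1, keepdims=True)) / sds[usable, None]
    return pd.Series(z.mean(axis=0), index=group, name="mean_abs_variation")


def paired_avd_series(t: AbundanceTable, design: SampleDesign, ddof: int = 1) -> pd.Series:
    """Per-pair instability-difference series (site A minus site B).

    Per-sample mean |a_i| scores are computed within each (site, stage)
    replicate group and differenced across the matched (stage, replicate)
    pairs, yielding one stability-difference value per D-value column —
    the series correlated against keystone or function D-abundances.
    """
    pv = {}
    for gid, ids in design.groups().items():
        pv.update(sample_variation_series(t, ids, ddof=ddof).to_dict())
    pairs = design.matched_pairs()
    values = [pv[a] - pv[b] for a, b in zip(pairs["sample_a"], pairs["sample_b"])]
    return pd.Series(values, index=list(pairs["label"]), name="avd_d")


def avd_vs_diversity(avd_values, div: pd.DataFrame) -> pd.DataFrame:
    """Regress each diversity index against AVD over paired observations.

    ``avd_values``: sequence of AVD values (one per group/sample) aligned with
    the rows of ``div`` (a diversity-index frame aggregated to the same
    groups).  Returns slope, intercept, Pearson r, Spearman rho and two-sided
    p-values per index; degenerate (constant) columns are flagged with NaN.
    """
    y = np.asarray(avd_values, dtype=float)
    if y.size != len(div) or y.size < 3:
        raise ValueError("need >= 3 paired AVD/diversity observations")
    rows = {}
    for col in div.columns:
        x = div[col].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows[col] = dict(slope=0.0 if np.ptp(y) == 0 else np.nan,
                             intercept=np.nan, pearson_r=np.nan, p_pearson=np.nan,
                             spearman_rho=np.nan, p_spearman=np.nan)
            continue
        lr = stats.linregress(x, y)
        sp = stats.spearmanr(x, y)
        rows[col] = dict(slope=lr.slope, intercept=lr.intercept,
                         pearson_r=lr.rvalue, p_pearson=lr.pvalue,
                         spearman_rho=float(sp.statistic), p_spearman=float(sp.pvalue))
    out = pd.DataFrame(rows).T
    out.index.name = "index"
    return out
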