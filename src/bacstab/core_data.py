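"""Tables, sample designs, paired site differences and alpha diversity.

The whole analysis operates on genus- (or function-) by-sample tables bound
to a two-site, multi-stage, replicated sampling design.  This module owns the
in-memory containers (:class:`AbundanceTable`, :class:`SampleDesign`,
:class:`DifferenceTable`), TSV I/O, relative-abundance normalisation,
top-N aggregation with an explicit remainder group, paired site differences
("D-values") and the usual alpha-diversity indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skbio.diversity.alpha import ace as _skbio_ace
from skbio.diversity.alpha import chao1 as _skbio_chao1

log = logging.getLogger(__name__)

SITES = ("A", "B")

__all__ = [
    "SampleDesign",
    "AbundanceTable",
    "DifferenceTable",
    "read_abundance_table",
    "write_abundance_table",
    "read_design",
    "read_taxonomy",
    "to_relative",
    "top_n_with_remainder",
    "d_values",
    "diversity",
]


@dataclass(frozen=True)
class SampleDesign:
    """Sample metadata: one row per sample with site, growth stage, replicate.

    Sites are coded ``A``/``B`` (the two wetlands), stages ``1..4`` (green
    leaf, yellow leaf, withering, fully withered), replicates ``1..R`` within
    each (site, stage) group.
    """

    frame: pd.DataFrame  # columns: sample_id, site, stage, replicate

    def __post_init__(self) -> None:
        required = ["sample_id", "site", "stage", "replicate"]
        missing = [c for c in required if c not in self.frame.columns]
        if missing:
            raise ValueError(f"design is missing columns: {missing}")
        df = self.frame.copy()
        df["sample_id"] = df["sample_id"].astype(str)
        df["site"] = df["site"].astype(str)
        df["stage"] = df["stage"].astype(int)
        df["replicate"] = df["replicate"].astype(int)
        bad_sites = sorted(set(df["site"]) - set(SITES))
        if bad_sites:
            raise ValueError(f"unknown site codes {bad_sites}; expected {SITES}")
        if df["sample_id"].duplicated().any():
            dups = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
            raise ValueError(f"duplicate sample ids in design: {dups}")
        trip = df[["site", "stage", "replicate"]]
        if trip.duplicated().any():
            raise ValueError("duplicate (site, stage, replicate) triples in design")
        object.__setattr__(self, "frame", df.reset_index(drop=True))

    @classmethod
    def from_tsv(cls, path) -> "SampleDesign":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def samples(self, site: str | None = None, stage: int | None = None) -> list[str]:
        df = self.frame
        if site is not None:
            df = df[df["site"] == site]
        if stage is not None:
            df = df[df["stage"] == stage]
        return list(df["sample_id"])

    def groups(self) -> dict[str, list[str]]:
        """Per-(site, stage) replicate groups, keyed like ``A1`` .. ``B4``."""
        out: dict[str, list[str]] = {}
        for (site, stage), sub in self.frame.groupby(["site", "stage"], sort=True):
            out[f"{site}{stage}"] = list(sub["sample_id"])
        return out

    def matched_pairs(self) -> pd.DataFrame:
        """Match site-A and site-B samples by (stage, replicate).

        Returns a frame with columns stage, replicate, sample_a, sample_b,
        label; unmatched combinations are excluded with a logged warning.
        """
        df = self.frame
        a = df[df["site"] == "A"].set_index(["stage", "replicate"])["sample_id"]
        b = df[df["site"] == "B"].set_index(["stage", "replicate"])["sample_id"]
        common = a.index.intersection(b.index).sortlevel()[0]
        dropped = a.index.symmetric_difference(b.index)
        if len(dropped):
            log.warning("excluding %d unmatched (stage, replicate) combinations", len(dropped))
        if not len(common):
            raise ValueError("no matched (stage, replicate) pairs between sites")
        out = pd.DataFrame(
            {
                "stage": [s for s, _ in common],
                "replicate": [r for _, r in common],
                "sample_a": [a.loc[key] for key in common],
                "sample_b": [b.loc[key] for key in common],
            }
        )
        out["label"] = [f"S{s}R{r}" for s, r in zip(out["stage"], out["replicate"])]
        return out


@dataclass
class AbundanceTable:
    """Taxon-by-sample matrix of counts or relative abundances.

    ``data`` holds taxa as rows (index = taxon id) and samples as columns.
    ``lineage`` optionally maps taxon id to a semicolon-delimited 7-rank
    lineage string; :meth:`phylum` extracts the phylum rank from it.
    """

    data: pd.DataFrame
    mode: str = "counts"  # "counts" | "relative"
    lineage: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "relative"):
            raise ValueError(f"mode must be 'counts' or 'relative', got {self.mode!r}")
        if self.data.index.duplicated().any():
            dups = sorted(self.data.index[self.data.index.duplicated()])
            raise ValueError(f"duplicate taxon ids: {dups}")
        values = self.data.to_numpy(dtype=float)
        if np.any(values < 0):
            taxon = self.data.index[np.where(values < 0)[0][0]]
            raise ValueError(f"negative abundance for taxon {taxon!r}")
        if self.mode == "relative":
            sums = values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                bad = self.data.columns[np.argmax(np.abs(sums - 1.0))]
                raise ValueError(f"relative-mode column {bad!r} does not sum to 1")

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def subset_samples(self, sample_ids) -> "AbundanceTable":
        return replace(self, data=self.data[list(sample_ids)])

    def phylum(self, taxon: str) -> str:
        """Phylum rank from the lineage, or 'unclassified' when absent."""
        if self.lineage is None or taxon not in self.lineage.index:
            return "unclassified"
        ranks = [r.strip() for r in str(self.lineage.loc[taxon]).split(";")]
        for r in ranks:
            if r.startswith("p__"):
                return r[3:] or "unclassified"
        return ranks[1] if len(ranks) > 1 and ranks[1] else "unclassified"

    def phylum_map(self) -> pd.Series:
        return pd.Series({t: self.phylum(t) for t in self.taxa}, name="phylum")


@dataclass
class DifferenceTable:
    """Per-(stage, replicate) paired site-A-minus-site-B differences."""

    data: pd.DataFrame  # entities x pair labels
    pairs: pd.DataFrame  # columns: stage, replicate, sample_a, sample_b, label

    @property
    def entities(self) -> list[str]:
        return list(self.data.index)

    @property
    def labels(self) -> list[str]:
        return list(self.data.columns)


def read_abundance_table(path, design: SampleDesign, lineage: pd.Series | None = None) -> AbundanceTable:
    """Read a taxon-by-sample TSV (row 1 = sample ids, column 1 = taxon ids).

    Mode is ``counts`` when every entry is integral, else ``relative``.
    Samples absent from the design are rejected.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise ValueError(f"malformed TSV {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    unknown = sorted(set(df.columns) - set(design.sample_ids))
    if unknown:
        raise ValueError(f"samples not present in design: {unknown}")
    values = df.to_numpy(dtype=float)
    mode = "counts" if np.allclose(values, np.round(values)) else "relative"
    if mode == "relative":
        sums = values.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            # real-valued but not closed: keep as relative after renormalising?
            # No -- refuse silent rescaling; caller should use to_relative().
            raise ValueError(
                "non-integer table whose columns do not sum to 1; "
                "read counts or pass the table through to_relative()"
            )
    return AbundanceTable(df, mode=mode, lineage=lineage)


def write_abundance_table(t: AbundanceTable, path) -> None:
    """Write TSV at full float precision (exact value round-trip)."""
    t.data.to_csv(path, sep="\t", index_label="taxon_id")


def read_design(path) -> SampleDesign:
    return SampleDesign.from_tsv(path)


def read_taxonomy(path) -> pd.Series:
    """Taxonomy TSV: taxon_id <tab> semicolon-delimited lineage."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(str)


def rarefy(t: AbundanceTable, depth: int | None = None, seed: int = 0) -> AbundanceTable:
    """Subsample each sample's counts without replacement to a common depth.

    ``depth`` defaults to the minimum sample sum.  Requires counts mode.
    """
    if t.mode != "counts":
        raise ValueError("rarefaction requires a counts-mode table")
    counts = np.round(t.data.to_numpy(dtype=float)).astype(np.int64)
    sums = counts.sum(axis=0)
    if depth is None:
        depth = int(sums.min())
    if depth < 1 or (sums < depth).any():
        bad = t.data.columns[sums < depth]
        raise ValueError(f"samples shallower than depth {depth}: {list(bad)}")
    rng = np.random.default_rng(seed)
    out = np.zeros_like(counts)
    for j in range(counts.shape[1]):
        pool = np.repeat(np.arange(counts.shape[0]), counts[:, j])
        keep = rng.choice(pool, size=depth, replace=False)
        out[:, j] = np.bincount(keep, minlength=counts.shape[0])
    return replace(t, data=pd.DataFrame(out, index=t.data.index, columns=t.data.columns))


def to_relative(t: AbundanceTable) -> AbundanceTable:
    """Divide each sample column by its sum; idempotent on relative tables."""
    sums = t.data.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {sorted(zero.index)}")
    return replace(t, data=t.data.div(sums, axis=1), mode="relative")


def top_n_with_remainder(t: AbundanceTable, n: int, per_phylum: bool | None = None) -> AbundanceTable:
    """Keep the top-``n`` taxa by mean relative abundance, pool the rest.

    The remainder rows are labelled ``Other`` (or ``Other <phylum>`` when a
    lineage is attached and ``per_phylum`` is enabled), so the pooled rare
    fraction takes part in downstream correlation networks as ordinary nodes.
    Column sums are preserved exactly.  Ties at rank ``n`` break by mean
    abundance descending, then taxon id ascending.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n >= len(t.data):
        log.info("top_n_with_remainder: n=%d >= %d taxa; table returned unchanged", n, len(t.data))
        return t
    if per_phylum is None:
        per_phylum = t.lineage is not None
    rel = to_relative(t) if t.mode == "counts" else t
    means = rel.data.mean(axis=1)
    order = means.to_frame("mean").reset_index(names="taxon")
    order = order.sort_values(["mean", "taxon"], ascending=[False, True], kind="mergesort")
    keep = list(order["taxon"].iloc[:n])
    rest = [x for x in t.taxa if x not in set(keep)]
    top = t.data.loc[keep]
    if per_phylum and t.lineage is not None:
        groups = pd.Series({x: t.phylum(x) for x in rest})
        pooled = {}
        for phylum in sorted(groups.unique()):
            members = groups.index[groups == phylum]
            pooled[f"Other {phylum}"] = t.data.loc[members].sum(axis=0)
        other = pd.DataFrame(pooled).T
    else:
        other = t.data.loc[rest].sum(axis=0).to_frame("Other").T
    out = pd.concat([top, other])
    out.index.name = t.data.index.name
    return replace(t, data=out)


def d_values(t: AbundanceTable, design: SampleDesign) -> DifferenceTable:
    """Paired site differences: value = site-A sample minus matched site-B sample.

    Pairs are matched by (stage, replicate index) and ordered by (stage,
    replicate); 4 stages x 9 replicates in both sites give 36 pair columns.
    """
    pairs = design.matched_pairs()
    a = t.data[list(pairs["sample_a"])].to_numpy(dtype=float)
    b = t.data[list(pairs["sample_b"])].to_numpy(dtype=float)
    data = pd.DataFrame(a - b, index=t.data.index, columns=list(pairs["label"]))
    return DifferenceTable(data=data, pairs=pairs)


def _shannon(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def diversity(t: AbundanceTable, richness_estimators: bool = True) -> pd.DataFrame:
    """Per-sample alpha diversity.

    Shannon (nats, -sum p ln p) and Simpson's D (sum p^2) work on any mode;
    Chao1 and ACE are singleton/doubleton estimators and require counts
    (ACE with the conventional rare-abundance cutoff of 10).  Pass
    ``richness_estimators=False`` to skip them on relative tables.
    """
    if richness_estimators and t.mode != "counts":
        raise ValueError(
            "chao1/ace require a counts-mode table (singleton/doubleton based); "
            "pass richness_estimators=False for shannon/simpson only"
        )
    rows = {}
    rel = to_relative(t) if t.mode == "counts" else t
    counts = None
    if t.mode == "counts" and richness_estimators:
        counts = np.round(t.data.to_numpy(dtype=float)).astype(np.int64)
    for j, s in enumerate(t.samples):
        p = rel.data[s].to_numpy(dtype=float)
        row = {
            "observed_richness": int((t.data[s] > 0).sum()),
            "shannon": _shannon(p),
            "simpson_D": float((p**2).sum()),
        }
        if counts is not None:
            c = counts[:, j]
            c = c[c > 0]
            row["chao1"] = float(_skbio_chao1(c, bias_corrected=True))
            row["ace"] = float(_skbio_ace(c, rare_threshold=10)) if (c <= 10).any() else float(len(c))
        else:
            row["chao1"] = np.nan
            row["ace"] = np.nan
        rows[s] = row
    out = pd.DataFrame(rows).T
    out.index.name = "sample_id"
    return out
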