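"""End-to-end orchestration: tables -> AVD -> networks -> keystones ->
stability -> functions -> machine-readable report bundle.

A single YAML-style configuration dict drives the whole analysis; every
threshold, seed and grid consumed anywhere appears in :data:`DEFAULT_CONFIG`
with its default.  Outputs are plain TSV/JSON files under an output
directory, deterministic under a fixed config + seed (the config is echoed
verbatim, floats are written at full precision, and all collections are
ordered).
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as _sstats

from . import avd as avdm
from . import keystone as km
from . import netbuild, stability
from .core_data import (
    AbundanceTable,
    SampleDesign,
    d_values,
    diversity,
    rarefy,
    read_abundance_table,
    read_design,
    read_taxonomy,
    to_relative,
    top_n_with_remainder,
    write_abundance_table,
)
from .functions import (
    FunctionTable,
    classify_functions,
    function_avd_regression,
    functional_network,
    permutation_importance,
    read_function_table,
)
from .synthcom import GeneratorSpec, generate_community, generate_function_tables, ground_truth

log = logging.getLogger(__name__)

__all__ = ["DEFAULT_CONFIG", "load_config", "run", "compare_sites", "simulate_to_dir"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": True,  # generate inputs with synthcom; else read the input paths
    "inputs": {
        "abundance": None,  # TSV taxa x samples
        "metadata": None,  # TSV sample_id/site/stage/replicate
        "taxonomy": None,  # TSV taxon_id + lineage
        "ko_l2": None,
        "ko_l3": None,
    },
    "generator": {},  # GeneratorSpec field overrides
    "modules": {  # stage toggles
        "avd": True,
        "networks": True,
        "keystones": True,
        "stability": True,
        "functions": True,
    },
    "top_n": 200,
    "avd": {"ddof": 1, "rarefy": False, "seed": 0},
    "network": {"r_min": 0.6, "p_max": 0.01, "keep_isolated": False, "seed": 0},
    "functions_network": {"r_min": 0.75, "p_max": 0.01},
    "stability": {
        "fractions": [round(float(f), 2) for f in np.arange(0.0, 0.951, 0.05)],
        "reps": 100,
        "shuffles": 500,
        "seed": 0,
    },
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge the defaults with an optional YAML file and overrides."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def merge(dst, src):
        for k, v in (src or {}).items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v

    if path is not None:
        with open(path) as fh:
            merge(cfg, yaml.safe_load(fh) or {})
    merge(cfg, overrides or {})
    return cfg


def simulate_to_dir(spec: GeneratorSpec, outdir) -> dict:
    """Write abundance/metadata/taxonomy/KO tables and the truth record."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, design, lineage = generate_community(spec)
    write_abundance_table(table, outdir / "abundance.tsv")
    design.frame.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    lineage.rename_axis("taxon_id").to_frame().to_csv(outdir / "taxonomy.tsv", sep="\t")
    fts = generate_function_tables(spec, table)
    for level, ft in fts.items():
        ft.data.to_csv(outdir / f"ko_l{level}.tsv", sep="\t", index_label="function")
    truth = ground_truth(spec)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth


def _load_inputs(cfg: dict):
    if cfg["simulate"]:
        spec = GeneratorSpec(seed=int(cfg["seed"]), **cfg.get("generator", {}))
        table, design, lineage = generate_community(spec)
        fts = generate_function_tables(spec, table)
        return table, design, lineage, fts
    paths = cfg["inputs"]
    design = read_design(paths["metadata"])
    lineage = read_taxonomy(paths["taxonomy"]) if paths.get("taxonomy") else None
    table = read_abundance_table(paths["abundance"], design, lineage=lineage)
    fts = {}
    for level in (2, 3):
        p = paths.get(f"ko_l{level}")
        if p:
            fts[level] = read_function_table(p, level)
    return table, design, lineage, fts


def _topology_record(name: str, g, topo: netbuild.TopologySummary | None) -> dict:
    rec = {"network": name}
    if topo is None:
        rec["empty"] = True
        return rec
    rec.update(topo.as_dict())
    return rec


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def run(cfg: dict, outdir) -> dict:
    """Execute the configured stages; return (and write) the summary bundle.

    Any stage failure raises with the stage name; outputs written before the
    failure are retained.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    run_log: list[str] = []

    def note(msg):
        log.info(msg)
        run_log.append(msg)

    summary: dict = {"seed": cfg["seed"]}
    stage = "inputs"
    try:
        table, design, lineage, fts = _load_inputs(cfg)
        note(f"inputs: {len(table.taxa)} taxa x {len(table.samples)} samples"
             f" ({'simulated' if cfg['simulate'] else 'files'})")
        rel = to_relative(table)
        phylum = table.phylum_map() if lineage is not None else None

        # --- AVD ---------------------------------------------------------
        if cfg["modules"]["avd"]:
            stage = "avd"
            ddof = int(cfg["avd"]["ddof"])
            avd_dir = outdir / "avd"
            avd_dir.mkdir(exist_ok=True)
            avd_input = rel
            if cfg["avd"].get("rarefy") and table.mode == "counts":
                avd_input = to_relative(
                    rarefy(table, seed=int(cfg["avd"].get("seed", 0))))
                note("avd: rarefied to minimum sample depth before AVD")
            results = avdm.avd_by_group(avd_input, design, ddof=ddof)
            rows = [
                {"group_id": r.group_id, "k": r.k, "n": r.n, "avd": r.avd,
                 "n_excluded": len(r.excluded_taxa)}
                for r in results
            ]
            pd.DataFrame(rows).to_csv(avd_dir / "avd.tsv", sep="\t", index=False)
            summary["avd"] = {r.group_id: r.avd for r in results}
            if table.mode == "counts":
                div = diversity(table)
                div.to_csv(avd_dir / "diversity.tsv", sep="\t")
                site_groups = {r.group_id: r.avd for r in results if len(r.group_id) == 2}
                div_groups = div.groupby(
                    [design.frame.set_index("sample_id").loc[div.index, "site"],
                     design.frame.set_index("sample_id").loc[div.index, "stage"]]
                ).mean()
                div_groups.index = [f"{s}{st}" for s, st in div_groups.index]
                common = [g for g in div_groups.index if g in site_groups]
                reg = avdm.avd_vs_diversity(
                    [site_groups[g] for g in common], div_groups.loc[common]
                )
                reg.to_csv(avd_dir / "avd_vs_diversity.tsv", sep="\t")
                summary["avd_vs_diversity"] = {
                    idx: {"slope": float(row["slope"]), "p": float(row["p_pearson"])}
                    for idx, row in reg.iterrows()
                }
            note(f"avd: {len(results)} groups")

        # --- networks ----------------------------------------------------
        graphs: dict = {}
        if cfg["modules"]["networks"]:
            stage = "networks"
            net_dir = outdir / "networks"
            net_dir.mkdir(exist_ok=True)
            top = top_n_with_remainder(rel, int(cfg["top_n"]))
            ncfg = cfg["network"]
            seed = int(ncfg["seed"])
            dt = d_values(top, design)
            sources = {
                "site_A": top.data[design.samples(site="A")],
                "site_B": top.data[design.samples(site="B")],
                "differential": dt.data,
            }
            summary["networks"] = {}
            attrs = phylum.to_frame("phylum") if phylum is not None else None
            for name, frame in sources.items():
                assoc = netbuild.spearman_matrix(frame)
                g = netbuild.build_network(
                    assoc, r_min=float(ncfg["r_min"]), p_max=float(ncfg["p_max"]),
                    keep_isolated=bool(ncfg["keep_isolated"]), node_attrs=attrs,
                )
                graphs[name] = g
                if g.number_of_edges() >= 1 and g.number_of_nodes() >= 2:
                    partition, q = netbuild.detect_modules(g, seed=seed)
                    topo = netbuild.topology(g, seed=seed, partition=partition)
                    comp = netbuild.module_composition(g, partition, phylum)
                    comp.to_csv(net_dir / f"{name}_modules.tsv", sep="\t")
                    nx_partition = pd.Series(partition, name="module")
                    nx_partition.rename_axis("node").to_frame().to_csv(
                        net_dir / f"{name}_partition.tsv", sep="\t")
                else:
                    topo = None
                netbuild.export_edge_list(g, net_dir / f"{name}_edges.tsv")
                netbuild.export_graphml(g, net_dir / f"{name}.graphml")
                summary["networks"][name] = _topology_record(name, g, topo)
                note(f"network {name}: {g.number_of_nodes()} nodes {g.number_of_edges()} edges")
            summary["d_pairs"] = len(dt.labels)

        # --- keystones ---------------------------------------------------
        if cfg["modules"]["keystones"] and cfg["modules"]["networks"]:
            stage = "keystones"
            key_dir = outdir / "keystones"
            key_dir.mkdir(exist_ok=True)
            gd = graphs["differential"]
            if gd.number_of_nodes() >= 2 and gd.number_of_edges() >= 1:
                metrics = km.node_metrics(gd)
                report = km.keystones(metrics)
                series = avdm.paired_avd_series(rel, design, ddof=int(cfg["avd"]["ddof"]))
                top_for_dt = top_n_with_remainder(rel, int(cfg["top_n"]))
                dt = d_values(top_for_dt, design)
                cors = km.keystone_avd_correlation(dt, report.keystone, series)
                out = report.metrics.join(cors)
                if phylum is not None:
                    out.insert(0, "taxonomy", [
                        phylum.loc[t] if t in phylum.index else "unclassified"
                        for t in out.index
                    ])
                out.to_csv(key_dir / "keystones.tsv", sep="\t")
                summary["keystones"] = {
                    "keystone": report.keystone,
                    "core": report.core,
                    "hub_top": report.hub_top,
                    "betweenness_top": report.betweenness_top,
                    "significant_avd": sorted(cors.index[cors["significant"] == True]),  # noqa: E712
                }
                note(f"keystones: {len(report.keystone)} (core {report.core})")

        # --- stability ---------------------------------------------------
        if cfg["modules"]["stability"] and cfg["modules"]["networks"]:
            stage = "stability"
            st_dir = outdir / "stability"
            st_dir.mkdir(exist_ok=True)
            scfg = cfg["stability"]
            fractions = [float(f) for f in scfg["fractions"]]
            summary["stability"] = {}
            rob_rows = []
            for name, g in graphs.items():
                rec: dict = {}
                if g.number_of_nodes() >= 3 and g.number_of_edges() >= 1:
                    vul = stability.vulnerability(g)
                    vul.per_node.rename_axis("node").to_frame().to_csv(
                        st_dir / f"{name}_vulnerability.tsv", sep="\t")
                    rec["max_vulnerability"] = vul.network
                    rec["global_efficiency"] = vul.efficiency
                    for strat in ("random", "targeted_degree"):
                        curve = stability.robustness(
                            g, strategy=strat, fractions=fractions,
                            n_reps=int(scfg["reps"]), seed=int(scfg["seed"]),
                        )
                        rec[f"robustness_auc_{strat}"] = stability.robustness_auc(curve)
                        for _, row in curve.curve.iterrows():
                            rob_rows.append({"network": name, "strategy": strat, **row})
                summary["stability"][name] = rec
            pd.DataFrame(rob_rows).to_csv(st_dir / "robustness.tsv", sep="\t", index=False)
            coh_rows = []
            summary["cohesion"] = {}
            for site in ("A", "B"):
                sub = rel.subset_samples(design.samples(site=site))
                coh = stability.cohesion(
                    sub, n_shuffles=int(scfg["shuffles"]), seed=int(scfg["seed"]))
                for sample, row in coh.samples.iterrows():
                    coh_rows.append({"sample_id": sample, "site": site, **row})
                summary["cohesion"][site] = {
                    "positive": float(coh.samples["positive"].mean()),
                    "negative": float(coh.samples["negative"].mean()),
                    "total": float(coh.samples["total"].mean()),
                }
            pd.DataFrame(coh_rows).to_csv(st_dir / "cohesion.tsv", sep="\t", index=False)
            note("stability: robustness, vulnerability, cohesion done")

        # --- functions ---------------------------------------------------
        if cfg["modules"]["functions"] and fts:
            stage = "functions"
            fn_dir = outdir / "functions"
            fn_dir.mkdir(exist_ok=True)
            fcfg = cfg["functions_network"]
            series = avdm.paired_avd_series(rel, design, ddof=int(cfg["avd"]["ddof"]))
            summary["functions"] = {}
            for level, ft in sorted(fts.items()):
                ft = classify_functions(ft)
                g, topo, core = functional_network(
                    ft, design, r_min=float(fcfg["r_min"]), p_max=float(fcfg["p_max"]),
                    seed=int(cfg["network"]["seed"]),
                )
                netbuild.export_edge_list(g, fn_dir / f"ko_l{level}_edges.tsv")
                relf = ft.data.div(ft.data.sum(axis=0), axis=1)
                dtf = d_values(AbundanceTable(relf, mode="relative"), design)
                reg = function_avd_regression(dtf, series)
                reg.insert(0, "class", [ft.classes.loc[f] for f in reg.index])
                reg.to_csv(fn_dir / f"ko_l{level}_avd_regression.tsv", sep="\t")
                candidates = sorted(set(core) | set(
                    ft.classes.index[ft.classes != "unclassified"]))
                importance = permutation_importance(
                    dtf.data.loc[candidates], series, seed=int(cfg["seed"]))
                importance.to_frame().to_csv(fn_dir / f"ko_l{level}_importance.tsv", sep="\t")
                summary["functions"][f"level_{level}"] = {
                    "network": _topology_record(f"ko_l{level}", g, topo),
                    "core_functions": core,
                    "n_destabilizing": int((reg["destabilizing"] == True).sum()),  # noqa: E712
                    "top_importance": importance.index[0] if len(importance) else None,
                }
                note(f"functions L{level}: {g.number_of_nodes()} nodes, core {core[:3]}")

        summary["site_contrast"] = compare_sites(summary, outdir)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
    (outdir / "run.log").write_text("\n".join(run_log) + "\n")
    return summary


def compare_sites(summary: dict, outdir=None) -> list[dict]:
    """Site-contrast table from a summary bundle.

    Per metric: site A value, site B value, difference, and a Wilcoxon
    rank-sum p where replicate-level values exist (AVD per stage group,
    per-sample cohesion).  Missing metrics are flagged, not dropped.
    """
    rows: list[dict] = []

    def add(metric, a, b, p=None):
        row = {"metric": metric, "site_a": a, "site_b": b}
        if a is None or b is None:
            row["missing"] = True
        else:
            row["difference"] = a - b
            if p is not None:
                row["p_value"] = p
        rows.append(row)

    avd_groups = summary.get("avd", {})
    a_vals = [v for k, v in avd_groups.items() if k.startswith("A") and len(k) == 2]
    b_vals = [v for k, v in avd_groups.items() if k.startswith("B") and len(k) == 2]
    if a_vals and b_vals:
        p = float(_sstats.ranksums(a_vals, b_vals).pvalue)
        add("avd_stage_groups_mean", float(np.mean(a_vals)), float(np.mean(b_vals)), p)
    add("avd_site", avd_groups.get("A"), avd_groups.get("B"))
    nets = summary.get("networks", {})
    for met in ("n_edges", "avgK", "GD"):
        add(f"network_{met}",
            nets.get("site_A", {}).get(met), nets.get("site_B", {}).get(met))
    stab = summary.get("stability", {})
    add("max_vulnerability",
        stab.get("site_A", {}).get("max_vulnerability"),
        stab.get("site_B", {}).get("max_vulnerability"))
    add("robustness_auc_targeted",
        stab.get("site_A", {}).get("robustness_auc_targeted_degree"),
        stab.get("site_B", {}).get("robustness_auc_targeted_degree"))
    coh = summary.get("cohesion", {})
    add("cohesion_total",
        coh.get("A", {}).get("total"), coh.get("B", {}).get("total"))
    if outdir is not None:
        pd.DataFrame(rows).to_csv(Path(outdir) / "site_contrast.tsv", sep="\t", index=False)
    return rows
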