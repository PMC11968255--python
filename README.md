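# bacstab

Stability analysis for soil bacterial communities from paired-site, staged
amplicon surveys: the **average variation degree (AVD)** stability index,
thresholded Spearman **co-occurrence and differential networks**, **keystone
taxa** from hub and betweenness centrality, network **robustness** and
**vulnerability**, null-model-corrected **cohesion**, and **KEGG
functional-trait networks** — together with a synthetic two-site community
generator so the entire pipeline can be exercised and validated without any
sequencing data.

The package is aimed at microbial ecologists comparing community stability
between two sites (e.g. two wetland types) sampled at matched growth stages
with replicated quadrats.

## The quantities it computes

**AVD.** For taxon *i* in a group of *k* replicate samples, the variation
degree of sample *s* is `a_i(s) = (x_i(s) − x̄_i) / δ_i`, with `δ_i` the
within-group standard deviation. The group's stability index is

```
AVD = Σ_i Σ_s |a_i(s)| / (k · n)
```

over the *n* taxa with `δ_i > 0`. Lower AVD = more stable community.

**Co-occurrence networks.** An edge joins two taxa (or functions) when
`|ρ_Spearman| > 0.6` (functions: `0.75`) **and** `p < 0.01` across samples
— or across the 36 paired site differences ("D-values") for the
differential network. Whole-network topology (avgK, avgCC, APD, modularity
via seeded Louvain, graph density, negative-edge ratio) is computed on the
unweighted skeleton.

**Keystone taxa.** The union of the top-5 nodes by HITS hub score and the
top-5 by (unnormalised) betweenness; the keystone with the highest degree
is the core taxon. Each keystone's D-value series is correlated against a
per-pair AVD-difference series.

**Stability.** Robustness = proportion of taxa surviving random or
degree-targeted node removal, counting secondary extinctions; vulnerability
`V_i = (E(G) − E(G−i)) / E(G)` from global efficiency; cohesion =
abundance-weighted sums of per-taxon null-corrected mean positive/negative
correlations (taxon-shuffle null).

**Functions.** KO level-2/3 read tables are classified as *broad* vs
*specialized* metabolism, built into functional networks on D-values, and
regressed against the AVD series — a positive slope marks a function whose
enhancement destabilises the community.

## Worked example

```python
from bacstab.synthcom import GeneratorSpec, generate_community, ground_truth
from bacstab.core_data import to_relative, d_values, top_n_with_remainder
from bacstab.avd import avd
from bacstab.netbuild import spearman_matrix, build_network, topology
from bacstab.keystone import node_metrics, keystones

spec = GeneratorSpec(seed=1)          # 2 sites x 4 stages x 9 replicates, 220 genera
table, design, lineage = generate_community(spec)
rel = to_relative(table)

for site in ("A", "B"):
    r = avd(rel, design.samples(site=site))
    print(f"AVD site {site}: {r.avd:.4f}  (k={r.k}, n={r.n})")

dt = d_values(top_n_with_remainder(rel, 200), design)
g = build_network(spearman_matrix(dt.data), keep_isolated=False)
t = topology(g, seed=0)
print(f"differential network: {t.n_nodes} nodes, {t.n_edges} edges, "
      f"avgK={t.avg_k:.2f}, GD={t.gd:.3f}, modularity={t.modularity_q:.2f}")

rep = keystones(node_metrics(g))
print(f"keystones: {len(rep.keystone)}  core taxon: {rep.core}")
```

prints

```
AVD site A: 0.8271  (k=36, n=220)
AVD site B: 0.8033  (k=36, n=220)
differential network: 118 nodes, 160 edges, avgK=2.71, GD=0.023, modularity=0.74
keystones: 9  core taxon: Genus_001
```

Site A carries the generator's doubled replicate noise, so its AVD is
higher (less stable); the differential network is sparse and modular; and
the recovered core taxon `Genus_001` is the first of the generator's five
planted hub genera (`ground_truth(spec)["hubs"]`).

The same analysis runs end to end from the shell:

```
bacstab run --seed 1 --out results/run1        # full bundle + summary.json
bacstab simulate --seed 1 --out data/          # just the synthetic tables
bacstab avd --abundance data/abundance.tsv --metadata data/metadata.tsv
```

`bacstab run` writes TSV/GraphML outputs per stage (`avd/`, `networks/`,
`keystones/`, `stability/`, `functions/`), a site-contrast table and a
`summary.json`; reruns with the same config and seed are byte-identical.

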