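"""Synthetic two-site, four-stage, replicated community generator.

Emulates the processed products of a paired-wetland 16S survey: 2 sites x 4
growth stages x 9 replicates (72 samples), a Proteobacteria-dominated genus
table with modular correlation structure, designated hub genera, planted
stabilizer/destabilizer taxa, and taxon-linked KO level-2/3 function read
tables — so that every downstream stage (AVD, networks, keystones, cohesion,
functional regressions) is testable without downloads.

Mechanism
---------
Each taxon's expected proportion in a sample is a softmax over log-scale
baselines (site-dependent evenness, shared stage effects) multiplied by a
bounded linear-scale response

    1 + 0.98 * tanh([loading * F_module(s) * sign + sigma_site * a_s * r] / 0.98)

where ``F_m`` are module latent factors (orthonormalised across modules and
site blocks, so planted blocks are exactly uncorrelated), ``sign`` carries
the planted negative associations, ``a_s`` is a per-sample lognormal
disturbance amplitude, and ``r = +/-1`` is taxon-private two-point noise
scaled by the site noise level.  Two-point noise on the linear scale makes
replicate disagreement bimodal, which is what the AVD index detects: the
noisy site (A, the salt-marsh analogue) has genuinely higher AVD, while
site B (the mangrove analogue) is the stable, low-AVD, high-diversity site.
Counts are a multinomial draw at fixed depth.

Hub taxa respond strongly to the first module's factor (and weakly to all
others), with little private noise, so they carry the highest degree and
hub centrality in inferred networks.  The stabilizer taxon's abundance is
coupled negatively (destabilizers positively) to the disturbance amplitude
``a_s``, providing ground truth for stability-correlation recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import AbundanceTable, SampleDesign
from .functions import FunctionTable

__all__ = [
    "GeneratorSpec",
    "generate_community",
    "generate_functions",
    "generate_function_tables",
    "default_incidence",
    "ground_truth",
    "KO_LEVEL2",
    "KO_LEVEL3",
]

DEFAULT_PHYLUM_PROFILE = {
    "Proteobacteria": 0.531,
    "Acidobacteria": 0.110,
    "Bacteroidetes": 0.073,
    "Actinobacteria": 0.030,
    "Firmicutes": 0.014,
    "Chloroflexi": 0.013,
    "Nitrospirae": 0.011,
    "Planctomycetes": 0.004,
    "Nitrospinae": 0.002,
    "Candidatus_Saccharibacteria": 0.001,
    "other": 0.211,
}

KO_LEVEL2 = [
    "Amino acid metabolism",
    "Carbohydrate metabolism",
    "Membrane transport",
    "Metabolism of cofactors and vitamins",
    "Metabolism of other amino acids",
    "Energy metabolism",
    "Lipid metabolism",
    "Nucleotide metabolism",
    "Glycan biosynthesis and metabolism",
    "Metabolism of terpenoids and polyketides",
    "Biosynthesis of other secondary metabolites",
    "Xenobiotics biodegradation and metabolism",
    "Translation",
    "Transcription",
    "Replication and repair",
    "Folding, sorting and degradation",
    "Signal transduction",
    "Cell motility",
    "Cell growth and death",
    "Transport and catabolism",
    "Membrane transport and secretion",
    "Enzyme families",
    "Cellular community - prokaryotes",
]

KO_LEVEL3 = [
    "Base excision repair",
    "Pyruvate metabolism",
    "Cysteine and methionine metabolism",
    "Nitrogen metabolism",
    "Sulfur metabolism",
    "Atrazine degradation",
    "Metabolism of xenobiotics by cytochrome P450",
    "Polycyclic aromatic hydrocarbon degradation",
    "Glycolysis / Gluconeogenesis",
    "Citrate cycle (TCA cycle)",
    "Oxidative phosphorylation",
    "Methane metabolism",
    "Sulfur relay system",
    "ABC transporters",
    "Two-component system",
    "Ribosome",
    "Purine metabolism",
    "Pyrimidine metabolism",
    "Aminoacyl-tRNA biosynthesis",
    "Peptidoglycan biosynthesis",
    "Fatty acid biosynthesis",
    "Pentose phosphate pathway",
    "Butanoate metabolism",
    "Propanoate metabolism",
    "Glycine, serine and threonine metabolism",
    "Arginine and proline metabolism",
    "Homologous recombination",
    "Mismatch repair",
    "Bacterial secretion system",
    "Flagellar assembly",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Study-condition knobs for the synthetic community.

    ``site_noise_ratio`` is sigma_A / sigma_B; values above 1 make site B the
    stable (low-AVD) site.  ``neg_edge_frac`` is the target fraction of
    negative edges in the inferred networks; the generator converts it to the
    corresponding negative-loading probability q via 2q(1-q) = f.
    ``module_rho`` is the linear-scale within-module factor loading; 0.55
    yields within-module Spearman correlations around 0.6 after private
    noise and counting noise, so inferred site networks sit near the edge
    threshold the way real genus tables do.
    """

    n_taxa: int = 220
    n_modules: int = 4
    module_rho: float = 0.55
    neg_edge_frac: float = 0.17
    n_hubs: int = 5
    stages: int = 4
    replicates: int = 9
    site_noise_ratio: float = 2.0
    sigma_stable: float = 0.4  # two-point noise amplitude of the stable site (B)
    amp_sd: float = 0.3  # lognormal sd of the per-sample disturbance amplitude
    stage_sd: float = 0.25
    base_sd: float = 1.2
    evenness_ratio: float = 1.25  # site A baseline spread multiplier (less even)
    hub_loading: float = 1.0
    hub_cross_loading: float = 0.15
    hub_noise_scale: float = 0.03
    hub_module_share: float = 0.35  # node share of the hub-bearing module
    n_stabilizers: int = 1
    n_destabilizers: int = 3
    stabilizer_effect: float = 2.5
    destabilizer_effect: float = 2.5
    planted_noise_scale: float = 0.3  # private-noise damping of stabilizer/destabilizer taxa
    planted_base: float = 0.5  # log-baseline of planted taxa (keystones are abundant)
    depth: int = 50_000
    phylum_profile: dict = field(default_factory=lambda: dict(DEFAULT_PHYLUM_PROFILE))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 1 or self.n_modules < 1:
            raise ValueError("degenerate spec: need >= 1 taxon and >= 1 module")
        n_planted = self.n_hubs + self.n_stabilizers + self.n_destabilizers
        if self.n_taxa < n_planted + self.n_modules:
            raise ValueError("too few taxa for the requested planted structure")
        if not (0 <= self.neg_edge_frac <= 0.5):
            raise ValueError("neg_edge_frac must lie in [0, 0.5]")
        if not (0 < self.module_rho < 1):
            raise ValueError("module_rho must lie in (0, 1)")

    @property
    def n_samples(self) -> int:
        return 2 * self.stages * self.replicates


def _taxon_ids(spec: GeneratorSpec) -> list[str]:
    return [f"Genus_{i + 1:03d}" for i in range(spec.n_taxa)]


def _structure(spec: GeneratorSpec) -> dict:
    """Planted structure: roles, module labels, loading signs, phyla.

    Fully determined by the GeneratorSpec fields except the loading signs,
    which are the only per-seed sampled part of the truth record.
    """
    taxa = _taxon_ids(spec)
    n = spec.n_taxa
    hubs = taxa[: spec.n_hubs]
    stabilizers = taxa[spec.n_hubs: spec.n_hubs + spec.n_stabilizers]
    destabilizers = taxa[
        spec.n_hubs + spec.n_stabilizers: spec.n_hubs + spec.n_stabilizers + spec.n_destabilizers
    ]
    planted = hubs + stabilizers + destabilizers
    modules: dict[str, int] = {}
    for t in hubs:
        modules[t] = 1
    other_mods = list(range(2, spec.n_modules + 1)) or [1]
    for j, t in enumerate(stabilizers + destabilizers):
        modules[t] = other_mods[j % len(other_mods)]
    members = taxa[len(planted):]
    n_mod1 = max(0, int(round(spec.hub_module_share * n)) - spec.n_hubs)
    for t in members[:n_mod1]:
        modules[t] = 1
    for j, t in enumerate(members[n_mod1:]):
        modules[t] = other_mods[j % len(other_mods)]
    # negative-loading probability q solving 2q(1-q) = neg_edge_frac
    q = 0.5 * (1.0 - np.sqrt(1.0 - 2.0 * spec.neg_edge_frac))
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 101]))
    plantset = set(planted)
    signs = {
        t: (1 if t in plantset else (-1 if rng.random() < q else 1)) for t in taxa
    }
    # deterministic phylum assignment by profile proportions, fixed interleave
    profile = spec.phylum_profile
    names = list(profile)
    counts = np.floor(np.asarray([profile[p] for p in names]) * n).astype(int)
    counts[-1] += n - counts.sum()
    phyla = [p for p, c in zip(names, counts) for _ in range(c)]
    order = np.random.default_rng(12345).permutation(n)
    phylum = {taxa[i]: phyla[j] for j, i in enumerate(order)}
    return {
        "taxa": taxa,
        "hubs": hubs,
        "stabilizers": stabilizers,
        "destabilizers": destabilizers,
        "modules": modules,
        "signs": signs,
        "phylum": phylum,
        "neg_loading_prob": float(q),
    }


def _design(spec: GeneratorSpec) -> SampleDesign:
    rows = [
        {"sample_id": f"{site}{stage}R{rep}", "site": site, "stage": stage, "replicate": rep}
        for site in ("A", "B")
        for stage in range(1, spec.stages + 1)
        for rep in range(1, spec.replicates + 1)
    ]
    return SampleDesign(pd.DataFrame(rows))


def _orthonormal_factors(rng: np.random.Generator, n_mod: int, n_samples: int) -> np.ndarray:
    """Module factors, unit variance, exactly uncorrelated across modules
    and between the two site blocks (Gram-Schmidt over matched-pair coords).

    Exact orthogonality keeps every planted module's realised inter-taxon
    correlation at its nominal level instead of fluctuating with the luck of
    36 factor draws.  Falls back to plain standardised draws when the sample
    count is too small to orthogonalise.
    """
    half = n_samples // 2
    raw = rng.normal(0.0, 1.0, size=(2 * n_mod, half))
    if 2 * n_mod >= half - 1:
        raw = (raw - raw.mean(axis=1, keepdims=True))
        sd = raw.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        basis = raw / sd
    else:
        vecs: list[np.ndarray] = []
        for v in raw:
            for u in vecs:
                v = v - (v @ u) * u
            v = v - v.mean()
            norm = np.sqrt((v**2).sum())
            if norm == 0:  # pragma: no cover - measure-zero degenerate draw
                v = np.ones(half)
                norm = np.sqrt(float(half))
            vecs.append(v / norm)
        basis = np.asarray(vecs) * np.sqrt(half)
    g = np.zeros((n_mod, n_samples))
    g[:, :half] = basis[:n_mod]
    g[:, half:] = basis[n_mod:]
    return g


def generate_community(spec: GeneratorSpec):
    """Generate (counts AbundanceTable, SampleDesign, taxonomy Series).

    Deterministic under identical spec + seed; column sums equal ``depth``.
    """
    struct = _structure(spec)
    design = _design(spec)
    taxa = struct["taxa"]
    n = spec.n_taxa
    samples = design.sample_ids
    ns = len(samples)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 202]))

    base = rng.normal(0.0, spec.base_sd, size=n)
    stage_eff = rng.normal(0.0, spec.stage_sd, size=(spec.stages, n))
    factors = _orthonormal_factors(rng, spec.n_modules, ns)
    amp = np.exp(rng.normal(0.0, spec.amp_sd, size=ns) - 0.5 * spec.amp_sd**2)
    flips = rng.choice([-1.0, 1.0], size=(n, ns))

    n_planted_front = spec.n_hubs + spec.n_stabilizers + spec.n_destabilizers
    base[:n_planted_front] = spec.planted_base

    meta = design.frame
    is_a = (meta["site"] == "A").to_numpy()
    sigma = np.where(is_a, spec.sigma_stable * spec.site_noise_ratio, spec.sigma_stable)
    evenness = np.where(is_a, spec.evenness_ratio, 1.0)
    stage_idx = meta["stage"].to_numpy() - 1

    mod_idx = np.array([struct["modules"][t] - 1 for t in taxa])
    sign_vec = np.array([struct["signs"][t] for t in taxa], dtype=float)
    noise_scale = np.ones(n)
    for t in struct["stabilizers"] + struct["destabilizers"]:
        noise_scale[taxa.index(t)] = spec.planted_noise_scale
    response = amp[None, :] * (
        spec.module_rho * factors[mod_idx, :] * sign_vec[:, None]
        + noise_scale[:, None] * sigma[None, :] * flips
    )
    hubset = set(struct["hubs"])
    for i, t in enumerate(taxa):
        if t in hubset:
            cross = factors.sum(axis=0) - factors[0]
            response[i] = amp * (
                spec.hub_loading * factors[0]
                + spec.hub_cross_loading * spec.module_rho * cross
                + spec.hub_noise_scale * sigma * flips[i]
            )
    multiplier = 1.0 + 0.98 * np.tanh(response / 0.98)

    coupling = np.zeros(n)
    for t in struct["stabilizers"]:
        coupling[taxa.index(t)] = -spec.stabilizer_effect
    for t in struct["destabilizers"]:
        coupling[taxa.index(t)] = spec.destabilizer_effect

    mu = (
        evenness[None, :] * base[:, None]
        + stage_eff[stage_idx, :].T
        + coupling[:, None] * (amp[None, :] - 1.0)
    )
    weights = np.exp(mu - mu.max(axis=0, keepdims=True)) * multiplier
    p = weights / weights.sum(axis=0, keepdims=True)
    counts = np.empty((n, ns), dtype=np.int64)
    for s in range(ns):
        counts[:, s] = rng.multinomial(spec.depth, p[:, s])

    lineage = pd.Series(
        {t: f"k__Bacteria;p__{struct['phylum'][t]};c__;o__;f__;g__{t}" for t in taxa},
        name="lineage",
    )
    table = AbundanceTable(
        pd.DataFrame(counts, index=pd.Index(taxa, name="taxon_id"), columns=samples),
        mode="counts",
        lineage=lineage,
    )
    return table, design, lineage


BROAD_CORE = {
    "Amino acid metabolism",
    "Carbohydrate metabolism",
    "Membrane transport",
    "Metabolism of cofactors and vitamins",
    "Base excision repair",
    "Pyruvate metabolism",
    "Cysteine and methionine metabolism",
}


def default_incidence(spec: GeneratorSpec, level: int) -> pd.DataFrame:
    """Taxon x function 0/1 carriage matrix for the default KO catalogue.

    Broad functions are carried by most taxa (functional redundancy) with a
    shared enrichment in the hub-bearing module, so they form the densest,
    highest-degree block of the functional network — the core functions.
    Other functions are enriched in one of the remaining modules in turn,
    giving the functional network a modular shape.  Specialized functions
    are carried by small planted sets: the nitrogen/sulfur/atrazine trio by
    the destabilizer taxa, the xenobiotics pair by the hub taxa.
    """
    struct = _structure(spec)
    taxa = struct["taxa"]
    mod = np.array([struct["modules"][t] for t in taxa])
    functions = KO_LEVEL2 if level == 2 else KO_LEVEL3
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 303, level]))
    inc = pd.DataFrame(0, index=pd.Index(taxa, name="taxon_id"), columns=functions, dtype=np.int8)
    dstb = struct["destabilizers"]
    # planted specialized functions are carried by their planted host taxa
    # only (distinct subsets where possible): a random extra carrier can be
    # orders of magnitude more abundant and would swamp the planted signal
    specialized_hosts = {
        "Nitrogen metabolism": dstb,
        "Sulfur metabolism": dstb[: max(1, len(dstb) - 1)],
        "Atrazine degradation": dstb[min(1, len(dstb) - 1):],
        "Metabolism of xenobiotics by cytochrome P450": struct["hubs"],
        "Polycyclic aromatic hydrocarbon degradation": struct["hubs"][: max(1, len(struct["hubs"]) - 1)],
    }
    cycle = list(range(1, spec.n_modules + 1))
    j = 0
    for fn in functions:
        if fn in specialized_hosts:
            inc.loc[sorted(set(specialized_hosts[fn])), fn] = 1
            continue
        if fn in BROAD_CORE:
            dominant = 1
        else:
            dominant = cycle[j % len(cycle)]
            j += 1
        p_in = np.where(mod == dominant, 0.9, 0.25)
        carried = rng.random(len(taxa)) < p_in
        carried[rng.integers(len(taxa))] = True  # never empty
        inc.loc[carried, fn] = 1
    return inc


def generate_functions(
    spec: GeneratorSpec, t: AbundanceTable, incidence: pd.DataFrame, level: int
) -> FunctionTable:
    """Function reads = incidence^T . taxon reads, Poisson-perturbed."""
    if list(incidence.index) != t.taxa:
        raise ValueError("incidence rows must match the taxa of the abundance table")
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 404, level]))
    raw = incidence.to_numpy(dtype=float).T @ t.data.to_numpy(dtype=float)
    reads = rng.poisson(0.1 * raw)
    df = pd.DataFrame(
        reads, index=pd.Index(list(incidence.columns), name="function"), columns=t.samples
    )
    return FunctionTable(df, level=level)


def generate_function_tables(spec: GeneratorSpec, t: AbundanceTable) -> dict[int, FunctionTable]:
    return {
        level: generate_functions(spec, t, default_incidence(spec, level), level)
        for level in (2, 3)
    }


def ground_truth(spec: GeneratorSpec) -> dict:
    """Planted-structure record for recovery tests.

    Deterministic under identical spec + seed; across seeds only the sampled
    loading signs differ.
    """
    struct = _structure(spec)
    return {
        "modules": struct["modules"],
        "hubs": list(struct["hubs"]),
        "signs": struct["signs"],
        "stabilizers": list(struct["stabilizers"]),
        "destabilizers": list(struct["destabilizers"]),
        "stable_site": "B",
        "destabilizing_functions": [
            "Nitrogen metabolism",
            "Sulfur metabolism",
            "Atrazine degradation",
        ],
        "neg_loading_prob": struct["neg_loading_prob"],
        "phylum": struct["phylum"],
    }
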