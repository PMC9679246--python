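"""Seeded synthetic fixtures with the statistical structure the analysis assumes.

The generator emulates the study design end to end without any database
downloads: a time-calibrated (ultrametric) species tree; cancer-gene copy
counts evolving by a linear birth--death process along that tree, with
lineage-specific duplication pressure shared between tumour-suppressor and
oncogene sets (which is what makes the two normalized counts strongly
correlated across species, as observed in real genomes) and whole-genome
duplication (WGD) clades whose counts are doubled; and life-history traits
in which log lifespan depends on log body length plus the TSG-OG contrast
with phylogenetically correlated residuals under known Pagel transforms.

Because the TSG and OG signals are nearly collinear, the lifespan effect is
invisible to either count alone and surfaces only in joint or ratio models —
the "masked relationship" the pipeline is designed to expose.

All outputs are pure functions of the seed; the fixture writer emits exactly
the plain-text formats the ingestion modules read.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .copy_number import GeneCountTable
from .pgls import BranchTransforms, CovarianceBuilder
from .phylo_io import Node, PhyloTree, write_gene_tree_file

__all__ = [
    "SimConfig",
    "simulate_yule_tree",
    "simulate_bm_traits",
    "simulate_gene_counts",
    "simulate_masked_lifespan",
    "simulate_study",
    "write_fixture",
]


@dataclass
class SimConfig:
    """Study-scale defaults for the synthetic fish dataset.

    Sizes mirror the real study: ~60 species with sequenced genomes, 243
    pure tumour suppressors and 243 pure oncogenes, copy numbers starting
    from the 2-copy teleost baseline, and one WGD clade standing in for the
    salmonid autotetraploidization.  ``rate_modifier_sigma`` sets the
    Brownian spread of lineage duplication pressure; its default is
    calibrated so the species-level correlation of normalized TSG and OG
    counts lands near ``tsg_og_corr`` (0.95, the near-proportional regime
    seen in real data).
    """

    seed: int
    n_taxa: int = 60
    birth_rate: float = 1.0
    n_tsg: int = 243
    n_og: int = 243
    gatekeeper_fraction: float = 0.4  # of TSGs; same share caretakers, rest unannotated
    duplication_rate: float = 0.10  # per copy per unit tree depth
    loss_rate: float = 0.10
    wgd_n_clades: int = 1
    wgd_clade_size: tuple = (4, 10)
    wgd_lineages: list | None = None  # explicit leaf-label sets override wgd_n_clades
    not_found_fraction: float = 0.05
    lineage_biased_missing: bool = False
    rate_modifier_sigma: float = 0.10  # BM sd of log duplication pressure over unit depth
    tsg_og_corr: float = 0.95
    beta_bodysize: float = 0.35  # slope of log10 lifespan on log10 length
    masking_effect: float = 1.0  # TSG-OG contrast effect, in residual-SD units
    resid_sigma: float = 0.15  # SD of the phylogenetic residual of log10 lifespan
    length_log_mean: float = 1.6  # log10 cm, ~40 cm typical fish
    length_log_sigma: float = 0.45
    lifespan_log_mean: float = 1.0  # log10 years at mean body size
    missing_lifespan_fraction: float = 0.17  # 11 of 65 genomes lacked lifespan data
    low_quality_fraction: float = 0.18
    true_lambda: float = 1.0
    true_kappa: float = 1.0
    true_delta: float = 1.0

    def __post_init__(self):
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        for name in ("birth_rate", "resid_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("duplication_rate", "loss_rate", "rate_modifier_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1.0 < self.tsg_og_corr < 1.0:
            raise ValueError("tsg_og_corr must be in (-1, 1)")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent deterministic substream per simulation stage."""
        tag = zlib.crc32(stream.encode()) % (2**31)
        return np.random.default_rng([int(self.seed) % (2**31), tag])

    def transforms(self) -> BranchTransforms:
        return BranchTransforms(kappa=self.true_kappa, lam=self.true_lambda, delta=self.true_delta)


def _species_names(n: int) -> list[str]:
    return [f"sp{i:03d}" for i in range(1, n + 1)]


def simulate_yule_tree(config: SimConfig) -> PhyloTree:
    """Pure-birth (Yule) ultrametric tree on ``n_taxa`` leaves, unit depth.

    Lineages split at exponential waiting times with total rate
    ``birth_rate * k``; after the n-th lineage appears the tree grows for one
    further exponential interval, then all tips are cut at the present and
    depths rescaled to 1.
    """
    rng = config.rng("yule")
    names = _species_names(config.n_taxa)
    # each active lineage: (node, birth_time of its pendant edge start)
    root = Node(label=None, length=0.0)
    active: list[tuple[Node, float]] = [(root, 0.0)]
    t = 0.0
    while len(active) < config.n_taxa:
        t += rng.exponential(1.0 / (config.birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        node, t0 = active.pop(i)
        node.length = t - t0
        left, right = Node(length=0.0), Node(length=0.0)
        node.children = [left, right]
        active.extend([(left, t), (right, t)])
    t += rng.exponential(1.0 / (config.birth_rate * len(active)))
    order = rng.permutation(len(active))
    for name, j in zip(names, order):
        node, t0 = active[j]
        node.label = name
        node.length = t - t0
    root.length = 0.0  # drop the stem: depths are measured from the first split
    # rescale to unit root-to-tip depth
    tree = PhyloTree(root)
    depth = tree.max_depth()

    def scale(node: Node) -> None:
        node.length /= depth
        for c in node.children:
            scale(c)

    scale(root)
    return PhyloTree(root)


def simulate_bm_traits(
    tree: PhyloTree,
    config: SimConfig,
    names: Sequence[str] = ("trait",),
    sigma: float | None = None,
    stream: str = "bm",
) -> pd.DataFrame:
    """Brownian-motion trait draws with covariance sigma^2 V(kappa, delta, lambda).

    One independent multivariate-normal column per requested trait name,
    mean 0; the covariance is the Pagel-transformed tree covariance at the
    config's true transform values.  Deterministic given the seed.
    """
    if not tree.is_ultrametric():
        raise ValueError("BM simulation expects an ultrametric tree")
    rng = config.rng(stream)
    sigma = config.resid_sigma if sigma is None else sigma
    builder = CovarianceBuilder(tree)
    V = builder.vcv(config.transforms())
    L = np.linalg.cholesky(V + 1e-12 * np.eye(len(V)))
    draws = {name: sigma * (L @ rng.standard_normal(len(V))) for name in names}
    return pd.DataFrame(draws, index=pd.Index(builder.taxa, name="species"))


def _bd_transition(counts: np.ndarray, lam: float, mu: float, t: float, rng) -> np.ndarray:
    """Exact linear birth--death transition for each count over a branch.

    Each extant copy founds an independent family; after time t it is extinct
    with probability alpha, else leaves a geometric number of descendants
    with parameter beta (Kendall's solution of the linear BD process).
    """
    if t <= 0 or (lam == 0 and mu == 0):
        return counts.copy()
    if abs(lam - mu) < 1e-12:
        alpha = beta = lam * t / (1.0 + lam * t)
    else:
        e = math.exp((lam - mu) * t)
        alpha = mu * (e - 1.0) / (lam * e - mu)
        beta = lam * (e - 1.0) / (lam * e - mu)
    extinct = rng.binomial(counts, alpha)
    survivors = counts - extinct
    extra = np.zeros_like(counts)
    pos = survivors > 0
    if beta > 0 and pos.any():
        extra[pos] = rng.negative_binomial(survivors[pos], 1.0 - beta)
    return survivors + extra


def _leaves_below(node: Node) -> list[str]:
    out, stack = [], [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n.label)
        stack.extend(n.children)
    return out


def _choose_wgd_clades(tree: PhyloTree, config: SimConfig, rng) -> list[frozenset]:
    if config.wgd_lineages is not None:
        return [frozenset(s) for s in config.wgd_lineages]
    if config.wgd_n_clades <= 0:
        return []
    lo, hi = config.wgd_clade_size
    candidates = []
    for node in tree.preorder():
        if node is tree.root or node.is_leaf:
            continue
        leaves = frozenset(_leaves_below(node))
        if lo <= len(leaves) <= hi:
            candidates.append(leaves)
    chosen: list[frozenset] = []
    order = rng.permutation(len(candidates))
    for idx in order:
        cand = candidates[idx]
        if all(cand.isdisjoint(c) for c in chosen):
            chosen.append(cand)
        if len(chosen) == config.wgd_n_clades:
            break
    return chosen


def simulate_gene_counts(
    tree: PhyloTree, config: SimConfig
) -> tuple[GeneCountTable, pd.DataFrame, dict]:
    """Copy counts for all TSG and OG genes along the tree.

    Per gene, copies start at 2 at the root (the teleost baseline after the
    shared genome duplications) and evolve by a linear birth--death process
    on each branch.  Duplication pressure varies across lineages: a Brownian
    log-rate modifier, shared by every gene, tilts the duplication/loss
    balance on each branch, so species in high-pressure lineages inflate
    both their TSG and OG counts together — the source of the strong
    cross-species TSG-OG correlation.  WGD clades double all counts at the
    clade stem.  A configurable fraction of gene-species pairs is masked as
    not-found to exercise normalization.

    Returns the (masked) count table, the complete ground-truth count
    matrix, and bookkeeping (gene roles, WGD clades, lineage modifiers).
    """
    rng = config.rng("genes")
    genes = [f"tsg{i:03d}" for i in range(1, config.n_tsg + 1)] + [
        f"og{i:03d}" for i in range(1, config.n_og + 1)
    ]
    n_genes = len(genes)
    wgd_clades = _choose_wgd_clades(tree, config, rng)
    wgd_leaves = set().union(*wgd_clades) if wgd_clades else set()
    # stem nodes at which the doubling is applied (one per WGD clade)
    stems: set[int] = set()
    for node in tree.preorder():
        below = frozenset(_leaves_below(node))
        if below in wgd_clades:
            stems.add(id(node))

    r = config.duplication_rate
    leaf_counts: dict[str, np.ndarray] = {}
    modifier: dict[str, float] = {}

    def walk(node: Node, counts: np.ndarray, u: float) -> None:
        if node.length > 0:
            du = rng.normal(0.0, config.rate_modifier_sigma * math.sqrt(node.length))
        else:
            du = 0.0
        # tilt duplication vs loss so that E[count] multiplies by exp(du)
        net = du / node.length if node.length > 0 else 0.0
        lam = max(r + net / 2.0, 0.0)
        mu = max(r - net / 2.0, 0.0)
        new_counts = _bd_transition(counts, lam, mu, node.length, rng)
        if id(node) in stems:
            new_counts = new_counts * 2
        if node.is_leaf:
            leaf_counts[node.label] = new_counts
            modifier[node.label] = u + du
        for ch in node.children:
            walk(ch, new_counts, u + du)

    root_counts = np.full(n_genes, 2, dtype=np.int64)
    walk(tree.root, root_counts, 0.0)

    species = sorted(leaf_counts)
    truth = pd.DataFrame({s: leaf_counts[s] for s in species}, index=genes)

    counts = truth.copy()
    found = pd.DataFrame(True, index=genes, columns=species)
    if config.not_found_fraction > 0:
        if config.lineage_biased_missing:
            # missingness concentrated in a random half of the species
            bad_species = rng.choice(species, size=max(1, len(species) // 2), replace=False)
            probs = pd.Series(config.not_found_fraction / 2, index=species)
            probs[bad_species] = config.not_found_fraction * 1.5
            mask = np.column_stack(
                [rng.random(n_genes) < probs[s] for s in species]
            )
        else:
            mask = rng.random((n_genes, len(species))) < config.not_found_fraction
        found &= ~mask
        counts = counts.where(found, 0)

    table = GeneCountTable(counts=counts.astype(int), found=found)
    meta = {
        "genes_tsg": genes[: config.n_tsg],
        "genes_og": genes[config.n_tsg :],
        "wgd_clades": [sorted(c) for c in wgd_clades],
        "wgd_leaves": sorted(wgd_leaves),
        "lineage_modifier": modifier,
    }
    return table, truth, meta


def gene_trees_from_counts(tree: PhyloTree, table: GeneCountTable) -> dict[str, str]:
    """CAFE-style gene trees encoding the same counts as the table.

    For each gene, the species tree is pruned to the species where the gene
    was found and each leaf label gets the ``_<count>`` suffix.
    """
    out: dict[str, str] = {}
    for gene in table.genes:
        present = [s for s in table.species if bool(table.found.loc[gene, s])]
        if len(present) < 2:
            continue
        sub = tree.prune_to_taxa(present)

        def relabel(node: Node) -> None:
            if node.is_leaf:
                node.label = f"{node.label}_{int(table.counts.loc[gene, node.label])}"
            for c in node.children:
                relabel(c)

        sub = sub.copy()
        relabel(sub.root)
        out[gene] = sub.to_newick()
    return out


def simulate_masked_lifespan(
    tree: PhyloTree,
    normalized: pd.DataFrame,
    config: SimConfig,
) -> pd.DataFrame:
    """Trait table in which lifespan responds to the TSG-OG contrast.

    log10 lifespan = mean + beta_bodysize * (log10 length - its mean)
                   + masking_effect * resid_sigma * standardized(z_tsg - z_og)
                   + Brownian residual (sd resid_sigma, true transforms).

    Body length is itself a Brownian trait.  Because z_tsg and z_og are
    nearly collinear by construction, each count alone carries almost none
    of the lifespan signal — only their contrast (equivalently the TSG/OG
    ratio) does.  Body mass is derived from length by a cubic allometry for
    the longevity-quotient analysis; a seeded fraction of species lose their
    lifespan value, and a fraction is tagged low-quality, to exercise the
    exclusion rules.
    """
    rng = config.rng("traits")
    species = list(normalized.index)
    bm = simulate_bm_traits(tree, config, names=("log_length", "resid"), sigma=1.0, stream="traits_bm")
    bm = bm.loc[species]
    log_length = config.length_log_mean + config.length_log_sigma * bm["log_length"]
    contrast = normalized["z_tsg"] - normalized["z_og"]
    sd = contrast.std(ddof=1)
    signal = contrast / sd if sd > 0 else contrast * 0.0
    log_life = (
        config.lifespan_log_mean
        + config.beta_bodysize * (log_length - config.length_log_mean)
        + config.masking_effect * config.resid_sigma * signal
        + config.resid_sigma * bm["resid"]
    )
    log_mass = math.log10(0.01) + 3.0 * log_length + rng.normal(0.0, 0.05, len(species))
    lifespan = (10.0**log_life).round(1)
    missing = rng.random(len(species)) < config.missing_lifespan_fraction
    lifespan = pd.Series(np.where(missing, np.nan, lifespan), index=species)
    quality = np.where(rng.random(len(species)) < config.low_quality_fraction, "low", "reliable")
    traits = pd.DataFrame(
        {
            "max_length_cm": (10.0**log_length).round(1),
            "max_lifespan_y": lifespan,
            "body_mass_g": (10.0**pd.Series(log_mass, index=species)).round(1),
            "source_quality": quality,
            "family": "",
        },
        index=pd.Index(species, name="species"),
    )
    return traits


@dataclass
class StudyBundle:
    """All pieces of one synthetic study plus its ground truth."""

    config: SimConfig
    tree: PhyloTree
    count_table: GeneCountTable
    truth_counts: pd.DataFrame
    gene_meta: dict
    gene_trees: dict
    normalized: pd.DataFrame
    traits: pd.DataFrame
    cosmic_table: pd.DataFrame
    gatekeeper_map: dict


def _cosmic_like_table(config: SimConfig, meta: dict) -> tuple[pd.DataFrame, dict]:
    rows = []
    gk_map: dict[str, str] = {}
    n_gk = int(round(config.gatekeeper_fraction * config.n_tsg))
    for i, g in enumerate(meta["genes_tsg"]):
        rows.append({"gene": g, "role": "TSG", "tier": 1 if i % 2 == 0 else 2, "somatic": 1, "germline": 0})
        if i < n_gk:
            gk_map[g.upper()] = "gatekeeper"
        elif i < 2 * n_gk:
            gk_map[g.upper()] = "caretaker"
    for i, g in enumerate(meta["genes_og"]):
        rows.append({"gene": g, "role": "oncogene", "tier": 1 if i % 2 == 0 else 2, "somatic": 1, "germline": 0})
    return pd.DataFrame(rows), gk_map


def simulate_study(config: SimConfig, with_gene_trees: bool = True) -> StudyBundle:
    """Run the whole generator: tree, counts, gene trees, traits, annotations.

    ``with_gene_trees=False`` skips emitting the per-gene CAFE trees (the
    slowest output) for replicated power/recovery simulations that consume
    the count table directly.
    """
    from .copy_number import classify_cosmic, build_normalized_counts

    tree = simulate_yule_tree(config)
    table, truth, meta = simulate_gene_counts(tree, config)
    gene_trees = gene_trees_from_counts(tree, table) if with_gene_trees else {}
    cosmic, gk_map = _cosmic_like_table(config, meta)
    classifications, _, _ = classify_cosmic(cosmic, gk_map)
    normalized = build_normalized_counts(table, classifications, tier_max=2)
    traits = simulate_masked_lifespan(tree, normalized, config)
    # family labels: WGD clade members get a duplicated-genome family name
    fam = pd.Series("backgroundidae", index=traits.index)
    for i, clade in enumerate(meta["wgd_clades"]):
        fam[fam.index.isin(clade)] = ("salmonidae", "cyprinidae")[i % 2]
    traits["family"] = fam
    return StudyBundle(
        config=config,
        tree=tree,
        count_table=table,
        truth_counts=truth,
        gene_meta=meta,
        gene_trees=gene_trees,
        normalized=normalized,
        traits=traits,
        cosmic_table=cosmic,
        gatekeeper_map=gk_map,
    )


def write_fixture(bundle: StudyBundle, outdir) -> dict:
    """Write one study as the plain-text formats the ingestion modules read.

    Emits: species_tree.nwk, gene_trees.nwk + gene_map.tsv, counts.tsv +
    counts.found.tsv, traits.csv, cosmic_genes.csv, gatekeeper_caretaker.tsv,
    ground_truth.json.  Returns the path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "species_tree": outdir / "species_tree.nwk",
        "gene_trees": outdir / "gene_trees.nwk",
        "gene_map": outdir / "gene_map.tsv",
        "counts": outdir / "counts.tsv",
        "found": outdir / "counts.found.tsv",
        "traits": outdir / "traits.csv",
        "cosmic": outdir / "cosmic_genes.csv",
        "gatekeeper": outdir / "gatekeeper_caretaker.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    paths["species_tree"].write_text(bundle.tree.to_newick() + "\n")
    write_gene_tree_file(bundle.gene_trees, paths["gene_trees"], paths["gene_map"])
    bundle.count_table.to_tsv(paths["counts"], paths["found"])
    bundle.traits.to_csv(paths["traits"])
    bundle.cosmic_table.to_csv(paths["cosmic"], index=False)
    with open(paths["gatekeeper"], "w") as fh:
        fh.write("gene\ttsg_class\n")
        for g, cls in bundle.gatekeeper_map.items():
            fh.write(f"{g}\t{cls}\n")
    truth = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(bundle.config).items()},
        "counts": {s: bundle.truth_counts[s].tolist() for s in bundle.truth_counts.columns},
        "genes": list(bundle.truth_counts.index),
        "wgd_clades": bundle.gene_meta["wgd_clades"],
    }
    paths["ground_truth"].write_text(json.dumps(truth, indent=1))
    return {k: str(v) for k, v in paths.items()}
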