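"""Synthetic study-shaped datasets with controllable statistical structure.

The generator emulates the post-clustering state of a root-tip sequencing
survey of a tropical-forest plot: ~21 autotrophic plant species sampled a
few root tips each, 5 mycoheterotrophic species, ~115 arbuscular
mycorrhizal fungal OTUs, uneven per-sample read depths, heterogeneous
fungal generality, optional phylogenetic signal in the interactions, and a
tunable preference (gamma) of mycoheterotrophs for fungi that are well
connected to autotrophs. Ground-truth detection probabilities are retained
so recovery tests can compare against them.

The ground truth is a SPECIES-level incidence probability matrix p:

* autotroph block: an additive blend of plant generality and (power-law
  skewed) fungal generality, mixed with a Brownian-on-the-fungal-tree
  component by ``phylo_signal_strength`` (closely related fungi then get
  detected by similar plants);
* mycoheterotroph block: attachment probability proportional to
  (expected autotroph degree of the fungus) ** gamma, scaled to a target
  species-level richness. gamma = 0 gives degree-independent attachment,
  larger gamma concentrates mycoheterotrophs on the best-connected fungi.

A species observed through k root-tip samples uses the per-sample
detection probability q = 1 - (1 - p)^(1/k), so the union of its samples'
detections is Bernoulli(p) regardless of sampling effort: uneven sample
numbers change read depth, not the expected species-level incidence. Read
counts per sample are a symmetric-Dirichlet-weighted multinomial over that
sample's realised fungi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .io import (
    GUILD_AUTOTROPH,
    GUILD_MYCOHETEROTROPH,
    parse_newick,
    write_count_table,
    write_metadata,
    write_newick,
)
from .exceptions import ValidationError
from .motifs import randomize_tripartite
from .networks import TripartiteNetwork


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped defaults: 21 autotrophs (1-9 samples each), 5
    mycoheterotrophs (3-9 samples), 115 fungi; per-sample reads
    ~ 900 + lognormal (median ~3.3k, comfortably above the 500-read filter
    and the 844-read rarefaction depth); moderate fungal degree
    heterogeneity; weak fungal phylogenetic signal; strong mycoheterotroph
    preference for well-connected fungi (gamma = 2)."""

    n_auto: int = 21
    n_mh: int = 5
    n_fungi: int = 115
    samples_per_auto: tuple[int, int] = (1, 9)
    samples_per_mh: tuple[int, int] = (3, 9)
    min_reads: int = 900
    log_reads_mean: float = math.log(2400.0)
    log_reads_sigma: float = 0.7
    degree_exponent: float = 1.0
    plant_generality: tuple[float, float] = (0.05, 0.25)
    fungal_generality_scale: float = 0.10
    fungal_generality_max: float = 0.90
    mh_degree_range: tuple[float, float] = (25.0, 45.0)
    gamma: float = 2.0
    phylo_signal_strength: float = 0.2
    phylo_logistic_slope: float = 2.5
    dirichlet_alpha: float = 1.0
    stress: bool = False  # inject filter-violating shallow samples
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_auto < 1 or self.n_mh < 1 or self.n_fungi < 2:
            raise ValidationError("need >=1 species per guild and >=2 fungi")
        if self.gamma < 0:
            raise ValidationError("gamma must be >= 0")
        if not 0.0 <= self.phylo_signal_strength <= 1.0:
            raise ValidationError("phylo_signal_strength must be in [0, 1]")

    @property
    def auto_ids(self) -> list[str]:
        return [f"Auto{i + 1:02d}" for i in range(self.n_auto)]

    @property
    def mh_ids(self) -> list[str]:
        return [f"Myco{i + 1:02d}" for i in range(self.n_mh)]

    @property
    def fungus_ids(self) -> list[str]:
        return [f"OTU{i + 1:03d}" for i in range(self.n_fungi)]


@dataclass
class SyntheticDataset:
    """Sample-level counts plus metadata, trees and the generating truth."""

    counts: pd.DataFrame
    metadata: pd.DataFrame
    fungal_tree: dendropy.Tree
    plant_tree: dendropy.Tree
    auto_probs: pd.DataFrame
    mh_probs: pd.DataFrame
    config: SimConfig

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_count_table(self.counts, directory / "counts.tsv")
        write_metadata(self.metadata, directory / "samples.tsv")
        write_newick(self.fungal_tree, directory / "fungi.nwk")
        write_newick(self.plant_tree, directory / "plants.nwk")


def generate_tree(
    n_tips: int, rng: np.random.Generator, labels: list[str] | None = None
) -> dendropy.Tree:
    """Random binary tree by sequential random joins of lineages, with
    exponential branch lengths; tips labelled deterministically."""
    if n_tips < 2:
        raise ValidationError("a tree needs at least 2 tips")
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n_tips)]
    if len(labels) != n_tips:
        raise ValidationError("label count must equal n_tips")
    lineages = list(labels)
    while len(lineages) > 1:
        i, j = rng.choice(len(lineages), size=2, replace=False)
        i, j = sorted((int(i), int(j)))
        b1, b2 = rng.exponential(1.0, size=2)
        merged = f"({lineages[i]}:{b1:.6f},{lineages[j]}:{b2:.6f})"
        lineages[i] = merged
        del lineages[j]
    return parse_newick(lineages[0] + ";")


def _brownian_tip_values(
    tree: dendropy.Tree, tips: list[str], rng: np.random.Generator
) -> np.ndarray:
    """One Brownian-motion realisation down the tree; returns tip values in
    the order of ``tips``."""
    values: dict[int, float] = {id(tree.seed_node): 0.0}
    tip_value: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        length = node.edge.length or 0.0
        v = values[id(node.parent_node)] + rng.normal(0.0, math.sqrt(max(length, 1e-12)))
        values[id(node)] = v
        if node.is_leaf():
            tip_value[node.taxon.label] = v
    return np.array([tip_value[t] for t in tips])


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_interactions(
    config: SimConfig,
    fungal_tree: dendropy.Tree,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Species-level incidence probability matrices for both guilds."""
    fungi = config.fungus_ids
    n_f = config.n_fungi

    # skewed fungal generality: truncated power-law tail, so a minority of
    # generalist fungi sits at the cap (the generalist core typical of AM
    # communities) while most fungi are specialists
    raw = 1.0 + rng.pareto(config.degree_exponent, size=n_f)
    c_f = np.clip(
        config.fungal_generality_scale * raw, 0.0, config.fungal_generality_max
    )
    r_a = rng.uniform(*config.plant_generality, size=config.n_auto)
    base = 0.5 * (r_a[:, None] + c_f[None, :])

    s = config.phylo_signal_strength
    if s > 0:
        phylo = np.empty_like(base)
        for i in range(config.n_auto):
            z = _brownian_tip_values(fungal_tree, fungi, rng)
            sd = z.std()
            z = (z - z.mean()) / sd if sd > 0 else z * 0.0
            center = np.log(base[i].mean() / (1.0 - base[i].mean()))
            phylo[i] = _sigmoid(config.phylo_logistic_slope * z + center)
        auto = np.clip((1.0 - s) * base + s * phylo, 0.0, 1.0)
    else:
        auto = np.clip(base, 0.0, 1.0)

    expected_auto_degree = auto.sum(axis=0)
    w = (expected_auto_degree + 1e-9) ** config.gamma
    w = w / w.sum()
    d_m = rng.uniform(*config.mh_degree_range, size=config.n_mh)
    mh = np.clip(d_m[:, None] * w[None, :], 0.0, 0.97)

    auto_probs = pd.DataFrame(auto, index=config.auto_ids, columns=fungi)
    mh_probs = pd.DataFrame(mh, index=config.mh_ids, columns=fungi)
    return auto_probs, mh_probs


def generate_counts(
    auto_probs: pd.DataFrame,
    mh_probs: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    fungal_tree: dendropy.Tree | None = None,
    plant_tree: dendropy.Tree | None = None,
) -> SyntheticDataset:
    """Realise sample-level read counts from the probability matrices."""
    records = []
    count_rows = []
    sample_ids = []
    for species, probs, guild, rng_range in (
        [(sp, auto_probs.loc[sp].to_numpy(), GUILD_AUTOTROPH, config.samples_per_auto)
         for sp in auto_probs.index]
        + [(sp, mh_probs.loc[sp].to_numpy(), GUILD_MYCOHETEROTROPH, config.samples_per_mh)
           for sp in mh_probs.index]
    ):
        n_samples = int(rng.integers(rng_range[0], rng_range[1] + 1))
        # per-sample detection such that the union over this species'
        # samples is Bernoulli(p) at the species level
        q = 1.0 - (1.0 - probs) ** (1.0 / n_samples)
        for k in range(n_samples):
            sample_id = f"{species}_s{k + 1}"
            incidence = rng.random(q.size) < q
            if not incidence.any():
                incidence[int(np.argmax(q))] = True  # every root tip hosts >=1 fungus
            total = config.min_reads + int(
                rng.lognormal(config.log_reads_mean, config.log_reads_sigma)
            )
            if config.stress and rng.random() < 0.2:
                total = int(rng.integers(50, 500))
            realized = np.flatnonzero(incidence)
            weights = rng.dirichlet(np.full(realized.size, config.dirichlet_alpha))
            reads = rng.multinomial(total, weights)
            row = np.zeros(probs.size, dtype=np.int64)
            row[realized] = reads
            count_rows.append(row)
            sample_ids.append(sample_id)
            records.append(
                {
                    "sample_id": sample_id,
                    "species_id": species,
                    "guild": guild,
                    "subplot": f"P{int(rng.integers(1, 3))}",
                }
            )
    counts = pd.DataFrame(
        np.vstack(count_rows), index=sample_ids, columns=list(auto_probs.columns)
    )
    counts.index.name = "id"
    metadata = pd.DataFrame(records)
    return SyntheticDataset(
        counts=counts,
        metadata=metadata,
        fungal_tree=fungal_tree,
        plant_tree=plant_tree,
        auto_probs=auto_probs,
        mh_probs=mh_probs,
        config=config,
    )


def generate_dataset(
    config: SimConfig | None = None, rng: np.random.Generator | None = None
) -> SyntheticDataset:
    """Full synthetic dataset: trees, interaction truth, counts, metadata."""
    config = SimConfig() if config is None else config
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fungal_tree = generate_tree(config.n_fungi, rng, labels=config.fungus_ids)
    plant_tree = generate_tree(
        config.n_auto + config.n_mh, rng, labels=config.auto_ids + config.mh_ids
    )
    auto_probs, mh_probs = generate_interactions(config, fungal_tree, rng)
    return generate_counts(
        auto_probs, mh_probs, config, rng,
        fungal_tree=fungal_tree, plant_tree=plant_tree,
    )


def generate_null_conditioned(
    net: TripartiteNetwork, rng: np.random.Generator
) -> TripartiteNetwork:
    """A tripartite network drawn exactly from the degree-proportional null
    of ``net`` (both blocks randomised separately); used for calibration."""
    return randomize_tripartite(net, rng)
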