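"""Host-structured synthetic phage datasets.

The generator emulates the statistical structure the analyses assume:
a genus-level host tree, one gene pool per host genus with
phylogenetically structured sharing, mosaic genomes that draw mostly
from their own host's pool but acquire foreign genes at a tunable
horizontal-transfer rate (foreign pools weighted by exp(-d/decay) in
host tree distance), and rare singleton genes to exercise the
small-cluster filter. It emulates co-occurrence statistics only — not
genome architecture, synteny, or gene order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from genenet.clustering import ClusterAssignment, assignments_from_map
from genenet.io import GeneRecord, GenomeRecord, HostTree, read_host_tree

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    ``hgt_rate`` is the probability that a gene is drawn from a foreign
    host's pool; foreign hosts are weighted by exp(-d / phylo_decay)
    where d is the host-tree distance. ``singleton_rate`` is the
    per-gene probability of a brand-new private gene. A fixed seed gives
    a bit-identical dataset (single PCG64 stream, fixed draw order).
    """

    n_hosts: int = 8
    tree_shape: str = "balanced"  # or "random-coalescent"
    n_genomes_per_host: int = 10
    genes_per_genome: int = 30
    pool_size_per_host: int = 40
    hgt_rate: float = 0.1
    phylo_decay: float = 1.0
    singleton_rate: float = 0.05
    seed: int = 1
    with_sequences: bool = False
    mutation_rate: float = 0.10
    ancestor_length: tuple[int, int] = (60, 120)

    def __post_init__(self) -> None:
        if self.n_hosts < 2:
            raise ValueError("need at least 2 hosts")
        if not (0 <= self.hgt_rate <= 1 and 0 <= self.singleton_rate <= 1):
            raise ValueError("rates must be in [0, 1]")
        if self.phylo_decay <= 0:
            raise ValueError("phylo_decay must be > 0")
        if min(self.n_genomes_per_host, self.genes_per_genome,
               self.pool_size_per_host) < 1:
            raise ValueError("counts must be positive")
        if self.genes_per_genome > self.pool_size_per_host * self.n_hosts:
            raise ValueError("genes_per_genome exceeds the total gene pool")
        if self.tree_shape not in {"balanced", "random-coalescent"}:
            raise ValueError(f"unknown tree_shape {self.tree_shape!r}")


@dataclass
class SimulatedDataset:
    """Everything a pipeline run needs, with ground truth attached."""

    genomes: list[GenomeRecord]
    genes: list[GeneRecord]
    cluster_assignments: list[ClusterAssignment]
    true_cluster_map: dict[str, str]
    host_tree: HostTree
    host_metadata: dict[str, str]
    config: SimulationConfig = field(repr=False)


def _balanced_newick(labels: list[str]) -> str:
    def rec(ls: list[str]) -> str:
        if len(ls) == 1:
            return f"{ls[0]}:1"
        mid = len(ls) // 2
        return f"({rec(ls[:mid])},{rec(ls[mid:])}):1"

    inner = rec(labels)
    # strip the root's own branch length
    return inner.rsplit(":", 1)[0] + ";"


def _coalescent_newick(labels: list[str], rng: np.random.Generator) -> str:
    """Kingman coalescent: merge uniform pairs at exponential waiting
    times; branch lengths are in coalescent units."""
    nodes = [f"{l}" for l in labels]
    heights = [0.0] * len(labels)
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        bi = t - heights[i]
        bj = t - heights[j]
        merged = f"({nodes[i]}:{bi:.6f},{nodes[j]}:{bj:.6f})"
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)]
        heights = [h for idx, h in enumerate(heights) if idx not in (i, j)]
        nodes.append(merged)
        heights.append(t)
    return nodes[0] + ";"


def _mutate(ancestor: np.ndarray, rate: float,
            rng: np.random.Generator) -> str:
    seq = ancestor.copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        choices = _AA[_AA != seq[i]]
        seq[i] = choices[rng.integers(len(choices))]
    return "".join(seq)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate one host-structured dataset under ``config``.

    Draw order (fixed for reproducibility): host tree (if coalescent),
    then genomes host by host, gene slot by gene slot, then sequences
    cluster by cluster.
    """
    rng = np.random.default_rng(config.seed)
    hosts = [f"Genus{i + 1:02d}" for i in range(config.n_hosts)]
    if config.tree_shape == "balanced":
        newick = _balanced_newick(hosts)
    else:
        newick = _coalescent_newick(hosts, rng)
    host_tree = read_host_tree(newick)

    # exp(-d / decay) weights for foreign-pool choice, per focal host
    dmat = np.array(
        [[host_tree.distance(a, b) for b in hosts] for a in hosts]
    )
    weights = np.exp(-dmat / config.phylo_decay)
    np.fill_diagonal(weights, 0.0)

    pools = {
        h: [f"{h}_g{k + 1:03d}" for k in range(config.pool_size_per_host)]
        for h in hosts
    }

    genomes: list[GenomeRecord] = []
    genes: list[GeneRecord] = []
    true_map: dict[str, str] = {}
    metadata: dict[str, str] = {}
    host_index = {h: i for i, h in enumerate(hosts)}
    for h in hosts:
        for g in range(config.n_genomes_per_host):
            genome_id = f"phage_{h}_{g + 1:02d}"
            metadata[genome_id] = h
            gene_ids = []
            for slot in range(config.genes_per_genome):
                gene_id = f"{genome_id}|{slot + 1}"
                u = rng.random()
                if u < config.singleton_rate:
                    cluster = f"sing_{genome_id}_{slot + 1}"
                elif rng.random() < config.hgt_rate:
                    w = weights[host_index[h]]
                    if w.sum() == 0:
                        donor = h
                    else:
                        donor = hosts[rng.choice(len(hosts), p=w / w.sum())]
                    pool = pools[donor]
                    cluster = pool[rng.integers(len(pool))]
                else:
                    pool = pools[h]
                    cluster = pool[rng.integers(len(pool))]
                gene_ids.append(gene_id)
                true_map[gene_id] = cluster
                genes.append(GeneRecord(gene_id, genome_id))
            genomes.append(GenomeRecord(genome_id, h, tuple(gene_ids)))

    if config.with_sequences:
        by_cluster: dict[str, list[int]] = {}
        for idx, gene in enumerate(genes):
            by_cluster.setdefault(true_map[gene.gene_id], []).append(idx)
        lo, hi = config.ancestor_length
        for cluster in sorted(by_cluster):
            length = int(rng.integers(lo, hi + 1))
            ancestor = _AA[rng.integers(len(_AA), size=length)]
            for idx in by_cluster[cluster]:
                seq = _mutate(ancestor, config.mutation_rate, rng)
                genes[idx] = replace(genes[idx], sequence=seq)

    assignments = assignments_from_map(true_map)
    return SimulatedDataset(
        genomes=genomes,
        genes=genes,
        cluster_assignments=assignments,
        true_cluster_map=true_map,
        host_tree=host_tree,
        host_metadata=metadata,
        config=config,
    )


def permute_labels(
    host_metadata: Mapping[str, str], seed: int
) -> dict[str, str]:
    """Uniformly permute the host column of the metadata, preserving the
    marginal host frequencies (a null model for MI and regression tests)."""
    if not host_metadata:
        raise ValueError("metadata is empty")
    rng = np.random.default_rng(seed)
    keys = list(host_metadata)
    values = [host_metadata[k] for k in keys]
    perm = rng.permutation(len(values))
    return {k: values[p] for k, p in zip(keys, perm)}
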