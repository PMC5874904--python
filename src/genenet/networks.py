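"""The genome x gene-cluster membership matrix P and its two projections.

Two genomes are adjacent in the genome network iff they share a gene
cluster; two clusters are adjacent in the gene network iff some genome
contains both. Both adjacencies are the sign of P P^T (resp. P^T P) with
a zeroed diagonal. Random-edge augmentation is used to raise MCL
granularity before the mimax search.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from genenet.clustering import ClusterAssignment
from genenet.io import GenomeRecord

logger = logging.getLogger(__name__)


@dataclass
class UndirectedNetwork:
    """A simple, unweighted, undirected graph with stable ordered node ids."""

    nodes: tuple[str, ...]
    graph: nx.Graph = field(repr=False)

    @classmethod
    def from_edges(
        cls, nodes: Iterable[str], edges: Iterable[tuple[str, str]]
    ) -> "UndirectedNetwork":
        g = nx.Graph()
        nodes = tuple(str(n) for n in nodes)
        g.add_nodes_from(nodes)
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                continue
            if u not in g or v not in g:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown node")
            g.add_edge(u, v)
        return cls(nodes=nodes, graph=g)

    @classmethod
    def from_adjacency(
        cls, nodes: Sequence[str], adjacency: np.ndarray
    ) -> "UndirectedNetwork":
        a = np.asarray(adjacency)
        edges = [
            (nodes[i], nodes[j])
            for i, j in zip(*np.nonzero(np.triu(a, k=1)))
        ]
        return cls.from_edges(nodes, edges)

    def edges(self) -> list[tuple[str, str]]:
        return [tuple(sorted(e)) for e in self.graph.edges()]

    def edge_set(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(e) for e in self.graph.edges())

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def adjacency_matrix(self) -> np.ndarray:
        return nx.to_numpy_array(self.graph, nodelist=self.nodes, dtype=float)

    def copy(self) -> "UndirectedNetwork":
        return UndirectedNetwork(nodes=self.nodes, graph=self.graph.copy())


@dataclass
class MembershipMatrix:
    """Binary genome x gene-cluster incidence (the pivot of the pipeline)."""

    genomes: tuple[str, ...]
    clusters: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.shape != (len(self.genomes), len(self.clusters)):
            raise ValueError("membership shape mismatch")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("membership entries must be 0/1")
        self.values = v.astype(np.int8)
        self._g_index = {g: i for i, g in enumerate(self.genomes)}
        self._c_index = {c: j for j, c in enumerate(self.clusters)}

    def row(self, genome_id: str) -> np.ndarray:
        return self.values[self._g_index[genome_id]]

    def clusters_of(self, genome_id: str) -> list[str]:
        r = self.row(genome_id)
        return [self.clusters[j] for j in np.nonzero(r)[0]]

    def genomes_with(self, cluster_id: str) -> list[str]:
        col = self.values[:, self._c_index[cluster_id]]
        return [self.genomes[i] for i in np.nonzero(col)[0]]

    def restrict_clusters(self, keep: Iterable[str]) -> "MembershipMatrix":
        keep_set = set(keep)
        idx = [j for j, c in enumerate(self.clusters) if c in keep_set]
        return MembershipMatrix(
            genomes=self.genomes,
            clusters=tuple(self.clusters[j] for j in idx),
            values=self.values[:, idx].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.genomes),
                            columns=list(self.clusters))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MembershipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            genomes=tuple(str(i) for i in df.index),
            clusters=tuple(str(c) for c in df.columns),
            values=df.to_numpy(),
        )


def build_membership(
    genomes: Sequence[GenomeRecord],
    clusters: Sequence[ClusterAssignment],
) -> MembershipMatrix:
    """Build P: entry {i,j} = 1 iff genome i carries >= 1 gene of cluster j
    (paralogs collapse to a single 1). Clusters must already be filtered;
    a genome with an all-zero row should have been excluded upstream and
    raises."""
    gene_to_genome: dict[str, str] = {}
    for genome in genomes:
        for gid in genome.gene_ids:
            gene_to_genome[gid] = genome.genome_id
    genome_ids = tuple(g.genome_id for g in genomes)
    g_index = {g: i for i, g in enumerate(genome_ids)}
    cluster_ids = tuple(c.cluster_id for c in clusters)
    values = np.zeros((len(genome_ids), len(cluster_ids)), dtype=np.int8)
    for j, cluster in enumerate(clusters):
        for gid in cluster.member_gene_ids:
            genome_id = gene_to_genome.get(gid)
            if genome_id is not None:
                values[g_index[genome_id], j] = 1
    empty = [genome_ids[i] for i in np.nonzero(values.sum(axis=1) == 0)[0]]
    if empty:
        raise ValueError(
            "genomes with no cluster membership (exclude them upstream): "
            + ", ".join(empty)
        )
    return MembershipMatrix(genomes=genome_ids, clusters=cluster_ids,
                            values=values)


def project_networks(
    P: MembershipMatrix,
) -> tuple[UndirectedNetwork, UndirectedNetwork]:
    """Project P into the genome network sign(P P^T) and the gene network
    sign(P^T P), diagonals discarded."""
    m = P.values.astype(np.int64)
    a_genome = (m @ m.T > 0).astype(np.int8)
    a_gene = (m.T @ m > 0).astype(np.int8)
    np.fill_diagonal(a_genome, 0)
    np.fill_diagonal(a_gene, 0)
    genome_net = UndirectedNetwork.from_adjacency(list(P.genomes), a_genome)
    gene_net = UndirectedNetwork.from_adjacency(list(P.clusters), a_gene)
    return genome_net, gene_net


def augment_edges(
    network: UndirectedNetwork, edges_per_node: int, seed: int
) -> UndirectedNetwork:
    """Add up to ``edges_per_node`` random edges per node, each to a
    uniformly sampled distinct non-neighbor. The result stays simple,
    original edges are preserved, and the outcome is deterministic for a
    fixed seed; the realized number of added edges is logged (edges
    proposed from both endpoints dedupe)."""
    if edges_per_node < 0:
        raise ValueError("edges_per_node must be >= 0")
    out = network.copy()
    if edges_per_node == 0:
        return out
    rng = np.random.default_rng(seed)
    before = out.n_edges
    for node in out.nodes:
        candidates = sorted(
            set(out.nodes) - {node} - set(out.graph.neighbors(node))
        )
        if not candidates:
            continue
        k = min(edges_per_node, len(candidates))
        if k < edges_per_node:
            logger.info(
                "node %s: only %d non-neighbors available (< %d requested)",
                node, len(candidates), edges_per_node,
            )
        picks = rng.choice(len(candidates), size=k, replace=False)
        for p in picks:
            out.graph.add_edge(node, candidates[p])
    logger.info("edge augmentation added %d edges", out.n_edges - before)
    return out
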