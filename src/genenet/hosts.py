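"""Host-side analyses: genus-level tree handling, host-association
profiles, abundance-weighted mean pairwise phylogenetic distance (MPD),
and the network-topology-versus-host-distance regressions.

A gene cluster's host profile counts, per host genus, the known-host
genomes that carry the cluster; a genome's profile is the elementwise sum
over its clusters. MPD treats a profile as a community of hosts and
averages cophenetic distances between them weighted by relative
abundance — 0 means the profile is single-host.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.sparse.csgraph import shortest_path

from genenet.io import UNKNOWN_HOST, GenomeRecord, HostTree, normalize_genus
from genenet.networks import MembershipMatrix, UndirectedNetwork

logger = logging.getLogger(__name__)


class EmptyProfileError(ValueError):
    """MPD is undefined (not 0) for a profile with no host counts."""


@dataclass
class HostProfile:
    """Host-genus counts for one gene cluster or genome."""

    owner: str
    counts: dict[str, int]

    def total(self) -> int:
        return sum(self.counts.values())

    def nonzero(self) -> dict[str, int]:
        return {h: c for h, c in self.counts.items() if c > 0}

    @property
    def is_single_host(self) -> bool:
        return len(self.nonzero()) == 1

    def __add__(self, other: "HostProfile") -> "HostProfile":
        counts = dict(self.counts)
        for h, c in other.counts.items():
            counts[h] = counts.get(h, 0) + c
        return HostProfile(owner=self.owner, counts=counts)


@dataclass
class PairStats:
    """Topology and host-distance summary for one unordered genome pair."""

    genome_a: str
    genome_b: str
    mean_shortest_path: float | None
    n_unreachable: int
    mean_similarity: float
    host_distance: float


# ---------------------------------------------------------------------------
# Genus collapse


def _node_depths(tree) -> dict:
    depths = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def _mrca(nodes: list, parents: Mapping) -> object:
    chains = []
    for node in nodes:
        chain = []
        cur = node
        while cur is not None:
            chain.append(cur)
            cur = parents[cur]
        chains.append(chain)
    common = set(chains[0])
    for chain in chains[1:]:
        common &= set(chain)
    # deepest common ancestor = first element of any chain that is common
    for node in chains[0]:
        if node in common:
            return node
    raise RuntimeError("disconnected tree")  # pragma: no cover


def collapse_to_genus(
    tree: HostTree,
    genus_map: Mapping[str, str],
    drop: Sequence[str] = (),
) -> HostTree:
    """Collapse a strain-level host tree to one taxon per genus.

    Each genus is placed at the most recent common ancestor (MRCA) of its
    mapped leaves, and genus-genus distances are the path lengths between
    those MRCA nodes on the source tree. ``genus_map`` may merge taxa
    (mapping two species names to one genus) and ``drop`` removes
    misplaced leaves before collapsing. Non-monophyletic genera are
    collapsed at their MRCA anyway, with a warning naming the intruding
    taxa.
    """
    if tree.tree is None:
        raise ValueError("collapse requires the underlying tree")
    dropset = set(drop)
    unmapped = [
        leaf.taxon.label
        for leaf in tree.tree.leaf_node_iter()
        if leaf.taxon.label not in genus_map and leaf.taxon.label not in dropset
    ]
    if unmapped:
        raise ValueError(f"leaves not mapped to a genus: {unmapped[:5]}")

    parents = {}
    leaves_by_genus: dict[str, list] = {}
    leaf_nodes = {}
    for node in tree.tree.preorder_node_iter():
        parents[node] = node.parent_node
    for leaf in tree.tree.leaf_node_iter():
        label = leaf.taxon.label
        if label in dropset:
            continue
        genus = genus_map[label]
        leaves_by_genus.setdefault(genus, []).append(leaf)
        leaf_nodes[label] = leaf

    depths = _node_depths(tree.tree)
    genus_nodes = {}
    for genus, leaves in leaves_by_genus.items():
        node = leaves[0] if len(leaves) == 1 else _mrca(leaves, parents)
        genus_nodes[genus] = node
        if len(leaves) > 1:
            own = {l.taxon.label for l in leaves}
            under = {
                l.taxon.label
                for l in node.leaf_iter()
                if l.taxon.label not in dropset
            }
            intruders = sorted(under - own)
            if intruders:
                logger.warning(
                    "genus %s is non-monophyletic; intruding taxa: %s",
                    genus, ", ".join(intruders),
                )

    genera = tuple(sorted(genus_nodes))
    n = len(genera)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            u, v = genus_nodes[genera[i]], genus_nodes[genera[j]]
            w = _mrca([u, v], parents)
            d[i, j] = d[j, i] = depths[u] + depths[v] - 2 * depths[w]
    return HostTree(taxa=genera, distance_matrix=d, tree=None)


# ---------------------------------------------------------------------------
# Host profiles and MPD


def host_profiles(
    P: MembershipMatrix, genomes: Sequence[GenomeRecord]
) -> tuple[list[HostProfile], list[HostProfile]]:
    """Per-cluster and per-genome host association profiles.

    A cluster's profile counts the known-host genomes containing it; a
    genome's profile sums the profiles of its clusters (so a genome with
    a known host contributes to its own profile — leave-one-out handling
    is done at prediction time). Clusters found only in unknown-host
    genomes get an empty profile and are flagged in the log.
    """
    known = {
        g.genome_id: normalize_genus(g.host_genus)
        for g in genomes
        if g.has_known_host
    }
    host_of = np.array(
        [known.get(gid, "") for gid in P.genomes], dtype=object
    )
    cluster_profiles: list[HostProfile] = []
    empty_clusters = []
    for j, cid in enumerate(P.clusters):
        carriers = np.nonzero(P.values[:, j])[0]
        counts: dict[str, int] = {}
        for i in carriers:
            h = host_of[i]
            if h:
                counts[h] = counts.get(h, 0) + 1
        if not counts:
            empty_clusters.append(cid)
        cluster_profiles.append(HostProfile(owner=cid, counts=counts))
    if empty_clusters:
        logger.warning(
            "%d clusters occur only in unknown-host genomes (empty profiles)",
            len(empty_clusters),
        )
    genome_profiles: list[HostProfile] = []
    for i, gid in enumerate(P.genomes):
        counts = {}
        for j in np.nonzero(P.values[i])[0]:
            for h, c in cluster_profiles[j].counts.items():
                counts[h] = counts.get(h, 0) + c
        genome_profiles.append(HostProfile(owner=gid, counts=counts))
    return cluster_profiles, genome_profiles


def mpd(profile: HostProfile, host_tree: HostTree) -> float:
    """Abundance-weighted mean pairwise phylogenetic distance of a profile.

    With relative abundances f_i, MPD = sum_{i != j} d_ij f_i f_j /
    sum_{i != j} f_i f_j over the hosts present. Single-host profiles
    return exactly 0; an empty profile raises :class:`EmptyProfileError`.
    """
    counts = profile.nonzero()
    if not counts:
        raise EmptyProfileError(f"profile {profile.owner!r} is empty")
    hosts = sorted(counts)
    tree_index = {normalize_genus(t): t for t in host_tree.taxa}
    missing = [h for h in hosts if normalize_genus(h) not in tree_index]
    if missing:
        raise ValueError(f"hosts not in tree: {missing}")
    if len(hosts) == 1:
        return 0.0
    f = np.array([counts[h] for h in hosts], dtype=float)
    f /= f.sum()
    num = 0.0
    den = 0.0
    for i, hi in enumerate(hosts):
        for j, hj in enumerate(hosts):
            if i == j:
                continue
            w = f[i] * f[j]
            num += w * host_tree.distance(
                tree_index[normalize_genus(hi)], tree_index[normalize_genus(hj)]
            )
            den += w
    return num / den


# ---------------------------------------------------------------------------
# Pairwise genome topology on the gene network


def _jaccard_matrix(a: np.ndarray) -> np.ndarray:
    """Open-neighborhood Jaccard similarity for all node pairs.

    J(u,v) = |N(u) & N(v)| / |N(u) | N(v)| with the nodes themselves
    excluded from the neighborhoods; pairs of isolated nodes get 0, and
    the diagonal is 1 by convention.
    """
    common = a @ a
    deg = a.sum(axis=1)
    union = deg[:, None] + deg[None, :] - common
    with np.errstate(divide="ignore", invalid="ignore"):
        j = np.where(union > 0, common / np.where(union > 0, union, 1), 0.0)
    np.fill_diagonal(j, 1.0)
    return j


def pairwise_topology(
    gene_network: UndirectedNetwork,
    genomes: Sequence[GenomeRecord],
    P: MembershipMatrix,
    host_tree: HostTree | None = None,
) -> list[PairStats]:
    """Mean shortest-path and mean neighborhood-similarity statistics for
    every unordered pair of distinct known-host genomes.

    For a genome pair, both means run over the rectangular block of
    (cluster of A) x (cluster of B) cells; identical clusters contribute
    path 0 and similarity 1. Cluster pairs in different components are
    excluded from the path mean and tallied in ``n_unreachable``; a pair
    with no reachable cells has ``mean_shortest_path = None``.
    ``host_distance`` is the genus-level cophenetic distance (0 for a
    shared host genus), or NaN when no tree is given.
    """
    node_index = {n: i for i, n in enumerate(gene_network.nodes)}
    a = gene_network.adjacency_matrix()
    dist = shortest_path(a, method="D", unweighted=True, directed=False)
    sim = _jaccard_matrix(a)

    known = [g for g in genomes if g.has_known_host]
    cluster_idx = {
        g.genome_id: np.array(
            [node_index[c] for c in P.clusters_of(g.genome_id)], dtype=int
        )
        for g in known
    }
    tree_index = (
        {normalize_genus(t): t for t in host_tree.taxa} if host_tree else {}
    )
    out: list[PairStats] = []
    for i in range(len(known)):
        for j in range(i + 1, len(known)):
            ga, gb = known[i], known[j]
            ia, ib = cluster_idx[ga.genome_id], cluster_idx[gb.genome_id]
            block_d = dist[np.ix_(ia, ib)]
            block_s = sim[np.ix_(ia, ib)]
            finite = np.isfinite(block_d)
            n_unreachable = int((~finite).sum())
            mean_path = (
                float(block_d[finite].mean()) if finite.any() else None
            )
            if host_tree is not None:
                ha = tree_index[normalize_genus(ga.host_genus)]
                hb = tree_index[normalize_genus(gb.host_genus)]
                hd = host_tree.distance(ha, hb)
            else:
                hd = math.nan
            out.append(
                PairStats(
                    genome_a=ga.genome_id,
                    genome_b=gb.genome_id,
                    mean_shortest_path=mean_path,
                    n_unreachable=n_unreachable,
                    mean_similarity=float(block_s.mean()),
                    host_distance=hd,
                )
            )
    return out


def pairstats_frame(stats: Sequence[PairStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome_a": s.genome_a,
                "genome_b": s.genome_b,
                "mean_path": s.mean_shortest_path,
                "n_unreachable": s.n_unreachable,
                "mean_similarity": s.mean_similarity,
                "host_distance": s.host_distance,
            }
            for s in stats
        ]
    )


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_used: int
    n_dropped: int


def host_distance_regression(
    stats: Sequence[PairStats], transform: str = "log"
) -> dict[str, RegressionFit]:
    """OLS of host phylogenetic distance on (log-transformed) mean
    shortest path and on (log-transformed) mean neighborhood similarity.

    Pairs with an undefined path mean, or a zero predictor under the log
    transform, are dropped from the corresponding fit and counted in
    ``n_dropped``.
    """
    if transform not in {"log", "none"}:
        raise ValueError("transform must be 'log' or 'none'")
    frames = {}
    for name, getter in (
        ("path", lambda s: s.mean_shortest_path),
        ("similarity", lambda s: s.mean_similarity),
    ):
        xs, ys = [], []
        dropped = 0
        for s in stats:
            x = getter(s)
            if x is None or not np.isfinite(s.host_distance):
                dropped += 1
                continue
            if transform == "log":
                if x <= 0:
                    dropped += 1
                    continue
                x = math.log(x)
            xs.append(x)
            ys.append(s.host_distance)
        if len(xs) < 3:
            raise ValueError(f"{name}: fewer than 3 usable pairs")
        x_arr = np.asarray(xs)
        if np.ptp(x_arr) == 0:
            raise ValueError(f"{name}: predictor has zero variance")
        fit = sm.OLS(np.asarray(ys), sm.add_constant(x_arr)).fit()
        frames[name] = RegressionFit(
            slope=float(fit.params[1]),
            intercept=float(fit.params[0]),
            r_squared=float(fit.rsquared),
            p_value=float(fit.pvalues[1]),
            n_used=len(xs),
            n_dropped=dropped,
        )
    return frames
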