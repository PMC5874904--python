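"""Greedy centroid clustering of homologous proteins and the small-cluster filter.

This is a desk-scale stand-in for UCLUST-style centroid clustering: genes
are processed in order of decreasing length and join the first centroid
whose global-alignment identity meets the threshold, else found a new
cluster. Precomputed cluster maps (e.g., UC files) bypass this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio import Align

from genenet.io import GeneRecord, GenomeRecord, _AA_ALPHABET

logger = logging.getLogger(__name__)

#: Amino-acid identity threshold balancing cluster discovery rate against
#: the frequency of singletons.
DEFAULT_IDENTITY = 0.35
#: Clusters with fewer members than this are discarded before network
#: construction (singletons and doubletons carry unreliable co-occurrence
#: signal).
DEFAULT_MIN_SIZE = 3


@dataclass
class ClusterAssignment:
    """One gene cluster: its members and the centroid that seeded it."""

    cluster_id: str
    member_gene_ids: frozenset[str]
    centroid_gene_id: str
    identity_threshold: float

    def __post_init__(self) -> None:
        if self.centroid_gene_id not in self.member_gene_ids:
            raise ValueError(
                f"cluster {self.cluster_id!r}: centroid not among members"
            )

    @property
    def size(self) -> int:
        return len(self.member_gene_ids)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Fractional identity from a global alignment with fixed scoring
    (match +1, mismatch -1, gap open -5, gap extend -1).

    Identity = matched columns / alignment columns, with terminal-gap
    columns excluded from the denominator. Symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires nonempty sequences")
    aln = _ALIGNER.align(a.upper(), b.upper())[0]
    s1, s2 = str(aln[0]), str(aln[1])
    # Trim terminal gap columns: region where both sequences have started
    # and neither has ended.
    lo = max(len(s1) - len(s1.lstrip("-")), len(s2) - len(s2.lstrip("-")))
    hi = min(len(s1.rstrip("-")), len(s2.rstrip("-")))
    if hi <= lo:
        return 0.0
    matches = sum(1 for i in range(lo, hi) if s1[i] == s2[i] and s1[i] != "-")
    return matches / (hi - lo)


def cluster_proteins(
    genes: Sequence[GeneRecord],
    identity_threshold: float = DEFAULT_IDENTITY,
) -> list[ClusterAssignment]:
    """Greedy centroid clustering of protein sequences.

    Genes are processed by decreasing sequence length (ties broken by
    gene_id); each joins the first existing centroid with pairwise
    identity >= threshold, otherwise it founds a new cluster. The
    procedure is deterministic for a fixed input set.
    """
    if not 0 < identity_threshold < 1:
        raise ValueError("identity_threshold must be in (0, 1)")
    for g in genes:
        if g.sequence is None:
            raise ValueError(f"gene {g.gene_id!r} has no sequence")
        bad = set(g.sequence.upper()) - _AA_ALPHABET
        if bad:
            raise ValueError(
                f"gene {g.gene_id!r} has illegal residues: {''.join(sorted(bad))}"
            )
    ordered = sorted(genes, key=lambda g: (-len(g.sequence), g.gene_id))
    centroids: list[GeneRecord] = []
    members: list[list[str]] = []
    for gene in ordered:
        for k, cen in enumerate(centroids):
            if pairwise_identity(gene.sequence, cen.sequence) >= identity_threshold:
                members[k].append(gene.gene_id)
                break
        else:
            centroids.append(gene)
            members.append([gene.gene_id])
    width = max(5, len(str(len(centroids))))
    return [
        ClusterAssignment(
            cluster_id=f"C{k + 1:0{width}d}",
            member_gene_ids=frozenset(m),
            centroid_gene_id=centroids[k].gene_id,
            identity_threshold=identity_threshold,
        )
        for k, m in enumerate(members)
    ]


def assignments_from_map(
    cluster_map: Mapping[str, str],
    identity_threshold: float = DEFAULT_IDENTITY,
) -> list[ClusterAssignment]:
    """Build ClusterAssignments from a gene->cluster mapping (e.g., a UC
    file); the centroid is taken as the lexicographically first member."""
    by_cluster: dict[str, list[str]] = {}
    for gene_id, cid in cluster_map.items():
        by_cluster.setdefault(cid, []).append(gene_id)
    return [
        ClusterAssignment(
            cluster_id=cid,
            member_gene_ids=frozenset(mem),
            centroid_gene_id=min(mem),
            identity_threshold=identity_threshold,
        )
        for cid, mem in sorted(by_cluster.items())
    ]


def filter_clusters(
    clusters: Iterable[ClusterAssignment],
    min_size: int = DEFAULT_MIN_SIZE,
    genomes: Sequence[GenomeRecord] | None = None,
) -> tuple[list[ClusterAssignment], list[str]]:
    """Drop clusters with fewer than ``min_size`` members and report the
    genomes whose every clustered gene fell in a dropped cluster.

    Returns (retained clusters, excluded genome ids). The exclusion report
    requires ``genomes``; without it the second element is empty.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    clusters = list(clusters)
    retained = [c for c in clusters if c.size >= min_size]
    excluded: list[str] = []
    if genomes is not None:
        kept_genes: set[str] = set()
        for c in retained:
            kept_genes.update(c.member_gene_ids)
        all_clustered: set[str] = set()
        for c in clusters:
            all_clustered.update(c.member_gene_ids)
        for genome in genomes:
            in_clustering = [g for g in genome.gene_ids if g in all_clustered]
            if in_clustering and not any(g in kept_genes for g in in_clustering):
                excluded.append(genome.genome_id)
    if excluded:
        logger.info("small-cluster filter excluded %d genomes", len(excluded))
    return retained, excluded
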