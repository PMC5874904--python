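"""Domain types and readers/writers for the external formats the pipeline touches.

Formats: protein FASTA (one file per genome), TSV host metadata
(genome_id<TAB>host_genus), cluster-map TSV (gene_id<TAB>cluster_id) or
USEARCH UC files, newick host trees with branch lengths, and network edge
lists (plain TSV or Cytoscape SIF).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Sentinel genus used for genomes whose host could not be resolved.
UNKNOWN_HOST = "unknown"

_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class GenomeRecord:
    """A phage genome: its identifier, annotated host genus, and gene ids.

    ``host_genus`` is :data:`UNKNOWN_HOST` when the metadata did not name a
    host; such genomes still enter network construction but are excluded
    from host-linked statistics.
    """

    genome_id: str
    host_genus: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError(f"genome {self.genome_id!r} has no genes")

    @property
    def has_known_host(self) -> bool:
        return self.host_genus != UNKNOWN_HOST


@dataclass(frozen=True)
class GeneRecord:
    """A single protein-coding gene, optionally carrying its sequence."""

    gene_id: str
    genome_id: str
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.sequence is not None:
            bad = set(self.sequence.upper()) - _AA_ALPHABET
            if bad:
                raise ValueError(
                    f"gene {self.gene_id!r} has illegal residues: "
                    f"{''.join(sorted(bad))}"
                )


@dataclass
class HostTree:
    """A host phylogeny together with its cophenetic distance matrix.

    ``taxa`` orders the rows/columns of ``distance_matrix``; entry (i, j)
    is the patristic (branch-length) distance between taxa i and j.
    ``tree`` may be None for derived (genus-collapsed) trees whose matrix
    was computed from ancestor depths on the source tree.
    """

    taxa: tuple[str, ...]
    distance_matrix: np.ndarray
    tree: dendropy.Tree | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.distance_matrix, dtype=float)
        if d.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(d, d.T):
            raise ValueError("cophenetic matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("cophenetic matrix must have zero diagonal")
        if np.any(d < 0):
            raise ValueError("cophenetic distances must be nonnegative")
        self.distance_matrix = d
        self._index = {t: i for i, t in enumerate(self.taxa)}

    def distance(self, a: str, b: str) -> float:
        return float(self.distance_matrix[self._index[a], self._index[b]])

    @property
    def diameter(self) -> float:
        return float(self.distance_matrix.max())


@dataclass
class AnnotationTable:
    """Functional-subsystem annotation counts before and after gene reduction.

    Each row is (subsystem label, count among all genes, count among the
    retained genes); the retained count can never exceed the full count.
    """

    rows: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        labels = [r[0] for r in self.rows]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate subsystem labels")
        for label, pre, post in self.rows:
            if pre < 0 or post < 0 or post > pre:
                raise ValueError(
                    f"row {label!r}: need 0 <= post ({post}) <= pre ({pre})"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["subsystem", "pre", "post"])


# ---------------------------------------------------------------------------
# Dataset loading


def _read_two_column_tsv(path: str | Path, col_a: str, col_b: str) -> pd.DataFrame:
    """Read a 2+ column TSV, tolerating presence or absence of a header row."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two tab-separated columns")
    first = [str(x).strip().lower() for x in df.iloc[0, :2]]
    if first == [col_a, col_b]:
        df = df.iloc[1:, :]
    df = df.iloc[:, :2].copy()
    df.columns = [col_a, col_b]
    df[col_a] = df[col_a].str.strip()
    df[col_b] = df[col_b].str.strip()
    return df.reset_index(drop=True)


def read_host_metadata(path: str | Path) -> dict[str, str]:
    """Read genome_id -> host_genus. Genus tokens are whitespace-stripped;
    comparisons downstream are case-insensitive via :func:`normalize_genus`."""
    df = _read_two_column_tsv(path, "genome_id", "host_genus")
    meta: dict[str, str] = {}
    for _, row in df.iterrows():
        gid = row["genome_id"]
        if gid in meta:
            raise ValueError(f"duplicate genome_id {gid!r} in host metadata")
        meta[gid] = row["host_genus"]
    return meta


def normalize_genus(token: str) -> str:
    """Canonical form for a host genus token (strip + casefold)."""
    return token.strip().casefold()


def read_cluster_map(path: str | Path) -> dict[str, str]:
    """Read gene_id -> cluster_id from a plain TSV or a USEARCH UC file."""
    path = Path(path)
    with open(path) as fh:
        head = fh.readline()
    fields = head.rstrip("\n").split("\t")
    if fields and fields[0] in {"H", "S", "C", "N"} and len(fields) >= 9:
        return _read_uc(path)
    df = _read_two_column_tsv(path, "gene_id", "cluster_id")
    out: dict[str, str] = {}
    for _, row in df.iterrows():
        gid = row["gene_id"]
        if gid in out and out[gid] != row["cluster_id"]:
            raise ValueError(f"gene {gid!r} assigned to two clusters")
        out[gid] = row["cluster_id"]
    return out


def _read_uc(path: Path) -> dict[str, str]:
    """Parse USEARCH UC output: S rows found clusters, H rows join them."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if not f or f[0] not in {"S", "H"}:
                continue
            rec_type, cluster_no = f[0], f[1]
            query = f[8].split(" ", 1)[0]
            out[query] = f"C{cluster_no}"
    return out


def load_dataset(
    fasta_paths: Sequence[str | Path] | None = None,
    host_metadata: str | Path | Mapping[str, str] | None = None,
    cluster_map: str | Path | Mapping[str, str] | None = None,
) -> tuple[list[GenomeRecord], list[GeneRecord]]:
    """Assemble genome and gene records from proteome FASTAs or a cluster map.

    Each FASTA file is one genome (genome_id = file stem). When only a
    cluster map is given, gene ids must follow the ``<genome_id>|<suffix>``
    convention so genes can be attributed to genomes. Genomes missing from
    the host metadata load with ``host_genus = unknown``; a cluster map
    naming a gene absent from the FASTA input is a hard error.
    """
    if fasta_paths is None and cluster_map is None:
        raise ValueError("need fasta_paths or cluster_map")

    meta: dict[str, str] = {}
    if host_metadata is not None:
        if isinstance(host_metadata, (str, Path)):
            meta = read_host_metadata(host_metadata)
        else:
            meta = dict(host_metadata)

    genes: list[GeneRecord] = []
    genome_genes: dict[str, list[str]] = {}

    if fasta_paths is not None:
        seen_gene_ids: set[str] = set()
        collide = False
        parsed: list[tuple[str, list[tuple[str, str]]]] = []
        for path in fasta_paths:
            path = Path(path)
            genome_id = path.stem
            if genome_id in genome_genes:
                raise ValueError(f"duplicate genome_id {genome_id!r}")
            genome_genes[genome_id] = []
            records = [(r.id, str(r.seq).upper().rstrip("*"))
                       for r in SeqIO.parse(str(path), "fasta")]
            if not records:
                raise ValueError(f"genome {genome_id!r} has no genes")
            for rid, _ in records:
                if rid in seen_gene_ids:
                    collide = True
                seen_gene_ids.add(rid)
            parsed.append((genome_id, records))
        for genome_id, records in parsed:
            for ordinal, (rid, seq) in enumerate(records, start=1):
                gene_id = f"{genome_id}|{ordinal}" if collide else rid
                genes.append(GeneRecord(gene_id, genome_id, seq or None))
                genome_genes[genome_id].append(gene_id)
        if collide:
            logger.warning(
                "FASTA headers collide across files; gene ids namespaced as "
                "'<genome_id>|<ordinal>'"
            )
    else:
        cmap = (read_cluster_map(cluster_map)
                if isinstance(cluster_map, (str, Path)) else dict(cluster_map))
        for gene_id in cmap:
            if "|" not in gene_id:
                raise ValueError(
                    f"gene {gene_id!r}: cannot infer source genome "
                    "(expected '<genome_id>|<suffix>')"
                )
            genome_id = gene_id.split("|", 1)[0]
            genome_genes.setdefault(genome_id, []).append(gene_id)
            genes.append(GeneRecord(gene_id, genome_id))

    if fasta_paths is not None and cluster_map is not None:
        cmap = (read_cluster_map(cluster_map)
                if isinstance(cluster_map, (str, Path)) else dict(cluster_map))
        known = {g.gene_id for g in genes}
        for gene_id in cmap:
            if gene_id not in known:
                raise ValueError(
                    f"cluster map references unknown gene {gene_id!r}"
                )

    genomes = []
    for genome_id, gene_ids in genome_genes.items():
        host = meta.get(genome_id, UNKNOWN_HOST)
        if not host or normalize_genus(host) in {"unknown", "na", "none", ""}:
            host = UNKNOWN_HOST
        genomes.append(GenomeRecord(genome_id, host, tuple(gene_ids)))
    return genomes, genes


# ---------------------------------------------------------------------------
# Host trees


def read_host_tree(newick: str | Path) -> HostTree:
    """Read a newick phylogeny with branch lengths and compute its
    cophenetic (patristic) distance matrix.

    Every non-root edge must carry a length; unrooted input is midpoint
    rooted (which leaves patristic distances unchanged) and logged.
    """
    src = Path(newick)
    if src.exists():
        tree = dendropy.Tree.get(path=str(src), schema="newick")
    else:
        tree = dendropy.Tree.get(data=str(newick), schema="newick")

    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("newick tree is missing branch lengths")

    if not tree.is_rooted:
        # Rooting does not change patristic distances; midpoint rooting is
        # cosmetic determinism and falls back to the as-read rooting when
        # the midpoint lands on a degenerate edge.
        try:
            if tree.length() > 0:
                tree.reroot_at_midpoint(update_bipartitions=False)
            logger.info("unrooted input tree rooted at midpoint")
        except (AssertionError, ValueError):
            logger.info("midpoint rooting failed; keeping as-read rooting")
        tree.is_rooted = True

    taxa = tuple(sorted(leaf.taxon.label for leaf in tree.leaf_node_iter()))
    pdm = tree.phylogenetic_distance_matrix()
    tns = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.distance(tns[taxa[i]], tns[taxa[j]])
    if n > 1 and np.any(d[~np.eye(n, dtype=bool)] == 0):
        logger.warning("distinct leaves at zero cophenetic distance "
                       "(zero-length terminal branches)")
    return HostTree(taxa=taxa, distance_matrix=d, tree=tree)


# ---------------------------------------------------------------------------
# Network export / import


def export_network(network, path: str | Path, format: str = "edge_tsv") -> Path:
    """Write a network as an edge list, one undirected edge per line with
    endpoints in lexicographic order; isolated nodes go to a ``.nodes``
    sidecar so round trips preserve the node set."""
    if len(network.nodes) == 0:
        raise ValueError("refusing to export an empty network")
    path = Path(path)
    edges = sorted(tuple(sorted((str(u), str(v)))) for u, v in network.edges())
    with open(path, "w") as fh:
        for u, v in edges:
            if format == "sif":
                fh.write(f"{u}\tco\t{v}\n")
            elif format == "edge_tsv":
                fh.write(f"{u}\t{v}\n")
            else:
                raise ValueError(f"unknown format {format!r}")
    sidecar = path.with_suffix(path.suffix + ".nodes")
    with open(sidecar, "w") as fh:
        for node in sorted(str(n) for n in network.nodes):
            fh.write(f"{node}\n")
    return path


def read_network(path: str | Path):
    """Read an edge list written by :func:`export_network` (either format),
    restoring isolated nodes from the sidecar when present."""
    from genenet.networks import UndirectedNetwork

    path = Path(path)
    edges: list[tuple[str, str]] = []
    nodes: list[str] = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) == 3 and f[1] == "co":
                edges.append((f[0], f[2]))
            elif len(f) == 2:
                edges.append((f[0], f[1]))
            elif line.strip():
                raise ValueError(f"{path}: malformed edge line {line!r}")
    sidecar = path.with_suffix(path.suffix + ".nodes")
    if sidecar.exists():
        nodes = [ln.strip() for ln in open(sidecar) if ln.strip()]
    else:
        seen: dict[str, None] = {}
        for u, v in edges:
            seen.setdefault(u)
            seen.setdefault(v)
        nodes = list(seen)
    return UndirectedNetwork.from_edges(nodes, edges)


# ---------------------------------------------------------------------------
# Annotation tables


def read_annotation_table(path: str | Path | None = None) -> AnnotationTable:
    """Read a subsystem annotation table (TSV: subsystem, pre, post).

    With no path, loads the packaged table of RAST subsystem counts for
    phage genes before and after the mimax reduction. A ``Total`` row, if
    present, is dropped (it is an aggregate, not an observation).
    """
    if path is None:
        ref = resources.files("genenet.data") / "phage_subsystem_annotations.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower() for c in df.columns]
    rows = [
        (str(r["subsystem"]), int(r["pre"]), int(r["post"]))
        for _, r in df.iterrows()
        if str(r["subsystem"]).strip().lower() != "total"
    ]
    return AnnotationTable(rows=rows)
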