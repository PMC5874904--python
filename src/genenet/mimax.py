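"""Mutual information between graph clusters and host genera, and the
constrained greedy *mimax* search.

The chi matrix counts, for each MCL cluster (row) and host genus
(column), how many known-host genome associations the cluster's gene
clusters carry. mimax is a single-chain stochastic hill climber: it
repeatedly proposes deleting a random retained row, rejects the proposal
if any genome would lose its last retained gene cluster, and otherwise
accepts iff the deletion strictly increases the mutual information
between rows and columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from genenet.hosts import HostProfile
from genenet.mcl import MclParams, MclResult, mcl_cluster
from genenet.networks import MembershipMatrix, UndirectedNetwork, augment_edges

logger = logging.getLogger(__name__)


@dataclass
class ChiMatrix:
    """MCL-cluster x host-genus count matrix with row provenance.

    ``provenance`` maps each row (MCL cluster label) to the gene-cluster
    ids it aggregates, which is what the genome-coverage constraint of
    mimax is evaluated against.
    """

    row_labels: tuple[int, ...]
    hosts: tuple[str, ...]
    counts: np.ndarray
    provenance: dict[int, frozenset[str]]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (len(self.row_labels), len(self.hosts)):
            raise ValueError("chi shape mismatch")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("chi entries must be nonnegative integers")
        if len(self.row_labels) and np.any(c.sum(axis=1) == 0):
            raise ValueError("chi has an all-zero row at construction")
        self.counts = c

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels),
                            columns=list(self.hosts))


def build_chi(
    mcl_result: MclResult, cluster_profiles: Sequence[HostProfile]
) -> ChiMatrix:
    """Aggregate gene-cluster host profiles by MCL cluster.

    Entry {i, j} sums host-j counts over the gene clusters labeled i.
    MCL clusters whose gene clusters all have empty profiles (only seen
    in unknown-host genomes) would yield all-zero rows and are dropped
    with a warning.
    """
    by_owner = {p.owner: p for p in cluster_profiles}
    unlabeled = [o for o in by_owner if o not in mcl_result.partition]
    if unlabeled:
        raise ValueError(f"gene clusters without an MCL label: {unlabeled[:5]}")
    hosts = tuple(sorted({h for p in cluster_profiles for h in p.nonzero()}))
    h_index = {h: j for j, h in enumerate(hosts)}
    labels = sorted(set(mcl_result.partition.values()))
    rows = []
    keep_labels = []
    provenance: dict[int, frozenset[str]] = {}
    for label in labels:
        members = [
            o for o, l in mcl_result.partition.items()
            if l == label and o in by_owner
        ]
        if not members:
            continue
        row = np.zeros(len(hosts), dtype=np.int64)
        for o in members:
            for h, c in by_owner[o].nonzero().items():
                row[h_index[h]] += c
        if row.sum() == 0:
            logger.warning(
                "MCL cluster %d has no known-host associations; dropped", label
            )
            continue
        rows.append(row)
        keep_labels.append(label)
        provenance[label] = frozenset(members)
    return ChiMatrix(
        row_labels=tuple(keep_labels),
        hosts=hosts,
        counts=np.array(rows, dtype=np.int64),
        provenance=provenance,
    )


def mutual_information(chi: ChiMatrix | np.ndarray) -> float:
    """Mutual information (nats) between the row and column variables of
    a count matrix: I = sum p(x,y) ln[p(x,y) / (p(x) p(y))], with zero
    cells contributing 0."""
    counts = chi.counts if isinstance(chi, ChiMatrix) else np.asarray(chi)
    counts = counts.astype(float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("mutual information of an all-zero matrix")
    p = counts / total
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (px * py))
    return float(np.nansum(np.where(p > 0, terms, 0.0)))


@dataclass
class MimaxState:
    """Outcome of one mimax chain: retained rows, final MI, full trace."""

    retained_rows: tuple[int, ...]
    current_mi: float
    trace: list[tuple[int, int, bool, float]] = field(repr=False)
    rng_seed: int = 0
    n_iterations: int = 0

    def accepted_mis(self) -> list[float]:
        return [mi for _, _, acc, mi in self.trace if acc]

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.trace, columns=["iteration", "proposed_row", "accepted", "mi"]
        )


def _coverage_matrix(chi: ChiMatrix, P: MembershipMatrix) -> np.ndarray:
    """Boolean genome x chi-row matrix: does the genome carry any gene
    cluster belonging to that row?"""
    c_index = {c: j for j, c in enumerate(P.clusters)}
    cov = np.zeros((len(P.genomes), len(chi.row_labels)), dtype=bool)
    for k, label in enumerate(chi.row_labels):
        cols = [c_index[c] for c in chi.provenance[label] if c in c_index]
        if cols:
            cov[:, k] = P.values[:, cols].any(axis=1)
    return cov


def mimax_search(
    chi: ChiMatrix,
    P: MembershipMatrix,
    max_iterations: int = 100_000,
    patience: int | None = None,
    seed: int = 0,
) -> MimaxState:
    """Constrained stochastic hill climb on row deletions of chi.

    Each iteration samples a retained row uniformly; the deletion is
    rejected outright if it would leave any covered genome with zero
    retained gene clusters, and otherwise accepted iff the MI strictly
    increases. The chain stops after ``patience`` consecutive
    non-accepted proposals (default: 10x the initial row count) or
    ``max_iterations``. The trace records every proposal.
    """
    n_rows = len(chi.row_labels)
    mi0 = mutual_information(chi)
    if n_rows <= 1:
        return MimaxState(
            retained_rows=chi.row_labels, current_mi=mi0, trace=[],
            rng_seed=seed,
        )
    if patience is None:
        patience = 10 * n_rows
    rng = np.random.default_rng(seed)
    cov = _coverage_matrix(chi, P)
    covered = cov.any(axis=1)
    ignored = int((~covered).sum())
    if ignored:
        logger.info(
            "%d genomes carry no gene cluster in any chi row; "
            "not part of the coverage constraint", ignored,
        )
    cov = cov[covered]
    cov_counts = cov.sum(axis=1).astype(np.int64)

    retained = np.ones(n_rows, dtype=bool)
    current = mi0
    trace: list[tuple[int, int, bool, float]] = []
    misses = 0
    it = 0
    while it < max_iterations and misses < patience and retained.sum() > 1:
        it += 1
        alive = np.nonzero(retained)[0]
        k = int(alive[rng.integers(len(alive))])
        label = chi.row_labels[k]
        # genomes whose entire retained coverage is this row
        would_orphan = np.any(cov[:, k] & (cov_counts == cov[:, k]))
        if would_orphan:
            trace.append((it, label, False, current))
            misses += 1
            continue
        trial = retained.copy()
        trial[k] = False
        mi = mutual_information(chi.counts[trial])
        if mi > current:
            retained = trial
            cov_counts -= cov[:, k]
            current = mi
            misses = 0
            trace.append((it, label, True, mi))
        else:
            misses += 1
            trace.append((it, label, False, current))
    return MimaxState(
        retained_rows=tuple(
            l for l, keep in zip(chi.row_labels, retained) if keep
        ),
        current_mi=current,
        trace=trace,
        rng_seed=seed,
        n_iterations=it,
    )


def exhaustive_best_subset(
    chi: ChiMatrix, P: MembershipMatrix
) -> tuple[tuple[int, ...], float]:
    """Enumerate every feasible row subset (brute force; only viable for
    small chi) and return the MI-optimal one. Feasible = every initially
    covered genome keeps >= 1 row. Used as the oracle for mimax tests."""
    from itertools import combinations

    n = len(chi.row_labels)
    if n > 20:
        raise ValueError("exhaustive search is for small instances only")
    cov = _coverage_matrix(chi, P)
    cov = cov[cov.any(axis=1)]
    best: tuple[tuple[int, ...], float] | None = None
    for size in range(1, n + 1):
        for subset in combinations(range(n), size):
            mask = np.zeros(n, dtype=bool)
            mask[list(subset)] = True
            if not np.all(cov[:, mask].any(axis=1)):
                continue
            counts = chi.counts[mask]
            if counts.sum() == 0:
                continue
            mi = mutual_information(counts)
            if best is None or mi > best[1]:
                best = (tuple(chi.row_labels[i] for i in subset), mi)
    assert best is not None
    return best


def granularity_boost(
    gene_network: UndirectedNetwork,
    inflation: float = 15.0,
    edges_per_node: int = 5,
    seed: int = 0,
    params: MclParams | None = None,
) -> MclResult:
    """Raise MCL granularity before mimax: add random edges (which break
    ties between near-equivalent nodes) and cluster at a high inflation.
    With ``edges_per_node=0`` and the base inflation this reduces to a
    plain MCL run."""
    from dataclasses import replace

    augmented = augment_edges(gene_network, edges_per_node, seed)
    base = params or MclParams()
    result = mcl_cluster(augmented, replace(base, inflation=inflation))
    logger.info(
        "granularity boost: %d clusters at inflation %.3g with %d extra "
        "edges/node", result.n_clusters, inflation, edges_per_node,
    )
    return result
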