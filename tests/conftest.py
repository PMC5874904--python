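import numpy as np
import pytest

from genenet.io import GenomeRecord, HostTree
from genenet.networks import MembershipMatrix, UndirectedNetwork


@pytest.fixture
def triangle_pair() -> UndirectedNetwork:
    return UndirectedNetwork.from_edges(
        "abcdef",
        [("a", "b"), ("b", "c"), ("a", "c"),
         ("d", "e"), ("e", "f"), ("d", "f")],
    )


@pytest.fixture
def toy_host_tree() -> HostTree:
    # A and B are sisters (d=2), C is the outgroup (d=4 to each)
    return HostTree(
        taxa=("A", "B", "C"),
        distance_matrix=np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float),
    )


@pytest.fixture
def toy_membership() -> tuple[MembershipMatrix, list[GenomeRecord]]:
    """3 genomes over 3 clusters forming a small shared structure."""
    P = MembershipMatrix(
        genomes=("G1", "G2", "G3"),
        clusters=("c1", "c2", "c3"),
        values=np.array([[1, 1, 0], [0, 1, 1], [0, 0, 1]]),
    )
    genomes = [
        GenomeRecord("G1", "A", ("G1|1", "G1|2")),
        GenomeRecord("G2", "A", ("G2|1", "G2|2")),
        GenomeRecord("G3", "B", ("G3|1",)),
    ]
    return P, genomes
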