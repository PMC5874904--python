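"""Regenerate mcl_reference_partitions.json.

The partitions come from the self-contained Markov-cluster implementation
below, written independently of the package (different code layout and
loop structure, same published algorithm: self-loops, column
normalization, expansion by squaring, entrywise inflation, pruning, and
component read-off of the limit matrix). The structured graphs — disjoint
cliques, a single clique, caveman rings — have analytically known
partitions and were verified by hand; the remaining graphs pin down
behavior on less regular topologies.

Run from the repository root:  python tests/data/make_mcl_fixture.py
"""

import json
from pathlib import Path

import networkx as nx
import numpy as np

INFLATIONS = [1.5, 2.0, 4.0]


def reference_mcl(adj, inflation, loop=1.0, prune=1e-8, tol=1e-6, limit=200):
    n = adj.shape[0]
    m = adj.astype(float) + loop * np.eye(n)
    for col in range(n):
        m[:, col] = m[:, col] / m[:, col].sum()
    for _ in range(limit):
        old = m.copy()
        m = m @ m
        m = m ** inflation
        m[m < prune] = 0.0
        for col in range(n):
            s = m[:, col].sum()
            if s > 0:
                m[:, col] = m[:, col] / s
        if np.abs(m - old).max() < tol:
            break
    # clusters = connected components of the symmetrized support
    support = (m + m.T) > 0
    seen = [False] * n
    clusters = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in range(n):
                if support[u, v] and not seen[v]:
                    seen[v] = True
                    stack.append(v)
        clusters.append(sorted(comp))
    return clusters


def graphs():
    out = {}
    g = nx.Graph()
    g.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    out["two_triangles"] = g
    out["k5"] = nx.complete_graph(5)
    b = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
    b.add_edge(0, 4)
    out["barbell_k4"] = b
    out["path8"] = nx.path_graph(8)
    out["star9"] = nx.star_graph(8)
    out["caveman_4x5"] = nx.connected_caveman_graph(4, 5)
    out["petersen"] = nx.petersen_graph()
    out["grid_4x5"] = nx.convert_node_labels_to_integers(
        nx.grid_2d_graph(4, 5)
    )
    t = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(6))
    t.add_edges_from([(0, 6), (1, 7)])
    out["two_k6_bridge"] = t
    out["er20_p02"] = nx.gnp_random_graph(20, 0.2, seed=5)
    out["ring_of_cliques"] = nx.ring_of_cliques(4, 5)
    out["lollipop"] = nx.lollipop_graph(6, 4)
    return out


def main():
    fixture = {}
    for name, g in sorted(graphs().items()):
        nodes = sorted(g.nodes())
        adj = nx.to_numpy_array(g, nodelist=nodes)
        edges = sorted([sorted([str(u), str(v)]) for u, v in g.edges()])
        entry = {"nodes": [str(n) for n in nodes], "edges": edges,
                 "partitions": {}}
        for infl in INFLATIONS:
            clusters = reference_mcl(adj, infl)
            entry["partitions"][str(infl)] = sorted(
                [sorted(str(nodes[i]) for i in c) for c in clusters]
            )
        fixture[name] = entry
    path = Path(__file__).parent / "mcl_reference_partitions.json"
    path.write_text(json.dumps(fixture, indent=1))
    print(f"wrote {path}")
    for name, entry in fixture.items():
        sizes = {i: sorted(len(c) for c in p)
                 for i, p in entry["partitions"].items()}
        print(name, sizes)


if __name__ == "__main__":
    main()
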