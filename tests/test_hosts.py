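import math

import numpy as np
import pytest

from genenet.hosts import (
    EmptyProfileError,
    HostProfile,
    collapse_to_genus,
    host_distance_regression,
    host_profiles,
    mpd,
    pairwise_topology,
)
from genenet.io import GenomeRecord, HostTree, read_host_tree
from genenet.networks import MembershipMatrix, UndirectedNetwork


def mpd_brute_force(counts, dist):
    """Independent double-sum oracle over all ordered host pairs."""
    hosts = sorted(h for h, c in counts.items() if c > 0)
    total = sum(counts[h] for h in hosts)
    f = {h: counts[h] / total for h in hosts}
    num = den = 0.0
    for a in hosts:
        for b in hosts:
            if a == b:
                continue
            num += f[a] * f[b] * dist[a][b]
            den += f[a] * f[b]
    return 0.0 if den == 0 else num / den


class TestCollapseToGenus:
    def test_strain_pair_collapses_to_mrca(self):
        tree = read_host_tree("((A1:1,A2:1):1,B:2);")
        out = collapse_to_genus(tree, {"A1": "A", "A2": "A", "B": "B"})
        assert out.taxa == ("A", "B")
        assert out.distance("A", "B") == pytest.approx(3.0)

    def test_already_genus_level_is_identity(self):
        tree = read_host_tree("((A:1,B:1):1,C:2);")
        out = collapse_to_genus(tree, {t: t for t in "ABC"})
        for a in "ABC":
            for b in "ABC":
                assert out.distance(a, b) == pytest.approx(tree.distance(a, b))

    def test_drop_list_removes_taxon(self):
        tree = read_host_tree("((A:1,B:1):1,C:2);")
        out = collapse_to_genus(tree, {"A": "A", "B": "B"}, drop=["C"])
        assert out.taxa == ("A", "B")

    def test_non_monophyletic_genus_collapses_with_warning(self, caplog):
        # X1 and X2 straddle Y: their MRCA subtree contains Y
        # (explicitly rooted so the MRCA placement is unambiguous)
        tree = read_host_tree("[&R] ((X1:1,Y:1):1,X2:2);")
        import logging

        with caplog.at_level(logging.WARNING):
            out = collapse_to_genus(tree, {"X1": "X", "X2": "X", "Y": "Y"})
        assert "Y" in " ".join(r.message for r in caplog.records)
        # X collapses to the root; distance measured from there
        assert out.distance("X", "Y") == pytest.approx(2.0)


class TestHostProfiles:
    def test_cluster_and_genome_counting(self):
        P = MembershipMatrix(
            ("G1", "G2", "G3"), ("c1", "c2"),
            np.array([[1, 1], [1, 1], [1, 0]]),
        )
        genomes = [GenomeRecord("G1", "E", ("G1|1",)),
                   GenomeRecord("G2", "E", ("G2|1",)),
                   GenomeRecord("G3", "S", ("G3|1",))]
        cluster_profiles, genome_profiles = host_profiles(P, genomes)
        assert cluster_profiles[0].counts == {"e": 2, "s": 1}
        assert cluster_profiles[1].counts == {"e": 2}
        # genome profile = sum over its clusters
        assert genome_profiles[0].counts == {"e": 4, "s": 1}

    def test_unknown_host_genomes_do_not_count(self):
        P = MembershipMatrix(("G1", "G2"), ("c1",), np.array([[1], [1]]))
        genomes = [GenomeRecord("G1", "E", ("G1|1",)),
                   GenomeRecord("G2", "unknown", ("G2|1",))]
        cluster_profiles, _ = host_profiles(P, genomes)
        assert cluster_profiles[0].counts == {"e": 1}

    def test_cluster_only_in_unknown_hosts_has_empty_profile(self):
        P = MembershipMatrix(("G1",), ("c1",), np.array([[1]]))
        genomes = [GenomeRecord("G1", "unknown", ("G1|1",))]
        cluster_profiles, _ = host_profiles(P, genomes)
        assert cluster_profiles[0].counts == {}


class TestMpd:
    def test_single_host_is_exactly_zero(self, toy_host_tree):
        assert mpd(HostProfile("x", {"A": 7}), toy_host_tree) == 0.0

    def test_two_hosts_equal_their_distance(self, toy_host_tree):
        assert mpd(HostProfile("x", {"A": 1, "C": 1}),
                   toy_host_tree) == pytest.approx(4.0)
        assert mpd(HostProfile("x", {"A": 5, "C": 1}),
                   toy_host_tree) == pytest.approx(4.0)

    def test_weighted_three_host_value(self, toy_host_tree):
        prof = HostProfile("x", {"A": 2, "B": 1, "C": 1})
        assert mpd(prof, toy_host_tree) == pytest.approx(3.2)

    def test_empty_profile_raises_not_zero(self, toy_host_tree):
        with pytest.raises(EmptyProfileError):
            mpd(HostProfile("x", {}), toy_host_tree)

    def test_agreement_with_brute_force_on_random_inputs(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            n = int(rng.integers(2, 7))
            taxa = tuple(f"T{i}" for i in range(n))
            # random additive distances from random points on a line
            pos = rng.random(n) * 10
            d = np.abs(pos[:, None] - pos[None, :])
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            if n > 1 and np.any(d[~np.eye(n, dtype=bool)] == 0):
                continue
            tree = HostTree(taxa, d)
            counts = {t: int(rng.integers(0, 5)) for t in taxa}
            if sum(counts.values()) == 0:
                counts[taxa[0]] = 1
            dist = {a: {b: d[i, j] for j, b in enumerate(taxa)}
                    for i, a in enumerate(taxa)}
            prof = HostProfile("x", counts)
            assert mpd(prof, tree) == pytest.approx(
                mpd_brute_force(counts, dist), abs=1e-10)

    def test_scaling_invariance_and_diameter_bound(self, toy_host_tree):
        prof = HostProfile("x", {"A": 2, "B": 1, "C": 1})
        scaled = HostProfile("x", {"A": 20, "B": 10, "C": 10})
        assert mpd(prof, toy_host_tree) == pytest.approx(
            mpd(scaled, toy_host_tree))
        assert mpd(prof, toy_host_tree) <= toy_host_tree.diameter


class TestPairwiseTopology:
    def path_net(self):
        return UndirectedNetwork.from_edges(
            ["c1", "c2", "c3"], [("c1", "c2"), ("c2", "c3")])

    def test_single_gene_pair_distance(self):
        P = MembershipMatrix(("G1", "G2"), ("c1", "c2", "c3"),
                             np.array([[1, 0, 0], [0, 0, 1]]))
        genomes = [GenomeRecord("G1", "A", ("G1|1",)),
                   GenomeRecord("G2", "B", ("G2|1",))]
        stats = pairwise_topology(self.path_net(), genomes, P)
        assert stats[0].mean_shortest_path == pytest.approx(2.0)

    def test_block_mean_includes_shared_cluster_zero(self):
        P = MembershipMatrix(("G1", "G2"), ("c1", "c2", "c3"),
                             np.array([[1, 1, 0], [0, 1, 1]]))
        genomes = [GenomeRecord("G1", "A", ("G1|1",)),
                   GenomeRecord("G2", "B", ("G2|1",))]
        stats = pairwise_topology(self.path_net(), genomes, P)
        # cells: d(c1,c2)=1, d(c1,c3)=2, d(c2,c2)=0, d(c2,c3)=1
        assert stats[0].mean_shortest_path == pytest.approx(1.0)

    def test_jaccard_of_structurally_equivalent_endpoints(self):
        # c1 and c3 both have open neighborhood {c2} -> J=1; J(c1,c2)=0
        P = MembershipMatrix(("G1", "G2"), ("c1", "c2", "c3"),
                             np.array([[1, 0, 0], [0, 0, 1]]))
        genomes = [GenomeRecord("G1", "A", ("G1|1",)),
                   GenomeRecord("G2", "B", ("G2|1",))]
        stats = pairwise_topology(self.path_net(), genomes, P)
        assert stats[0].mean_similarity == pytest.approx(1.0)

    def test_unreachable_pairs_tallied_not_averaged(self):
        net = UndirectedNetwork.from_edges(["c1", "c2"], [])
        P = MembershipMatrix(("G1", "G2"), ("c1", "c2"),
                             np.array([[1, 0], [0, 1]]))
        genomes = [GenomeRecord("G1", "A", ("G1|1",)),
                   GenomeRecord("G2", "B", ("G2|1",))]
        stats = pairwise_topology(net, genomes, P)
        assert stats[0].mean_shortest_path is None
        assert stats[0].n_unreachable == 1

    def test_unknown_host_genomes_skipped(self):
        P = MembershipMatrix(("G1", "G2"), ("c1", "c2"),
                             np.array([[1, 0], [0, 1]]))
        genomes = [GenomeRecord("G1", "A", ("G1|1",)),
                   GenomeRecord("G2", "unknown", ("G2|1",))]
        stats = pairwise_topology(self.path_net(), genomes, P)
        assert stats == []

    def test_host_distance_zero_iff_same_genus(self, toy_host_tree):
        P = MembershipMatrix(("G1", "G2", "G3"), ("c1", "c2", "c3"),
                             np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]]))
        genomes = [GenomeRecord("G1", "A", ("G1|1",)),
                   GenomeRecord("G2", "A", ("G2|1",)),
                   GenomeRecord("G3", "C", ("G3|1",))]
        stats = pairwise_topology(self.path_net(), genomes, P, toy_host_tree)
        by_pair = {(s.genome_a, s.genome_b): s.host_distance for s in stats}
        assert by_pair[("G1", "G2")] == 0.0
        assert by_pair[("G1", "G3")] == pytest.approx(4.0)


class TestHostDistanceRegression:
    def synth_stats(self, xs, ys):
        from genenet.hosts import PairStats

        return [
            PairStats(f"a{i}", f"b{i}", x, 0, x / 10.0, y)
            for i, (x, y) in enumerate(zip(xs, ys))
        ]

    def test_perfect_log_linear_fit(self):
        xs = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        ys = 2.0 * np.log(xs) + 1.0
        fits = host_distance_regression(self.synth_stats(xs, ys))
        assert fits["path"].r_squared == pytest.approx(1.0)
        assert fits["path"].slope == pytest.approx(2.0)

    def test_permuted_response_has_near_zero_r_squared(self):
        rng = np.random.default_rng(5)
        xs = rng.random(200) * 5 + 0.1
        ys = rng.permutation(rng.random(200))
        fits = host_distance_regression(self.synth_stats(xs, ys))
        assert fits["path"].r_squared < 0.05

    def test_zero_predictors_dropped_and_counted(self):
        xs = [1.0, 2.0, 4.0, 0.0]
        ys = [1.0, 2.0, 3.0, 9.0]
        from genenet.hosts import PairStats

        stats = [PairStats(f"a{i}", f"b{i}", x, 0, 0.1 + 0.1 * i, y)
                 for i, (x, y) in enumerate(zip(xs, ys))]
        fits = host_distance_regression(stats)
        assert fits["path"].n_used == 3
        assert fits["path"].n_dropped == 1

    def test_constant_predictor_is_an_error(self):
        with pytest.raises(ValueError):
            host_distance_regression(
                self.synth_stats([2.0, 2.0, 2.0], [1.0, 2.0, 3.0]))
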