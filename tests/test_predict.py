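import numpy as np
import pytest

from genenet.hosts import HostProfile, host_profiles
from genenet.io import GeneRecord, GenomeRecord, read_annotation_table
from genenet.networks import MembershipMatrix
from genenet.predict import (
    HostPrediction,
    accuracy_report,
    assign_external_genes,
    enrichment_outliers,
    logistic_mpd,
    predict_hosts,
)


def membership(genome_hosts, carried, clusters):
    values = np.zeros((len(genome_hosts), len(clusters)), dtype=int)
    c_index = {c: j for j, c in enumerate(clusters)}
    for i, cs in enumerate(carried):
        for c in cs:
            values[i, c_index[c]] = 1
    gids = [f"G{i}" for i in range(len(genome_hosts))]
    P = MembershipMatrix(tuple(gids), tuple(clusters), values)
    genomes = [
        GenomeRecord(gid, host, (f"{gid}|1",))
        for gid, host in zip(gids, genome_hosts)
    ]
    return P, genomes


class TestPredictHosts:
    def test_majority_argmax(self):
        # c1 in 5 E-genomes + focal S genome; c2 in 2 S genomes + focal
        hosts = ["e"] * 5 + ["s"] * 3
        carried = [["c1"]] * 5 + [["c2"]] * 2 + [["c1", "c2"]]
        P, genomes = membership(hosts, carried, ["c1", "c2"])
        profiles, _ = host_profiles(P, genomes)
        preds = predict_hosts(P, profiles, genomes)
        focal = [p for p in preds if p.genome_id == "G7"][0]
        # LOO profile: c1 gives {e:5}, c2 gives {s:2} -> predict e (wrongly)
        assert focal.predicted_genus == "e"
        assert focal.correct is False

    def test_own_genome_excluded_from_counts(self):
        """Recompute one profile with and without the focal exclusion."""
        hosts = ["e", "e", "s"]
        carried = [["c1"], ["c1"], ["c1"]]
        P, genomes = membership(hosts, carried, ["c1"])
        profiles, _ = host_profiles(P, genomes)
        assert profiles[0].counts == {"e": 2, "s": 1}
        preds = predict_hosts(P, profiles, genomes)
        focal = [p for p in preds if p.genome_id == "G2"][0]
        # with exclusion the S genome sees {e:2}; without it s would tie e
        assert focal.predicted_genus == "e"
        e_focal = [p for p in preds if p.genome_id == "G0"][0]
        # E genome sees {e:1, s:1} -> tie, resolved to larger global freq (e)
        assert e_focal.tie is True
        assert e_focal.predicted_genus == "e"

    def test_private_clusters_yield_no_prediction(self):
        hosts = ["e", "s"]
        carried = [["c1"], ["c2"]]
        P, genomes = membership(hosts, carried, ["c1", "c2"])
        profiles, _ = host_profiles(P, genomes)
        preds = predict_hosts(P, profiles, genomes)
        assert all(p.predicted_genus is None for p in preds)
        with pytest.raises(ValueError):
            accuracy_report(preds)

    def test_single_host_loo_profile_has_zero_mpd(self, toy_host_tree):
        hosts = ["a", "a", "a"]
        carried = [["c1"], ["c1"], ["c1"]]
        P, genomes = membership(hosts, carried, ["c1"])
        profiles, _ = host_profiles(P, genomes)
        preds = predict_hosts(P, profiles, genomes, toy_host_tree)
        assert all(p.profile_mpd == 0.0 for p in preds)
        assert all(p.correct for p in preds)


class TestAssignExternalGenes:
    def centroids(self):
        rng = np.random.default_rng(2)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        seqs = ["".join(rng.choice(aas, size=120)) for _ in range(3)]
        cents = [GeneRecord(f"cen{i}", f"G{i}", s) for i, s in enumerate(seqs)]
        clusters = {f"cen{i}": f"C{i}" for i in range(3)}
        return cents, clusters

    def test_identical_query_assigned_to_its_centroid(self):
        cents, clusters = self.centroids()
        query = GeneRecord("q1", "ext", cents[1].sequence)
        out = assign_external_genes([query], cents, clusters)
        assert out["q1"] == "C1"

    def test_unrelated_short_sequence_unassigned(self):
        cents, clusters = self.centroids()
        query = GeneRecord("q1", "ext", "MK")
        out = assign_external_genes([query], cents, clusters)
        assert out["q1"] is None

    def test_equidistant_query_takes_lower_cluster_id(self):
        seq = "MKLVVTTAGHQRWYEDNSPACLIK" * 4
        cents = [GeneRecord("cenB", "GB", seq), GeneRecord("cenA", "GA", seq)]
        clusters = {"cenB": "C9", "cenA": "C1"}
        query = GeneRecord("q1", "ext", seq)
        out = assign_external_genes([query], cents, clusters)
        assert out["q1"] == "C1"


class TestAccuracyReport:
    def preds(self, spec):
        return [
            HostPrediction(f"G{i}", pred, ann, pred == ann, 0.0)
            for i, (ann, pred) in enumerate(spec)
        ]

    def test_all_correct(self):
        table, overall = accuracy_report(
            self.preds([("e", "e"), ("s", "s"), ("e", "e")]))
        assert overall == 1.0
        assert (table["accuracy"] == 1.0).all()
        assert table["most_common_incorrect"].isna().all()

    def test_overall_fraction(self):
        spec = [("e", "e")] * 8 + [("e", "s")] * 2
        _, overall = accuracy_report(self.preds(spec))
        assert overall == pytest.approx(0.8)

    def test_sister_genus_confusion_is_modal(self):
        spec = (
            [("e", "e")] * 3 + [("e", "s")] * 2 + [("e", "x")]
            + [("s", "s")] * 3 + [("s", "e")] * 2
        )
        table, _ = accuracy_report(self.preds(spec))
        row_e = table[table["host_genus"] == "e"].iloc[0]
        row_s = table[table["host_genus"] == "s"].iloc[0]
        assert row_e["most_common_incorrect"] == "s"
        assert row_s["most_common_incorrect"] == "e"


class TestLogisticMpd:
    def simulate(self, beta0, beta1, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.random(n) * 4
        p = 1 / (1 + np.exp(-(beta0 + beta1 * x)))
        y = rng.random(n) < p
        return [
            HostPrediction(f"G{i}", "e" if yi else "s", "e", bool(yi),
                           float(xi))
            for i, (xi, yi) in enumerate(zip(x, y))
        ]

    def test_independent_correctness_gives_near_zero_mcfadden(self):
        preds = self.simulate(0.5, 0.0, 400, seed=6)
        fit = logistic_mpd(preds)
        assert abs(fit.mcfadden_r_squared) < 0.02

    def test_recovers_negative_coefficient_within_two_se(self):
        preds = self.simulate(2.0, -1.5, 500, seed=3)
        fit = logistic_mpd(preds)
        assert fit.mpd_coefficient < 0
        assert abs(fit.mpd_coefficient - (-1.5)) < 2 * fit.coef_se

    def test_all_correct_input_is_an_error(self):
        preds = [HostPrediction(f"G{i}", "e", "e", True, float(i))
                 for i in range(10)]
        with pytest.raises(ValueError):
            logistic_mpd(preds)


class TestEnrichment:
    def test_collinear_table_fits_perfectly_without_outliers(self):
        from genenet.io import AnnotationTable

        table = AnnotationTable(
            rows=[(f"s{i}", 10 * i + 10, 5 * i + 5) for i in range(6)])
        res = enrichment_outliers(table)
        assert res.r_squared == pytest.approx(1.0)
        assert (res.table["direction"] == "none").all()

    def test_packaged_table_regression_and_outliers(self):
        res = enrichment_outliers(read_annotation_table())
        assert res.r_squared_adj == pytest.approx(0.9292, abs=5e-4)
        base = res.table[res.table["subsystem"] == "Phage baseplate proteins"]
        assert base["ci_lower"].iloc[0] == pytest.approx(18.421, abs=1e-3)
        assert base["ci_upper"].iloc[0] == pytest.approx(29.384, abs=1e-3)
        assert base["direction"].iloc[0] == "over"
        flagged = set(res.outliers()["subsystem"])
        assert flagged == {
            "Phage baseplate proteins", "Phage replication",
            "Phage packaging", "Phage neck proteins", "Phage DNA synthesis",
            "Phage nin genes-N-independent survival",
            "Regulation and cell signaling",
        }

    def test_r_squared_invariant_under_column_rescaling(self):
        """Counts vs frequencies give the same R^2 (affine invariance),
        justifying the counts-based fit."""
        import statsmodels.api as sm

        from genenet.io import read_annotation_table

        df = read_annotation_table().to_frame()
        r2 = []
        for sx, sy in [(1.0, 1.0), (1 / 1589, 1 / 680)]:
            fit = sm.OLS(df["post"] * sy,
                         sm.add_constant(df["pre"] * sx)).fit()
            r2.append(fit.rsquared)
        assert r2[0] == pytest.approx(r2[1], abs=1e-12)

    def test_prediction_interval_is_wider(self):
        table = read_annotation_table()
        mean_band = enrichment_outliers(table, interval="mean").table
        pred_band = enrichment_outliers(table, interval="prediction").table
        width_mean = (mean_band["ci_upper"] - mean_band["ci_lower"]).mean()
        width_pred = (pred_band["ci_upper"] - pred_band["ci_lower"]).mean()
        assert width_pred > width_mean

    def test_zero_variance_pre_counts_rejected(self):
        from genenet.io import AnnotationTable

        table = AnnotationTable(rows=[("a", 5, 1), ("b", 5, 2), ("c", 5, 3)])
        with pytest.raises(ValueError):
            enrichment_outliers(table)
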