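"""End-to-end pipeline: cluster -> build -> mcl -> hosts/topology ->
chi/mimax -> predict, with a run manifest recording seeds, parameters,
and per-stage row counts."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from genenet import __version__
from genenet.clustering import assignments_from_map, cluster_proteins, filter_clusters
from genenet.config import RunConfig
from genenet.hosts import (
    host_distance_regression,
    host_profiles,
    pairstats_frame,
    pairwise_topology,
)
from genenet.io import (
    export_network,
    load_dataset,
    read_cluster_map,
    read_host_tree,
)
from genenet.mcl import sweep_inflation
from genenet.mimax import build_chi, granularity_boost, mimax_search, mutual_information
from genenet.networks import build_membership, project_networks
from genenet.predict import accuracy_report, logistic_mpd, predict_hosts
from genenet.simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage in dependency order and write artifacts plus a
    ``manifest.json`` into ``out_dir``. Reruns with the same config and
    seed reproduce the outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "genenet_version": __version__,
        "config_hash": config.digest(),
        "seed": config.seed,
        "stages": [],
    }

    def stage(name: str):
        def deco(fn):
            try:
                info = fn() or {}
            except Exception as exc:  # noqa: BLE001
                raise PipelineError(name, exc) from exc
            manifest["stages"].append({"name": name, **info})
            return info

        return deco

    state: dict = {}

    @stage("load")
    def _load():
        if config.simulate:
            sim = simulate_dataset(
                SimulationConfig(
                    n_hosts=config.sim_n_hosts,
                    n_genomes_per_host=config.sim_genomes_per_host,
                    genes_per_genome=config.sim_genes_per_genome,
                    pool_size_per_host=config.sim_pool_size,
                    hgt_rate=config.sim_hgt_rate,
                    phylo_decay=config.sim_phylo_decay,
                    singleton_rate=config.sim_singleton_rate,
                    seed=config.seed,
                )
            )
            state.update(
                genomes=sim.genomes, genes=sim.genes,
                clusters=sim.cluster_assignments, tree=sim.host_tree,
            )
        else:
            fasta_paths = (
                sorted(Path(config.fasta_dir).glob("*.f*a*"))
                if config.fasta_dir else None
            )
            genomes, genes = load_dataset(
                fasta_paths=fasta_paths,
                host_metadata=config.hosts_tsv,
                cluster_map=config.cluster_map,
            )
            if config.cluster_map:
                clusters = assignments_from_map(
                    read_cluster_map(config.cluster_map)
                )
            else:
                clusters = cluster_proteins(genes, config.identity_threshold)
            state.update(
                genomes=genomes, genes=genes, clusters=clusters,
                tree=read_host_tree(config.host_tree),
            )
        return {"n_genomes": len(state["genomes"]),
                "n_genes": len(state["genes"])}

    @stage("filter")
    def _filter():
        retained, excluded = filter_clusters(
            state["clusters"], config.min_cluster_size, state["genomes"]
        )
        state["clusters"] = retained
        state["genomes"] = [
            g for g in state["genomes"] if g.genome_id not in set(excluded)
        ]
        (out / "excluded_genomes.txt").write_text(
            "".join(f"{g}\n" for g in excluded)
        )
        return {"n_clusters": len(retained), "n_excluded_genomes": len(excluded)}

    @stage("build")
    def _build():
        P = build_membership(state["genomes"], state["clusters"])
        genome_net, gene_net = project_networks(P)
        state.update(P=P, genome_net=genome_net, gene_net=gene_net)
        P.to_tsv(out / "membership.tsv")
        export_network(genome_net, out / "genome.edges")
        export_network(gene_net, out / "gene.edges")
        return {
            "membership_shape": list(P.values.shape),
            "genome_edges": genome_net.n_edges,
            "gene_edges": gene_net.n_edges,
        }

    @stage("mcl")
    def _mcl():
        sweep = sweep_inflation(state["gene_net"], config.inflation_grid())
        sweep.table.to_csv(out / "inflation_sweep.tsv", sep="\t", index=False)
        state["sweep"] = sweep
        return {
            "recommended_inflation": sweep.recommended_inflation,
            "grid_points": len(sweep.table),
        }

    @stage("hosts")
    def _hosts():
        cluster_profiles, genome_profiles = host_profiles(
            state["P"], state["genomes"]
        )
        state.update(cluster_profiles=cluster_profiles,
                     genome_profiles=genome_profiles)
        stats = pairwise_topology(
            state["gene_net"], state["genomes"], state["P"], state["tree"]
        )
        state["pairstats"] = stats
        pairstats_frame(stats).to_csv(out / "pairstats.tsv", sep="\t",
                                      index=False)
        fits = host_distance_regression(stats)
        state["regressions"] = fits
        return {
            "n_pairs": len(stats),
            "path_slope": fits["path"].slope,
            "similarity_slope": fits["similarity"].slope,
        }

    @stage("mimax")
    def _mimax():
        boosted = granularity_boost(
            state["gene_net"], config.mimax_inflation,
            config.augment_edges_per_node, seed=config.seed,
        )
        chi = build_chi(boosted, state["cluster_profiles"])
        mi_before = mutual_information(chi)
        best = None
        for rep in range(config.mimax_replicates):
            result = mimax_search(
                chi, state["P"],
                max_iterations=config.mimax_max_iterations,
                seed=config.seed * 1000 + rep,
            )
            result.trace_frame().to_csv(
                out / f"mimax_trace_rep{rep}.tsv", sep="\t", index=False
            )
            if best is None or result.current_mi > best.current_mi:
                best = result
        state.update(chi=chi, mimax=best)
        retained_gene_clusters = sorted(
            c for label in best.retained_rows for c in chi.provenance[label]
        )
        state["retained_clusters"] = retained_gene_clusters
        (out / "retained_clusters.txt").write_text(
            "".join(f"{c}\n" for c in retained_gene_clusters)
        )
        return {
            "n_chi_rows": len(chi.row_labels),
            "mi_before": mi_before,
            "mi_after": best.current_mi,
            "rows_retained": len(best.retained_rows),
        }

    @stage("predict")
    def _predict():
        P_kept = state["P"].restrict_clusters(state["retained_clusters"])
        predictions = predict_hosts(
            P_kept, state["cluster_profiles"], state["genomes"], state["tree"]
        )
        state["predictions"] = predictions
        table, overall = accuracy_report(predictions)
        table.to_csv(out / "accuracy_by_genus.tsv", sep="\t", index=False)
        try:
            logi = logistic_mpd(predictions)
            logi_info = {
                "mpd_coefficient": logi.mpd_coefficient,
                "mcfadden_r_squared": logi.mcfadden_r_squared,
            }
        except ValueError:
            logi_info = {"mpd_coefficient": None, "mcfadden_r_squared": None}
        return {"overall_accuracy": overall, **logi_info}

    manifest["n_stages"] = len(manifest["stages"])
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_jsonable)
    state["manifest"] = manifest
    return state


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
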