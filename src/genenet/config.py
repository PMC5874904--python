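"""Run configuration: one serializable object covering every stage."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Parameters for a full pipeline run.

    Defaults follow the method's stated choices: 35% clustering identity,
    minimum cluster size 3, an ICCC inflation sweep over 1.2-6, mimax at
    inflation 15 with 5 random edges per node, blastp-style assignment
    thresholds E < 1e-5 and bitscore > 50, and a 99.9% enrichment CI.
    """

    # inputs (either simulate, or fasta_dir/cluster_map + hosts + tree)
    fasta_dir: str | None = None
    cluster_map: str | None = None
    hosts_tsv: str | None = None
    host_tree: str | None = None
    simulate: bool = True

    # clustering
    identity_threshold: float = 0.35
    min_cluster_size: int = 3

    # MCL / ICCC
    inflation_grid_start: float = 1.2
    inflation_grid_stop: float = 6.0
    inflation_grid_step: float = 0.4

    # mimax
    mimax_inflation: float = 15.0
    augment_edges_per_node: int = 5
    mimax_replicates: int = 3
    mimax_max_iterations: int = 20000

    # prediction / enrichment
    max_evalue: float = 1e-5
    min_bitscore: float = 50.0
    ci_level: float = 0.999

    # simulation (used when simulate=True)
    sim_n_hosts: int = 8
    sim_genomes_per_host: int = 10
    sim_genes_per_genome: int = 30
    sim_pool_size: int = 40
    sim_hgt_rate: float = 0.1
    sim_phylo_decay: float = 1.0
    sim_singleton_rate: float = 0.05

    seed: int = 1

    def inflation_grid(self) -> list[float]:
        grid = []
        x = self.inflation_grid_start
        while x <= self.inflation_grid_stop + 1e-9:
            grid.append(round(x, 6))
            x += self.inflation_grid_step
        return grid

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        canonical = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]
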