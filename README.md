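# genenet

Gene co-occurrence network analysis for bacteriophage genomes.

Phages exchange genes promiscuously and share no universal marker gene, so
classical phylogenetics cannot place diverse phages in a common frame. This
package takes the network view instead: every phage proteome is reduced to
its homologous **gene clusters**, and two clusters are connected whenever
they co-occur in a genome. The topology of that gene network turns out to
track the phylogeny of the bacterial *hosts*, which makes it a usable
substrate for host-range analysis and host prediction. `genenet` is aimed
at phage ecologists and comparative genomicists who want to run this style
of analysis on their own genome sets, or to study its behavior on
controlled synthetic data.

## What it computes

Starting from a binary genome × gene-cluster membership matrix *P*
(entry *{i,j}* = 1 iff genome *i* carries a member of cluster *j*):

- **Networks.** Genome network `A_genome = sign(P Pᵀ)` and gene network
  `A_gene = sign(Pᵀ P)` (diagonals dropped) — simple, unweighted graphs.
- **MCL.** A from-scratch Markov Cluster algorithm (expansion ↔ inflation
  on a column-stochastic flow matrix) partitions either network; the
  intracluster clustering coefficient (ICCC) selects the inflation across
  a sweep.
- **Host association.** Each gene cluster gets a host-genus count vector;
  a genome's vector is the sum over its clusters. The abundance-weighted
  mean pairwise phylogenetic distance,
  `MPD = Σ_{i≠j} d_ij f_i f_j / Σ_{i≠j} f_i f_j`,
  summarizes how phylogenetically dispersed a profile's hosts are
  (0 ⇔ single host). Genome-pair topology (mean BFS shortest path and
  mean open-neighborhood Jaccard similarity between their gene sets) is
  regressed against host cophenetic distance.
- **mimax.** With MCL clusters as rows and host genera as columns of a
  count matrix χ, the mutual information
  `I(X,Y) = Σ p(x,y) ln[p(x,y) / p(x)p(y)]`
  measures how well graph structure encodes host identity. The *mimax*
  search greedily deletes random χ rows, rejecting any deletion that would
  strip a genome of its last gene cluster and keeping only deletions that
  strictly increase *I* — isolating the host-informative gene clusters.
  Granularity is raised beforehand by high-inflation MCL (default 15) on a
  network augmented with 5 random edges per node.
- **Prediction.** A phage's host is predicted as the most frequent genus
  among homologs of its retained clusters, excluding the phage's own
  genome (leave-one-out); accuracy is analyzed against profile MPD by
  logistic regression (McFadden's R²). A blastp-style thresholded
  assignment (E < 1e-5, bitscore > 50) maps external phage genes onto
  cluster centroids.
- **Enrichment.** Functional subsystem annotation counts before vs. after
  the mimax reduction are compared by OLS with a pointwise 99.9%
  confidence band; subsystems outside the band are called over- or
  under-represented.

A synthetic-data module generates host-structured phage datasets (host
tree, per-host gene pools, tunable cross-host HGT with phylogenetic decay,
singleton injection, optional divergent sequences) so the whole pipeline
is testable without any downloads.

## Worked example

The packaged subsystem annotation table (32 functional categories,
counts among all phage genes vs. among the mimax-retained genes) is
analyzed with:

```bash
$ genenet enrich
                                       subsystem  pre  post     fitted  ci_lower   ci_upper direction
Cofactors, vitamins, prosthetic groups, pigments   20     7   8.849666  2.948222  14.751110      none
                           Cell wall and capsule   11     6   5.086445 -1.104589  11.277480      none
                        Phage baseplate proteins   56    46  23.902548 18.421051  29.384044      over
                               Phage replication  215   110  90.386109 76.765036 104.007183      over
...
# R2 = 0.9315 (adj 0.9292), slope = 0.4181
```

Reading: retained counts regress on full counts with adjusted R² = 0.9292;
baseplate proteins (46 observed vs. a 99.9% band of 18.4–29.4) are
significantly over-retained — the reduction concentrates on host-contact
machinery — while, further down the table, packaging and regulatory genes
fall below their bands.

A full synthetic run (8 host genera, 10 genomes per host, 30 genes per
genome, 10% HGT):

```bash
$ genenet all --out-dir run1 --seed 1
```

prints the per-stage manifest, including:

```
{"name": "load",    "n_genomes": 80, "n_genes": 2400}
{"name": "filter",  "n_clusters": 309, "n_excluded_genomes": 0}
{"name": "build",   "membership_shape": [80, 309], "genome_edges": 980, "gene_edges": 9149}
{"name": "mcl",     "recommended_inflation": 5.2, "grid_points": 13}
{"name": "hosts",   "n_pairs": 3160, "path_slope": 6.575, "similarity_slope": -0.927}
{"name": "mimax",   "n_chi_rows": 299, "mi_before": 1.763, "mi_after": 2.079, "rows_retained": 96}
{"name": "predict", "overall_accuracy": 1.0}
```

Reading: across the 3160 genome pairs, host phylogenetic distance rises
with mean gene-network path length (slope +6.58) and falls with mean
neighborhood similarity (slope −0.93) — topological closeness predicts
host relatedness. mimax trims 299 MCL clusters to 96 while raising the
cluster–host mutual information from 1.76 to 2.08 nats, and leave-one-out
majority prediction recovers every host on this low-HGT dataset.

Other subcommands: `genenet load`, `cluster`, `build`, `mcl`,
`mcl-sweep`, `boost`, `assign`, `simulate` (see `genenet --help`).

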