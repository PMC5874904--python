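# Methods

This note documents the models and procedures `genenet` implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## Membership matrix and network projections

The pipeline pivots on the binary membership matrix *P* (genomes ×
gene clusters), with entry 1 iff the genome carries at least one member
of the cluster; paralogs collapse to a single 1. The genome and gene
networks are `sign(P Pᵀ)` and `sign(Pᵀ P)` with zeroed diagonals —
simple, unweighted graphs by construction. Edge weights are deliberately
not carried: the analyses downstream (MCL granularity scans, shortest
paths, Jaccard similarity) are defined on the unweighted sign structure,
and weighted variants are out of scope.

Clusters with fewer than 3 members (default `min_size = 3`) are removed
before *P* is built: a co-occurrence observed in one or two genomes is
not a reliable edge. Genomes whose every clustered gene fell in dropped
clusters are excluded and reported.

## Protein clustering

The built-in clusterer is a greedy centroid method for desk-scale data:
genes are processed in decreasing length order (ties by id — this
matches the length-sort convention of centroid clusterers and makes the
output deterministic); a gene joins the first centroid whose pairwise
identity reaches the threshold (default 0.35), else founds a cluster.
Identity comes from a global alignment with fixed scoring (match +1,
mismatch −1, gap open −5, gap extend −1); the denominator is alignment
columns with terminal-gap columns excluded, the closest convention to
the common centroid-clustering identity definition. The clusterer makes
no speed claims: it is quadratic in the number of sequences, and
precomputed cluster maps (plain TSV or UC format) bypass it entirely
for large corpora.

## Markov clustering and ICCC

MCL is implemented from scratch on dense arrays (the intended scale is
networks of at most a few thousand nodes). Self-loops of weight 1 are
added before column normalization — standard practice that damps
oscillation on near-bipartite structures. One iteration is expansion
(matrix power, default 2), inflation (entrywise power, then column
renormalization), and pruning of entries below 1e-8 followed by
renormalization. Convergence is max entrywise change < 1e-6, with a cap
of 200 iterations (non-convergence returns the current interpretation
with a flag). Clusters are read off as connected components of the
symmetrized nonzero pattern of the limit matrix; a node attracted to two
attractor systems therefore lands in the single component containing
both, which is a deterministic resolution of the overlap case. Labels
are assigned 1..k in order of each cluster's smallest node index.

The ICCC of a partition is the size-weighted mean, over clusters of at
least 3 nodes, of the mean local clustering coefficient of the cluster's
induced subgraph. Clusters of size < 3 cannot close a triangle and are
excluded from numerator and weights; if no cluster reaches size 3 the
ICCC is 0 by convention. An unweighted mean is available
(`iccc(..., weighted=False)`); the weighted form is the default because
it scores the partition by node mass rather than by cluster count. The
inflation sweep picks the ICCC argmax, breaking ties toward the smaller
(coarser) inflation.

The MCL oracle used in the tests is a committed fixture of partitions on
12 graphs of ≤ 30 nodes at inflations 1.5/2/4, generated by an
independently written dense implementation
(`tests/data/make_mcl_fixture.py`) and hand-verified on the structured
graphs whose MCL partition is known (disjoint cliques and caveman rings
return the cliques; a single clique is one cluster; bridged cliques
split at the bridge).

## Host profiles and MPD

A gene cluster's host profile counts the known-host genomes that carry
it, one count per genome per genus. A genome's profile is the sum over
its clusters — note this double-counts genera through multiple clusters
by design: the profile measures the genome's gene-level host exposure,
not a deduplicated host list. Genomes without a resolvable host genus
participate in network construction but contribute to no profile, no χ
entry, and no accuracy denominator.

MPD uses relative abundances f over the profile's hosts:
`MPD = Σ_{i≠j} d_ij f_i f_j / Σ_{i≠j} f_i f_j`, with d the genus-level
cophenetic distance. It is scale-invariant in the counts, bounded by the
tree diameter, exactly 0 for single-host profiles, and *undefined* (a
distinct error, not 0) for empty profiles.

Genus collapse places each genus at the MRCA of its mapped leaves and
measures genus–genus distances as path lengths between MRCA nodes on the
source tree; merge and drop lists handle taxonomy corrections.
Non-monophyletic genera collapse at their MRCA anyway, with a warning
naming the intruding taxa. Note the MRCA placement (unlike leaf-to-leaf
patristic distance) depends on the rooting; unrooted input trees are
midpoint-rooted when possible, falling back to the as-read rooting.

## Pairwise genome topology and the distance regressions

For each unordered pair of known-host genomes, the mean shortest path
and mean similarity are taken over the full rectangular block of
(cluster of A) × (cluster of B) cells, including cells where both
genomes share a cluster (path 0, similarity 1). Shortest paths are BFS
edge counts; similarity is open-neighborhood Jaccard (the node itself
excluded), 1 on the diagonal, 0 for pairs of isolated nodes. Cluster
pairs in different components are excluded from the path mean — not set
to infinity — and their count is reported per genome pair; the expected
regime is a dominant giant component where this matters little.

Host distance is regressed on the log of each predictor by OLS. Pairs
with an undefined path mean or a zero predictor are dropped from the log
fit and counted. With host-structured data the similarity slope is
negative (similar repertoires ⇒ close hosts) and the path slope
positive; the package asserts these directions on synthetic data rather
than any dataset-specific R².

## χ, mutual information, and mimax

χ aggregates gene-cluster host profiles by MCL cluster; its provenance
map (row → gene-cluster ids) is what the feasibility constraint is
evaluated against. Rows that would be all-zero (clusters seen only in
unknown-host genomes) are dropped at construction with a warning.

Mutual information is computed in nats (natural log); with ~20 host
genera the theoretical ceiling ln(20) ≈ 3.0 makes typical values of 1–2.5
interpretable. Zero cells contribute 0. The implementation is
cross-checked in tests against the independent decomposition
I = H(rows) + H(cols) − H(joint) at 1e-12.

mimax is the single-chain stochastic hill climber the procedure
describes — no population or crossover; replicates are independent
seeded chains. Each iteration samples a retained row uniformly, rejects
it if deletion would orphan any genome (leave it with zero retained gene
clusters), else accepts iff MI *strictly* increases. Termination, which
the procedure leaves open, is `patience` consecutive non-accepted
proposals (default 10× the initial row count, counting
rejected-for-coverage proposals) or `max_iterations` (default 1e5). The
full proposal trace is recorded so the monotonicity and coverage
invariants can be replayed and asserted. An exhaustive subset
enumeration (`exhaustive_best_subset`) serves as the optimality oracle
on instances of ≤ 20 rows.

Before mimax, granularity is raised by clustering at inflation 15 on a
network augmented with 5 random edges per node. Augmentation samples,
per node in order, uniformly among current non-neighbors without
replacement; proposals from both endpoints dedupe, so the realized added
count (logged) can be below nodes × rate. The scheme is seeded and
reproducible.

## Prediction, logistic analysis, enrichment

Leave-one-out prediction subtracts the focal genome's own contribution
(one count on its genus per carried cluster) before taking the argmax
genus. Ties are broken toward the genus with the larger global genome
frequency, then lexicographically, and always flagged. Genomes whose
retained clusters occur nowhere else yield no prediction and are tallied
separately. Accuracy on the MPD = 0 stratum is exactly 1 whenever
annotations are consistent — a structural property the tests assert.

The logistic analysis fits correctness on profile MPD by ML and reports
McFadden's R² = 1 − ℓ_model/ℓ_null. Perfect separation is detected and a
ridge-penalized fit substituted, flagged as such.

External genes are assigned to cluster *centroids* only, by local
alignment (BLOSUM62, gap open −11 / extend −1). The bitscore is a
Karlin–Altschul calibrated surrogate (λ = 0.267, K = 0.041, gapped
protein defaults) and the E-value uses the query × database length
product; both are documented as surrogates, not bit-identical to BLAST.
An external alignment backend can be injected via the `scorer` hook.

The enrichment regression fits post-reduction counts on pre-reduction
counts by OLS (the aggregate Total row is excluded). The outlier band is
the pointwise 99.9% *confidence interval for the mean response* (t
distribution, n−2 df), computed on counts; the wider prediction interval
is available behind `interval="prediction"` and compared in tests. R² is
affine-invariant, so counts and frequencies give the same fit quality;
both plain and adjusted R² are reported (adjusted = 1−(1−R²)(n−1)/(n−2)).

## Synthetic data

The generator emulates exactly the statistical structure the analyses
assume: a genus-level host tree (balanced with unit branch lengths by
default, so distances are interpretable in integer steps; a Kingman
coalescent option provides irregular trees), one gene pool per host, and
mosaic genomes drawing each gene from the own-host pool with probability
1 − hgt_rate, else from a foreign pool weighted by exp(−d/phylo_decay).
Exponential decay in tree distance is the single-knob mechanism that
produces the monotone topology–host-distance relationship the regressions
test. Singletons are injected per gene at `singleton_rate` to exercise
the small-cluster filter.

Defaults — 8 hosts, 10 genomes/host, 30 genes/genome, pool 40/host,
hgt_rate 0.1, phylo_decay 1.0, singleton_rate 0.05 — are the package's
standard study conditions: enough genomes per host for stable profiles,
a pool size that makes same-host genomes overlap heavily (~75% expected
pairwise cluster overlap) while cross-host overlap comes only through
HGT, and an HGT rate low enough that host signal dominates but high
enough that profiles are not trivially single-host.

Optional sequences are generated per cluster from a random ancestor
(length 60–120) with 10% per-site substitution per member, placing
within-cluster identity (~0.8) far above the 0.35 threshold and
between-cluster identity (~0.05) far below it; tests confirm the
sequences recluster to ground truth (pairwise Rand index ≥ 0.95).

All randomness flows through a single seeded PCG64 stream with a fixed
draw order (tree, then genomes host-by-host and slot-by-slot, then
sequences cluster-by-cluster), so a fixed seed reproduces the dataset
bit-identically across platforms.

What the generator does **not** emulate: genome architecture (synteny,
module order), lifestyle or functional gene classes, uneven host
sampling, sequencing artifacts, or within-cluster sequence variation
that carries host signal. Passing tests therefore demonstrate that the
implementation realizes the method's assumptions and recovers planted
structure — not that the method performs equivalently on real phage
corpora, whose headline statistics depend on the underlying genome
snapshot and annotation services and are reported by the pipeline but
never asserted.

## Problem sizes and design choices of record

- The default test and acceptance runs use 80-genome / ~300-cluster
  synthetic datasets, MCL networks of ≤ 30 nodes for oracle comparison,
  1000 random matrices for the MI oracle, and 500 profile/tree pairs for
  the MPD oracle; these sizes give stable results in seconds.
- The CLI exposes the file-to-file stages (`load`, `cluster`, `build`,
  `mcl`, `mcl-sweep`, `boost`, `assign`, `enrich`, `simulate`) plus the
  orchestrated `all`; the host-profile, topology, χ/mimax, and
  prediction stages operate on in-memory intermediates and are exposed
  through `all` (which writes their TSV artifacts) and the library API,
  rather than as standalone commands with bespoke serialization.
- Unknown-host genomes: kept in networks, excluded from profiles, χ,
  MPD, and scoring — the least surprising treatment and the one that
  keeps every host-linked statistic defined.
- Known limitations: the greedy clusterer is quadratic and centroid-order
  dependent (as is the tool it mirrors); dense MCL memory grows as the
  square of node count; the surrogate bitscore is calibrated but not
  BLAST-identical; mimax is a local optimizer and relies on restarts for
  hard instances.
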