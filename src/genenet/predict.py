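"""Majority-host prediction, external-gene assignment, accuracy-vs-MPD
logistic analysis, and the annotation enrichment regression.

A phage's host is predicted as the genus with the greatest representation
among the homologs of its (mimax-retained) gene clusters, excluding the
phage's own genome from every count (leave-one-out). Accuracy is then
related to the MPD of the same leave-one-out profile: a profile
concentrated on one genus (MPD = 0) predicts perfectly by construction
when annotations are consistent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from Bio import Align
from Bio.Align import substitution_matrices

from genenet.hosts import EmptyProfileError, HostProfile, mpd
from genenet.io import (
    AnnotationTable,
    GeneRecord,
    GenomeRecord,
    HostTree,
    normalize_genus,
)
from genenet.networks import MembershipMatrix

logger = logging.getLogger(__name__)


@dataclass
class HostPrediction:
    """One genome's leave-one-out host call."""

    genome_id: str
    predicted_genus: str | None
    annotated_genus: str | None
    correct: bool | None
    profile_mpd: float | None
    tie: bool = False


@dataclass
class EnrichmentResult:
    """Per-subsystem enrichment calls from the pre/post regression."""

    table: pd.DataFrame
    slope: float
    intercept: float
    r_squared: float
    r_squared_adj: float
    p_value: float
    ci_level: float

    def outliers(self) -> pd.DataFrame:
        return self.table[self.table["direction"] != "none"]


# ---------------------------------------------------------------------------
# Leave-one-out host prediction


def predict_hosts(
    P: MembershipMatrix,
    cluster_profiles: Sequence[HostProfile],
    genomes: Sequence[GenomeRecord],
    host_tree: HostTree | None = None,
) -> list[HostPrediction]:
    """Predict every genome's host by the leave-one-out majority rule.

    For each genome, sum its clusters' host profiles after subtracting
    the genome's own contribution (one count on its annotated genus for
    every cluster it carries). The argmax genus is the prediction; ties
    go to the genus with the larger global frequency, then lexicographic,
    and are flagged. Genomes whose clusters occur nowhere else get
    ``predicted_genus=None`` and are excluded from accuracy denominators.
    """
    prof_by_owner = {p.owner: p for p in cluster_profiles}
    genome_by_id = {g.genome_id: g for g in genomes}
    global_freq: dict[str, int] = {}
    for g in genomes:
        if g.has_known_host:
            h = normalize_genus(g.host_genus)
            global_freq[h] = global_freq.get(h, 0) + 1

    out: list[HostPrediction] = []
    for gid in P.genomes:
        genome = genome_by_id[gid]
        own = normalize_genus(genome.host_genus) if genome.has_known_host else None
        loo: dict[str, int] = {}
        for cid in P.clusters_of(gid):
            prof = prof_by_owner.get(cid)
            if prof is None:
                continue
            for h, c in prof.nonzero().items():
                loo[h] = loo.get(h, 0) + c
            if own is not None:
                loo[own] = loo.get(own, 0) - 1
        loo = {h: c for h, c in loo.items() if c > 0}
        if not loo:
            out.append(
                HostPrediction(
                    genome_id=gid, predicted_genus=None, annotated_genus=own,
                    correct=None, profile_mpd=None,
                )
            )
            continue
        best = max(loo.values())
        top = sorted(h for h, c in loo.items() if c == best)
        tie = len(top) > 1
        if tie:
            top.sort(key=lambda h: (-global_freq.get(h, 0), h))
        predicted = top[0]
        profile = HostProfile(owner=gid, counts=loo)
        value: float | None = None
        if host_tree is not None:
            try:
                value = mpd(profile, host_tree)
            except (EmptyProfileError, ValueError):
                value = None
        out.append(
            HostPrediction(
                genome_id=gid,
                predicted_genus=predicted,
                annotated_genus=own,
                correct=(predicted == own) if own is not None else None,
                profile_mpd=value,
                tie=tie,
            )
        )
    return out


# ---------------------------------------------------------------------------
# External gene assignment (blastp-style thresholds)

# Karlin-Altschul parameters for gapped BLOSUM62 (open 11 / extend 1);
# the resulting "bitscore" is a calibrated surrogate, not bit-identical
# to BLAST's.
_KA_LAMBDA = 0.267
_KA_K = 0.041


def _make_local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def assign_external_genes(
    query_genes: Sequence[GeneRecord],
    centroids: Sequence[GeneRecord],
    centroid_clusters: Mapping[str, str],
    max_evalue: float = 1e-5,
    min_bitscore: float = 50.0,
    scorer=None,
) -> dict[str, str | None]:
    """Assign external query genes to gene clusters via their centroids.

    Each query is locally aligned (BLOSUM62, gap open -11 / extend -1 by
    default) against every centroid; the best hit passing both the
    E-value and bitscore thresholds wins, ties going to the smaller
    cluster id (logged). ``scorer(query_seq, centroid_seq) -> raw score``
    is pluggable so an external protein-BLAST backend can be swapped in.
    """
    if scorer is None:
        aligner = _make_local_aligner()

        def scorer(a: str, b: str) -> float:
            return float(aligner.score(a, b))

    db_size = sum(len(c.sequence or "") for c in centroids)
    out: dict[str, str | None] = {}
    for query in query_genes:
        if not query.sequence:
            out[query.gene_id] = None
            continue
        best: tuple[float, str] | None = None
        tied = False
        for cen in centroids:
            if not cen.sequence:
                continue
            raw = scorer(query.sequence, cen.sequence)
            bits = (_KA_LAMBDA * raw - math.log(_KA_K)) / math.log(2)
            evalue = len(query.sequence) * db_size * 2.0 ** (-bits)
            if bits <= min_bitscore or evalue >= max_evalue:
                continue
            cid = centroid_clusters[cen.gene_id]
            if best is None or bits > best[0]:
                best, tied = (bits, cid), False
            elif bits == best[0]:
                tied = True
                if cid < best[1]:
                    best = (bits, cid)
        if tied:
            logger.info("query %s: tie between centroids; lower cluster id "
                        "kept", query.gene_id)
        out[query.gene_id] = best[1] if best else None
    return out


# ---------------------------------------------------------------------------
# Accuracy reporting and the logistic MPD analysis


def accuracy_report(
    predictions: Sequence[HostPrediction],
) -> tuple[pd.DataFrame, float]:
    """Per-genus accuracy table and overall accuracy.

    Only scored predictions (known annotation, non-None call) enter the
    denominators; each genus row lists its modal incorrect prediction.
    """
    scored = [p for p in predictions if p.correct is not None]
    if not scored:
        raise ValueError("no scored predictions")
    rows = []
    for genus in sorted({p.annotated_genus for p in scored}):
        group = [p for p in scored if p.annotated_genus == genus]
        wrong = [p.predicted_genus for p in group if not p.correct]
        modal = (
            pd.Series(wrong).mode().iloc[0] if wrong else None
        )
        rows.append(
            {
                "host_genus": genus,
                "accuracy": sum(p.correct for p in group) / len(group),
                "most_common_incorrect": modal,
                "n": len(group),
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["accuracy", "n"], ascending=[False, False]
    ).reset_index(drop=True)
    overall = sum(p.correct for p in scored) / len(scored)
    return table, overall


@dataclass
class LogisticMpdFit:
    intercept: float
    mpd_coefficient: float
    mcfadden_r_squared: float
    coef_se: float | None
    separation: bool
    n: int


def logistic_mpd(predictions: Sequence[HostPrediction]) -> LogisticMpdFit:
    """Logistic regression of prediction correctness on profile MPD.

    McFadden's R^2 = 1 - ll_model / ll_null. Perfect separation (e.g.,
    every prediction correct) cannot be fit by ML; a ridge-penalized fit
    is substituted and flagged via ``separation=True``.
    """
    pts = [
        (p.profile_mpd, 1.0 if p.correct else 0.0)
        for p in predictions
        if p.correct is not None and p.profile_mpd is not None
    ]
    if not pts:
        raise ValueError("no usable (mpd, correctness) points")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if y.min() == y.max():
        raise ValueError("correctness does not vary; logistic fit impossible")
    if np.ptp(x) == 0:
        raise ValueError("MPD does not vary; logistic fit impossible")
    X = sm.add_constant(x)
    model = sm.Logit(y, X)
    separation = False
    try:
        fit = model.fit(disp=False, maxiter=200)
        if not np.all(np.isfinite(fit.bse)):
            raise np.linalg.LinAlgError
        params = fit.params
        se = float(fit.bse[1])
        llf = float(fit.llf)
    except Exception:
        separation = True
        logger.warning("perfect separation detected; ridge-penalized logistic "
                       "fit substituted")
        fit = model.fit_regularized(
            method="l1", alpha=1e-4, disp=False, maxiter=500
        )
        params = np.asarray(fit.params)
        se = None
        llf = float(model.loglike(params))
    llnull = float(sm.Logit(y, np.ones_like(y)).fit(disp=False).llf)
    mcfadden = 1.0 - llf / llnull
    return LogisticMpdFit(
        intercept=float(params[0]),
        mpd_coefficient=float(params[1]),
        mcfadden_r_squared=float(mcfadden),
        coef_se=se,
        separation=separation,
        n=len(y),
    )


# ---------------------------------------------------------------------------
# Annotation enrichment regression


def enrichment_outliers(
    table: AnnotationTable,
    ci_level: float = 0.999,
    interval: str = "mean",
) -> EnrichmentResult:
    """Regress retained-set annotation counts on full-set counts and flag
    subsystems outside the pointwise confidence band.

    The default band is the CI for the mean response at each subsystem's
    pre-count (t distribution, n-2 df); ``interval='prediction'`` gives
    the wider prediction interval instead. Observed post-counts above the
    band are flagged ``over``, below it ``under``.
    """
    df = table.to_frame()
    if len(df) < 3:
        raise ValueError("need at least 3 subsystem rows")
    pre = df["pre"].to_numpy(dtype=float)
    post = df["post"].to_numpy(dtype=float)
    if np.ptp(pre) == 0:
        raise ValueError("pre-counts have zero variance")
    X = sm.add_constant(pre)
    fit = sm.OLS(post, X).fit()
    pred = fit.get_prediction(X)
    alpha = 1.0 - ci_level
    ci = pred.conf_int(obs=(interval == "prediction"), alpha=alpha)
    lower, upper = ci[:, 0], ci[:, 1]
    direction = np.where(
        post > upper, "over", np.where(post < lower, "under", "none")
    )
    out = df.copy()
    out["fitted"] = fit.fittedvalues
    out["ci_lower"] = lower
    out["ci_upper"] = upper
    out["direction"] = direction
    return EnrichmentResult(
        table=out,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        r_squared_adj=float(fit.rsquared_adj),
        p_value=float(fit.f_pvalue),
        ci_level=ci_level,
    )
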