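"""Pathway-coupled lncRNA discovery via weighted-KS enrichment.

For each lncRNA, all mRNAs are ranked in descending order of their
correlation with that lncRNA (tumor samples only, Spearman by default so
the whole pipeline stays invariant to monotone distortions). The
enrichment score (ES) of a pathway gene set within that ranking is the
classic weighted Kolmogorov-Smirnov running-sum statistic: hits increment
by |corr|^w normalized over hit weights, misses decrement by 1/(N - N_h),
and the ES is the signed maximal deviation from zero, bounded in [-1, 1].
Significance comes from a random gene-set permutation null; lncRNAs with
|ES| above a threshold (default 0.995) and Benjamini-Hochberg FDR below a
threshold (default 0.05) are flagged as pathway-derived.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .config import PipelineConfig
from .io import ExpressionCohort, GeneSet, ValidationError


@dataclass
class CorrelationRanking:
    """All mRNAs ordered by descending correlation with one lncRNA."""

    lncrna_id: str
    mrna_ids_ordered: List[str]
    correlations: np.ndarray  # aligned, non-increasing

    def __post_init__(self) -> None:
        self.correlations = np.asarray(self.correlations, dtype=float)
        if len(self.mrna_ids_ordered) != len(self.correlations):
            raise ValidationError("ids and correlations must have equal length")
        if np.any(np.diff(self.correlations) > 1e-12):
            raise ValidationError("correlations must be non-increasing")


@dataclass(frozen=True)
class PESResult:
    lncrna_id: str
    pes: float
    p_value: float
    q_value: float
    n_permutations: int
    is_pdl: bool


def _correlation_matrix(cohort: ExpressionCohort, method: str) -> pd.DataFrame:
    """mRNA x lncRNA correlation over tumor samples."""
    tumor = cohort.values[cohort.tumor_samples]
    if tumor.shape[1] < 3:
        raise ValidationError("correlation ranking requires at least 3 tumor samples")
    lnc = tumor.loc[cohort.lncrna_ids].to_numpy()
    mrna = tumor.loc[cohort.mrna_ids].to_numpy()
    if method == "spearman":
        lnc = rankdata(lnc, axis=1)
        mrna = rankdata(mrna, axis=1)
    elif method != "pearson":
        raise ValidationError(f"unknown correlation method {method!r}")

    def _standardize(x):
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        z = np.zeros_like(x)
        ok = sd[:, 0] > 0
        z[ok] = (x[ok] - mu[ok]) / sd[ok]
        return z, ok

    zl, ok_l = _standardize(lnc)
    zm, _ = _standardize(mrna)  # flat mRNAs get correlation 0
    corr = zm @ zl.T / tumor.shape[1]
    df = pd.DataFrame(corr, index=cohort.mrna_ids, columns=cohort.lncrna_ids)
    df.attrs["lncrna_ok"] = pd.Series(ok_l, index=cohort.lncrna_ids)
    return df


def _ranking_from_column(lncrna_id: str, col: pd.Series) -> CorrelationRanking:
    # descending correlation; ties broken by gene id lexicographic order
    ordered = col.sort_index().sort_values(ascending=False, kind="stable")
    return CorrelationRanking(lncrna_id, list(ordered.index), ordered.to_numpy())


def correlation_ranking(
    cohort: ExpressionCohort, lncrna_id: str, method: str = "spearman"
) -> CorrelationRanking:
    """Rank all mRNAs by descending correlation with ``lncrna_id``."""
    if lncrna_id not in cohort.lncrna_ids:
        raise ValidationError(f"{lncrna_id!r} is not an annotated lncRNA in this cohort")
    corr = _correlation_matrix(cohort, method)
    if not corr.attrs["lncrna_ok"][lncrna_id]:
        raise ValidationError(f"lncRNA {lncrna_id!r} has zero variance; correlation undefined")
    return _ranking_from_column(lncrna_id, corr[lncrna_id])


def enrichment_score(
    ranking: CorrelationRanking, gene_set: GeneSet, weight_exponent: float = 1.0
) -> float:
    """Signed maximal deviation of the weighted-KS running sum; ES in [-1, 1]."""
    hits = np.fromiter(
        (g in gene_set.members for g in ranking.mrna_ids_ordered), dtype=bool,
        count=len(ranking.mrna_ids_ordered),
    )
    return _running_sum_es(np.abs(ranking.correlations), hits, weight_exponent)


def _running_sum_es(abs_corr: np.ndarray, hits: np.ndarray, weight_exponent: float) -> float:
    n = hits.size
    n_hit = int(hits.sum())
    if n_hit == 0:
        raise ValidationError("gene set does not intersect the ranked list")
    if n_hit == n:
        raise ValidationError("gene set covers the whole ranked universe")
    w = abs_corr ** weight_exponent
    hit_w = np.where(hits, w, 0.0)
    total = hit_w.sum()
    if total == 0:
        # all hit correlations exactly zero: fall back to unweighted steps
        hit_w = hits.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~hits) / (n - n_hit)
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    # cumsum round-off can push the extreme a few ulp outside [-1, 1]
    return float(np.clip(running[i], -1.0, 1.0))


def pes_permutation_test(
    ranking: CorrelationRanking,
    gene_set: GeneSet,
    n_perm: int,
    seed: int,
    weight_exponent: float = 1.0,
):
    """Observed ES plus a two-sided permutation p-value.

    The null is the ES of ``n_perm`` random gene sets of the same size drawn
    without replacement from the ranked universe;
    p = (1 + #{|ES_null| >= |ES_obs|}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100 for a usable permutation p-value")
    members = gene_set.members & set(ranking.mrna_ids_ordered)
    k = len(members)
    n = len(ranking.mrna_ids_ordered)
    if k == 0:
        raise ValidationError("gene set does not intersect the ranked list")
    if k >= n:
        raise ValidationError("gene set size must be smaller than the ranked universe")
    obs = enrichment_score(ranking, gene_set, weight_exponent)
    abs_corr = np.abs(ranking.correlations)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    hits = np.zeros(n, dtype=bool)
    for b in range(n_perm):
        idx = rng.choice(n, size=k, replace=False)
        hits[:] = False
        hits[idx] = True
        null[b] = _running_sum_es(abs_corr, hits, weight_exponent)
    p = (1.0 + np.sum(np.abs(null) >= abs(obs))) / (n_perm + 1.0)
    return float(obs), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


def identify_pdls(
    cohort: ExpressionCohort,
    gene_set: GeneSet,
    cfg: Optional[PipelineConfig] = None,
) -> List[PESResult]:
    """Score every lncRNA in the cohort and flag pathway-derived ones.

    q-values are BH over all lncRNA permutation p-values; the flag applies
    |ES| > pes_abs_threshold and q < fdr_threshold with strict inequalities.
    Zero-variance lncRNAs receive ES 0 and p 1 (they cannot be ranked).
    """
    cfg = cfg or PipelineConfig()
    lnc_ids = list(cohort.lncrna_ids)
    if not lnc_ids:
        raise ValidationError("cohort contains no lncRNAs")
    if not len(cohort.mrna_ids):
        raise ValidationError("cohort contains no mRNAs")
    corr = _correlation_matrix(cohort, cfg.correlation_method)
    ok = corr.attrs["lncrna_ok"]
    ss = np.random.SeedSequence(entropy=cfg.rng_seed, spawn_key=(7,))
    sub_seeds = ss.generate_state(len(lnc_ids))
    # key the permutation stream to the lncRNA's sorted position so results
    # are invariant to the row order of the input matrix
    seed_for = {lid: int(s) for lid, s in zip(sorted(lnc_ids), sub_seeds)}
    pes, pvals = np.zeros(len(lnc_ids)), np.ones(len(lnc_ids))
    for i, lid in enumerate(lnc_ids):
        if not ok[lid]:
            continue
        ranking = _ranking_from_column(lid, corr[lid])
        pes[i], pvals[i] = pes_permutation_test(
            ranking, gene_set, cfg.n_permutations, seed_for[lid],
            cfg.weight_exponent,
        )
    qvals = bh_adjust(pvals)
    return [
        PESResult(
            lncrna_id=lid,
            pes=float(pes[i]),
            p_value=float(pvals[i]),
            q_value=float(qvals[i]),
            n_permutations=cfg.n_permutations,
            is_pdl=bool(abs(pes[i]) > cfg.pes_abs_threshold and qvals[i] < cfg.fdr_threshold),
        )
        for i, lid in enumerate(lnc_ids)
    ]


def pdl_ids(results: List[PESResult]) -> List[str]:
    return [r.lncrna_id for r in results if r.is_pdl]
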