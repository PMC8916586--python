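"""Pair-based risk signatures: Cox screening, LASSO fitting, risk scores.

Candidate pairs are screened by single-covariate Cox proportional-hazards
fits (Efron tie handling) with a hazard-ratio-direction consistency check
across cohorts; survivors enter an L1-penalized Cox model whose penalty is
chosen by k-fold cross-validated partial-likelihood deviance (the
Verweij & Van Houwelingen construction, lambda at the minimum). The
resulting linear score over binary pair indicators is thresholded at the
maximally selected log-rank cutpoint to define high- and low-risk groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .config import PipelineConfig
from .io import SurvivalTable, ValidationError
from .pairs import OrientedPair, PairIndicatorMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoxScreenResult:
    pair: OrientedPair
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    cohort_id: str


@dataclass
class SignatureModel:
    """Retained pairs with non-zero coefficients and an optional risk cutoff."""

    pairs: List[OrientedPair]
    coefficients: List[float]
    cutoff: Optional[float] = None
    training_cohort: str = ""
    lasso_lambda: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if len(self.pairs) == 0:
            raise ValidationError("a signature model must contain at least one pair")
        if len(self.pairs) != len(self.coefficients):
            raise ValidationError("pairs and coefficients must align")
        if any(c == 0 for c in self.coefficients):
            raise ValidationError("signature coefficients must be non-zero")


@dataclass
class RiskScoreVector:
    sample_ids: pd.Index
    scores: np.ndarray
    group: Optional[pd.Series] = None  # per-sample 'high'/'low'

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.sample_ids, name="risk_score")


def _align(indicators: PairIndicatorMatrix, survival: SurvivalTable):
    common = indicators.sample_ids.intersection(survival.sample_ids)
    if len(common) == 0:
        raise ValidationError("no samples shared between indicators and survival")
    X = indicators.indicators[common]
    surv = survival.subset(common)
    return X, surv


def univariate_cox_screen(
    indicators: PairIndicatorMatrix,
    survival: SurvivalTable,
    min_events: int = 10,
) -> List[CoxScreenResult]:
    """Single-covariate Cox PH fit per pair (Efron ties, Wald p and 95% CI).

    Constant indicators are skipped with a warning.
    """
    X, surv = _align(indicators, survival)
    if surv.event.sum() == 0:
        raise ValidationError("survival table contains no events")
    if surv.event.sum() < min_events:
        raise ValidationError(
            f"univariate screen needs >= {min_events} events, got {int(surv.event.sum())}"
        )
    results: List[CoxScreenResult] = []
    base = pd.DataFrame({"time": surv.time, "event": surv.event})
    for pair in indicators.pairs:
        x = X.loc[f"{pair.gene_a}|{pair.gene_b}"].to_numpy()
        if x.min() == x.max():
            logger.warning(
                "pair (%s, %s): constant indicator, skipped", pair.gene_a, pair.gene_b
            )
            continue
        df = base.copy()
        df["x"] = x.astype(float)
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        coef = float(cph.params_["x"])
        se = float(cph.standard_errors_["x"])
        results.append(
            CoxScreenResult(
                pair=pair,
                hr=float(np.exp(coef)),
                ci_low=float(np.exp(coef - 1.959963984540054 * se)),
                ci_high=float(np.exp(coef + 1.959963984540054 * se)),
                p_value=float(cph.summary.loc["x", "p"]),
                cohort_id="",
            )
        )
    return results


def select_consistent_pairs(
    screens: Dict[str, List[CoxScreenResult]],
    training_cohort: str,
    cfg: Optional[PipelineConfig] = None,
) -> List[OrientedPair]:
    """Pairs significant in the training cohort with one hazard direction
    everywhere.

    Retains pairs with p < cox_p_threshold in the training cohort (all
    cohorts if ``cfg.require_p_all_cohorts``) and sign(log HR) identical in
    every cohort; HR exactly 1 anywhere excludes the pair.
    """
    cfg = cfg or PipelineConfig()
    if training_cohort not in screens:
        raise ValidationError(f"training cohort {training_cohort!r} missing from screens")
    by_key = {
        cid: {r.pair.key: r for r in results} for cid, results in screens.items()
    }
    selected: List[OrientedPair] = []
    for key, train_res in by_key[training_cohort].items():
        per_cohort = []
        for cid, res in by_key.items():
            if key not in res:
                raise ValidationError(
                    f"pair {key} was not screened in cohort {cid!r}"
                )
            per_cohort.append(res[key])
        if cfg.require_p_all_cohorts:
            if any(r.p_value >= cfg.cox_p_threshold for r in per_cohort):
                continue
        elif train_res.p_value >= cfg.cox_p_threshold:
            continue
        signs = {np.sign(np.log(r.hr)) for r in per_cohort}
        if len(signs) != 1 or 0.0 in signs:
            continue
        selected.append(train_res.pair)
    return selected


def _breslow_partial_loglik(eta: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow-tie Cox partial log-likelihood of a linear predictor."""
    order = np.argsort(-time, kind="stable")  # descending: cumulative risk sets
    eta, time, event = eta[order], time[order], event[order]
    # log cumulative sum of exp(eta) over the risk set (numerically shifted)
    shift = eta.max()
    cum = np.logaddexp.accumulate(eta - shift) + shift
    # samples tied on time share the same risk set: take the last index per time
    ll = 0.0
    i = 0
    n = len(time)
    while i < n:
        j = i
        while j + 1 < n and time[j + 1] == time[i]:
            j += 1
        d = event[i : j + 1].sum()
        if d > 0:
            ll += eta[i : j + 1][event[i : j + 1] == 1].sum() - d * cum[j]
        i = j + 1
    return float(ll)


def fit_lasso_cox(
    indicators: PairIndicatorMatrix,
    survival: SurvivalTable,
    cfg: Optional[PipelineConfig] = None,
    training_cohort: str = "",
) -> SignatureModel:
    """L1-penalized Cox over a descending lambda path; lambda chosen at the
    minimum of the k-fold cross-validated partial-likelihood deviance.

    Folds are stratified by event status and seeded from ``cfg.rng_seed``.
    """
    cfg = cfg or PipelineConfig()
    X_df, surv = _align(indicators, survival)
    if len(indicators.pairs) < 2:
        raise ValidationError("LASSO fitting needs at least 2 candidate pairs")
    if surv.event.sum() < 10:
        raise ValidationError("LASSO fitting needs at least 10 events")
    X = X_df.to_numpy(dtype=float).T  # samples x pairs
    time = surv.time.to_numpy()
    event = surv.event.to_numpy().astype(bool)
    y = Surv.from_arrays(event=event, time=time)

    path = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=100, alpha_min_ratio=1e-4, fit_baseline_model=False
    )
    path.fit(X, y)
    alphas = np.asarray(path.alphas_)

    skf = StratifiedKFold(
        n_splits=cfg.lasso_folds, shuffle=True, random_state=cfg.rng_seed % (2**31)
    )
    cv_dev = np.zeros((cfg.lasso_folds, len(alphas)))
    for k, (tr, te) in enumerate(skf.split(X, event.astype(int))):
        fold = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=list(alphas), fit_baseline_model=False)
        fold.fit(X[tr], Surv.from_arrays(event=event[tr], time=time[tr]))
        fold_alphas = np.asarray(fold.alphas_)
        coefs = fold.coef_  # features x fitted alphas
        for j, alpha in enumerate(alphas):
            jj = int(np.argmin(np.abs(fold_alphas - alpha)))
            beta = coefs[:, jj]
            # Verweij & Van Houwelingen: deviance of the held-out contribution
            ll_full = _breslow_partial_loglik(X @ beta, time, event.astype(int))
            ll_train = _breslow_partial_loglik(X[tr] @ beta, time[tr], event[tr].astype(int))
            cv_dev[k, j] = -2.0 * (ll_full - ll_train)
    mean_dev = cv_dev.mean(axis=0)
    best = int(np.argmin(mean_dev))
    lambda_star = float(alphas[best])
    beta = path.coef_[:, best]
    nz = np.flatnonzero(beta)
    if nz.size == 0:
        raise ValidationError(
            "no pair has a non-zero coefficient at the selected lambda; "
            "relax the screening thresholds or add candidates"
        )
    kept_pairs = [indicators.pairs[i] for i in nz]
    return SignatureModel(
        pairs=kept_pairs,
        coefficients=[float(beta[i]) for i in nz],
        cutoff=None,
        training_cohort=training_cohort,
        lasso_lambda=lambda_star,
        seed=cfg.rng_seed,
    )


def risk_score(model: SignatureModel, indicators: PairIndicatorMatrix) -> RiskScoreVector:
    """Linear score: sum_i coefficient_i * indicator_i per sample (no intercept)."""
    rows = []
    for pair in model.pairs:
        rows.append(indicators.values_for(pair).astype(float))
    X = np.asarray(rows)  # pairs x samples
    scores = np.asarray(model.coefficients) @ X
    return RiskScoreVector(sample_ids=indicators.sample_ids, scores=scores)


def _logrank_chisq(time: np.ndarray, event: np.ndarray, in_group1: np.ndarray) -> float:
    """Two-group log-rank chi-square (1 df), vectorized over event times."""
    t_event = np.unique(time[event == 1])
    at_risk = time[None, :] >= t_event[:, None]
    n = at_risk.sum(axis=1).astype(float)
    n1 = (at_risk & in_group1[None, :]).sum(axis=1).astype(float)
    died = (time[None, :] == t_event[:, None]) & (event[None, :] == 1)
    d = died.sum(axis=1).astype(float)
    d1 = (died & in_group1[None, :]).sum(axis=1).astype(float)
    expected = d * n1 / n
    with np.errstate(invalid="ignore", divide="ignore"):
        var = d * (n1 / n) * (1 - n1 / n) * (n - d) / np.maximum(n - 1, 1.0)
    o_minus_e = (d1 - expected).sum()
    v = var[np.isfinite(var)].sum()
    if v <= 0:
        return 0.0
    return float(o_minus_e**2 / v)


def optimal_cutoff(
    scores: RiskScoreVector,
    survival: SurvivalTable,
    min_group_frac: float = 0.10,
) -> float:
    """Maximally selected log-rank cutpoint.

    Evaluates the two-group log-rank statistic at every midpoint of sorted
    unique scores leaving at least ``min_group_frac`` of samples per side
    and returns the split maximizing the statistic (ties -> lower cutoff).
    """
    ser = scores.as_series()
    common = ser.index.intersection(survival.sample_ids)
    if len(common) < 20:
        raise ValidationError("cutoff selection needs at least 20 samples")
    s = ser[common].to_numpy()
    surv = survival.subset(common)
    time, event = surv.time.to_numpy(), surv.event.to_numpy()
    uniq = np.unique(s)
    if uniq.size < 2:
        raise ValidationError("all risk scores identical; no admissible cutoff")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    min_side = np.array([min((s > c).mean(), (s <= c).mean()) for c in candidates])
    admissible = candidates[min_side >= min_group_frac]
    if admissible.size == 0:
        # heavily discrete scores may leave no split meeting the floor;
        # fall back to the least imbalanced splits so both groups stay
        # non-empty, and warn
        logger.warning(
            "no split satisfies the %.0f%% group-size floor; falling back to "
            "the least imbalanced candidate splits",
            100 * min_group_frac,
        )
        admissible = candidates[min_side == min_side.max()]
    best_stat, best_cut = -np.inf, None
    for cut in admissible:
        stat = _logrank_chisq(time, event, s > cut)
        if stat > best_stat + 1e-12:
            best_stat, best_cut = stat, cut
    return float(best_cut)


def assign_groups(scores: RiskScoreVector, cutoff: float) -> RiskScoreVector:
    """high iff score > cutoff (strict)."""
    if not np.isfinite(cutoff):
        raise ValidationError("cutoff must be finite")
    group = pd.Series(
        np.where(scores.scores > cutoff, "high", "low"), index=scores.sample_ids
    )
    return RiskScoreVector(scores.sample_ids, scores.scores, group)
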