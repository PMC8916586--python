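"""Validation of fitted signatures on survival cohorts.

Kaplan-Meier curves with log-rank tests, cumulative/dynamic time-dependent
AUC at fixed horizons (IPCW censoring adjustment), Harrell's concordance
index with a percentile-bootstrap CI, calibration of Cox-predicted against
Kaplan-Meier-observed survival in score bins, multivariate Cox adjustment,
and generic two-group comparisons (Wilcoxon rank-sum / Fisher's exact) for
user-supplied per-sample scores.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import mannwhitneyu, fisher_exact
from sksurv.metrics import concordance_index_censored, cumulative_dynamic_auc
from sksurv.util import Surv

from .io import SurvivalTable, ValidationError
from .signature import RiskScoreVector

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25


@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    test: str
    group_summaries: Dict[str, dict] = field(default_factory=dict)


@dataclass
class EvaluationReport:
    cohort_id: str
    km_logrank_chisq: float
    km_logrank_p: float
    auc_by_year: Dict[float, float]
    c_index: float
    c_index_ci: Tuple[float, float]
    calibration_bins: List[dict] = field(default_factory=list)
    multivariate: List[dict] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["auc_by_year"] = {str(k): v for k, v in self.auc_by_year.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "EvaluationReport":
        with open(path) as fh:
            payload = json.load(fh)
        payload["auc_by_year"] = {float(k): v for k, v in payload["auc_by_year"].items()}
        payload["c_index_ci"] = tuple(payload["c_index_ci"])
        return cls(**payload)


def _align_groups(groups: pd.Series, survival: SurvivalTable):
    common = groups.index.intersection(survival.sample_ids)
    if len(common) == 0:
        raise ValidationError("no samples shared between groups and survival")
    return groups[common], survival.subset(common)


def km_logrank(groups: pd.Series, survival: SurvivalTable):
    """Product-limit curves per group and the two-group log-rank test.

    Returns (chi-square, p, curves) with curves a dict group -> KM DataFrame.
    """
    groups, surv = _align_groups(groups, survival)
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise ValidationError(f"log-rank test needs two groups, got {levels}")
    res = multivariate_logrank_test(surv.time, groups, surv.event)
    curves = {}
    for lev in levels:
        mask = (groups == lev).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(surv.time[mask], surv.event[mask], label=str(lev))
        curves[lev] = kmf.survival_function_
    return float(res.test_statistic), float(res.p_value), curves


def time_dependent_auc(
    scores: RiskScoreVector,
    survival: SurvivalTable,
    horizons_years: Sequence[float],
) -> Dict[float, float]:
    """Cumulative/dynamic AUC at each horizon (IPCW censoring adjustment).

    Cases are events by the horizon, controls are samples still at risk;
    horizons are supplied in years (1 year = 365.25 days).
    """
    ser = scores.as_series()
    common = ser.index.intersection(survival.sample_ids)
    surv = survival.subset(common)
    t = surv.time.to_numpy()
    e = surv.event.to_numpy().astype(bool)
    max_fu = t.max()
    times_days = []
    for h in horizons_years:
        d = h * DAYS_PER_YEAR
        if d >= max_fu:
            raise ValidationError(
                f"horizon {h} years ({d:.0f} days) is beyond the maximum follow-up "
                f"({max_fu:.0f} days)"
            )
        times_days.append(d)
    y = Surv.from_arrays(event=e, time=t)
    auc, _ = cumulative_dynamic_auc(y, y, ser[common].to_numpy(), times_days)
    return {float(h): float(a) for h, a in zip(horizons_years, auc)}


def concordance_index(
    scores: RiskScoreVector,
    survival: SurvivalTable,
    n_boot: int = 2000,
    seed: int = 0,
) -> Tuple[float, float, float]:
    """Harrell's C over usable pairs with a percentile-bootstrap 95% CI."""
    ser = scores.as_series()
    common = ser.index.intersection(survival.sample_ids)
    surv = survival.subset(common)
    s = ser[common].to_numpy()
    t = surv.time.to_numpy()
    e = surv.event.to_numpy().astype(bool)
    if not e.any():
        raise ValidationError("no comparable pairs: survival has no events")
    c = float(concordance_index_censored(e, t, s)[0])
    if n_boot <= 0:
        return c, float("nan"), float("nan")
    rng = np.random.default_rng(seed)
    n = len(s)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if not e[idx].any():
            draws[b] = np.nan
            continue
        draws[b] = concordance_index_censored(e[idx], t[idx], s[idx])[0]
    lo, hi = np.nanpercentile(draws, [2.5, 97.5])
    return c, float(lo), float(hi)


def calibration_at_horizon(
    scores: RiskScoreVector,
    survival: SurvivalTable,
    horizon_years: float,
    n_bins: int = 3,
) -> List[dict]:
    """Mean Cox-predicted vs KM-observed survival at a horizon, per score bin.

    A one-covariate Cox model on the risk score (Breslow baseline) supplies
    the predictions; samples are split into ``n_bins`` equal-size score bins
    (degenerate bins are merged with a warning).
    """
    if n_bins < 2:
        raise ValidationError("calibration needs at least 2 bins")
    ser = scores.as_series()
    common = ser.index.intersection(survival.sample_ids)
    surv = survival.subset(common)
    horizon = horizon_years * DAYS_PER_YEAR
    if horizon >= surv.time.max():
        raise ValidationError("calibration horizon is beyond the maximum follow-up")
    df = pd.DataFrame(
        {"time": surv.time, "event": surv.event, "score": ser[common]}
    )
    if df["score"].nunique() == 1:
        # degenerate constant score: prediction collapses to the marginal KM
        kmf = KaplanMeierFitter()
        kmf.fit(df["time"], df["event"])
        pred = pd.Series(float(kmf.predict(horizon)), index=df.index)
    else:
        cph = CoxPHFitter(baseline_estimation_method="breslow")
        cph.fit(df, duration_col="time", event_col="event")
        pred = cph.predict_survival_function(df, times=[horizon]).iloc[0]
    try:
        bins = pd.qcut(df["score"], n_bins, labels=False, duplicates="drop")
    except ValueError:
        bins = pd.Series(0, index=df.index)
    if bins.isna().all():  # constant score: qcut yields no bin edges at all
        bins = pd.Series(0, index=df.index)
    if bins.nunique() < n_bins:
        logger.warning(
            "score ties collapsed calibration bins: %d requested, %d effective",
            n_bins, bins.nunique(),
        )
    out = []
    for b in sorted(bins.unique()):
        mask = bins == b
        kmf = KaplanMeierFitter()
        kmf.fit(df.loc[mask, "time"], df.loc[mask, "event"])
        observed = float(kmf.predict(horizon))
        out.append(
            {
                "bin": int(b),
                "mean_predicted": float(pred[mask.to_numpy()].mean()),
                "km_observed": observed,
                "n": int(mask.sum()),
            }
        )
    return out


def multivariate_cox(
    scores: RiskScoreVector,
    survival: SurvivalTable,
    covariates: pd.DataFrame,
) -> List[dict]:
    """Cox PH fit of risk score + clinical covariates; adjusted HR, CI, p.

    Rows with missing covariates are dropped (complete-case, logged);
    a collinear covariate raises an error naming it.
    """
    ser = scores.as_series()
    common = ser.index.intersection(survival.sample_ids).intersection(covariates.index)
    cov = covariates.loc[common]
    n_dropped = int(cov.isna().any(axis=1).sum())
    if n_dropped:
        logger.warning("dropping %d samples with missing covariates", n_dropped)
        cov = cov.dropna()
        common = cov.index
    surv = survival.subset(common)
    design = pd.concat([ser[common].rename("risk_score"), cov], axis=1).astype(float)
    # collinearity check: each column against the others
    X = design.to_numpy()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        for j, name in enumerate(design.columns):
            others = np.delete(X, j, axis=1)
            resid = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
            if np.allclose(resid, 0, atol=1e-10):
                raise ValidationError(f"covariate {name!r} is collinear with the others")
        raise ValidationError("design matrix is singular")
    df = design.copy()
    df["time"] = surv.time
    df["event"] = surv.event
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    out = []
    for name in design.columns:
        coef = float(cph.params_[name])
        se = float(cph.standard_errors_[name])
        out.append(
            {
                "covariate": name,
                "hr": float(np.exp(coef)),
                "ci_low": float(np.exp(coef - 1.959963984540054 * se)),
                "ci_high": float(np.exp(coef + 1.959963984540054 * se)),
                "p_value": float(cph.summary.loc[name, "p"]),
            }
        )
    return out


# ---------------------------------------------------------------------------
# generic two-group comparisons
# ---------------------------------------------------------------------------

def _fisher_2xk(table: np.ndarray) -> float:
    """Exact two-sided Fisher p for a 2 x k table by enumeration of all
    tables with the observed margins (multivariate hypergeometric null)."""
    row1 = int(table[0].sum())
    cols = table.sum(axis=0).astype(int)

    def log_comb(n, k):
        return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)

    denom = log_comb(int(cols.sum()), row1)

    def table_logp(cells):
        return sum(log_comb(c, x) for c, x in zip(cols, cells)) - denom

    obs_logp = table_logp(table[0].astype(int))
    total = 0.0
    ranges = [range(0, c + 1) for c in cols[:-1]]
    for partial in itertools.product(*ranges):
        last = row1 - sum(partial)
        if not 0 <= last <= cols[-1]:
            continue
        lp = table_logp(list(partial) + [last])
        if lp <= obs_logp + 1e-9:
            total += math.exp(lp)
    return min(1.0, total)


def compare_groups(
    values: pd.Series,
    groups: pd.Series,
    test: str = "wilcoxon_rank_sum",
) -> GroupComparison:
    """Compare a per-sample variable between two risk groups.

    Continuous values use the Wilcoxon rank-sum test (exact for both groups
    <= 50 without ties, normal approximation with continuity correction
    otherwise); categorical values use Fisher's exact test on the 2 x k
    contingency table.
    """
    common = values.index.intersection(groups.index)
    values, groups = values[common], groups[common]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValidationError(f"compare_groups needs exactly two groups, got {levels}")
    a = values[groups == levels[0]]
    b = values[groups == levels[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be non-empty")

    if test == "wilcoxon_rank_sum":
        x = pd.to_numeric(a, errors="coerce")
        y = pd.to_numeric(b, errors="coerce")
        if x.isna().any() or y.isna().any():
            raise ValidationError("wilcoxon_rank_sum requires numeric values")
        no_ties = len(set(x) | set(y)) == len(x) + len(y)
        method = "exact" if (len(x) <= 50 and len(y) <= 50 and no_ties) else "asymptotic"
        stat, p = mannwhitneyu(x, y, alternative="two-sided", method=method)
        summaries = {
            str(lev): {
                "n": int(len(v)),
                "median": float(v.median()),
                "iqr": [float(v.quantile(0.25)), float(v.quantile(0.75))],
            }
            for lev, v in ((levels[0], x), (levels[1], y))
        }
        return GroupComparison(float(stat), float(p), test, summaries)

    if test == "fisher_exact":
        table = pd.crosstab(groups, values.astype(str))
        if table.shape[0] != 2 or table.shape[1] < 2:
            raise ValidationError(
                f"fisher_exact needs a 2 x k table with k >= 2, got {table.shape}"
            )
        arr = table.to_numpy()
        if arr.shape[1] == 2:
            stat, p = fisher_exact(arr, alternative="two-sided")
            stat = float(stat)
        else:
            p = _fisher_2xk(arr)
            stat = float("nan")
        summaries = {
            str(g): {"n": int(arr[i].sum()), "counts": dict(zip(table.columns, map(int, arr[i])))}
            for i, g in enumerate(table.index)
        }
        return GroupComparison(stat, float(p), test, summaries)

    raise ValidationError(f"unknown test {test!r}")


def evaluate_cohort(
    cohort_id: str,
    scores: RiskScoreVector,
    survival: SurvivalTable,
    horizons_years: Sequence[float] = (1.0, 3.0, 5.0),
    covariates: Optional[pd.DataFrame] = None,
    n_boot: int = 2000,
    seed: int = 0,
    calibration_horizon_years: Optional[float] = None,
) -> EvaluationReport:
    """Assemble the full per-cohort report for grouped risk scores.

    Horizons beyond the cohort's follow-up are skipped with a warning.
    """
    if scores.group is None:
        raise ValidationError("scores must carry group assignments; call assign_groups first")
    chisq, p, _ = km_logrank(scores.group, survival)
    max_fu_years = survival.subset(
        scores.sample_ids.intersection(survival.sample_ids)
    ).time.max() / DAYS_PER_YEAR
    feasible = [h for h in horizons_years if h < max_fu_years]
    skipped = sorted(set(horizons_years) - set(feasible))
    if skipped:
        logger.warning("skipping AUC horizons beyond follow-up: %s", skipped)
    aucs = time_dependent_auc(scores, survival, feasible) if feasible else {}
    c, lo, hi = concordance_index(scores, survival, n_boot=n_boot, seed=seed)
    calib_h = calibration_horizon_years
    if calib_h is None and feasible:
        calib_h = feasible[len(feasible) // 2]
    calibration = (
        calibration_at_horizon(scores, survival, calib_h) if calib_h is not None else []
    )
    multi = multivariate_cox(scores, survival, covariates) if covariates is not None else []
    return EvaluationReport(
        cohort_id=cohort_id,
        km_logrank_chisq=chisq,
        km_logrank_p=p,
        auc_by_year=aucs,
        c_index=c,
        c_index_ci=(lo, hi),
        calibration_bins=calibration,
        multivariate=multi,
    )
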