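"""Multi-cohort synthetic expression + survival data with planted truth.

The generator emulates the study design the package targets: several
tumor/normal cohorts profiled on different platforms, a pathway gene set
whose activity couples a subset of lncRNAs to the mRNA field, a planted
set of lncRNA pairs whose within-sample ordering is stable in normals and
reversed in tumors, and survival times whose hazard is driven by the
binary pair indicators.

Generative model
----------------
* A latent pathway activity z_s ~ N(0, 1) per sample. Pathway mRNAs and
  true pathway-coupled lncRNAs load on z (loading scaled by
  ``coupling_strength``); everything else is independent Gaussian noise
  around a gene-specific log2 baseline.
* All coupled lncRNAs share one loading, so z cancels inside within-pair
  differences: pair support fractions are governed by ``noise_sd`` alone.
* Planted pairs occupy disjoint baseline bands above the rest of the
  coupled lncRNAs: in normals member A sits ``pair_offset_normal`` below
  the band center and member B the same amount above; in tumors BOTH
  members rise (B by ``member_shift``, A far enough to sit
  ``2 * pair_offset_tumor`` above B). Both members therefore deregulate
  "up" relative to the static null-lncRNA field while their ordering
  flips. Band centers are spaced by more than 2*pair_offset_normal so
  that no cross-pair combination changes ordering between normals and
  tumors, even in the noiseless limit.
* Tumor survival: T ~ Weibull(shape; rate = baseline_hazard *
  exp(sum_p beta_p x_ps)) with x_ps the realized binary indicator of
  planted pair p; shape 1 (exponential) by default. Censoring is uniform
  on (0, u] with u calibrated by bisection so the expected censoring
  fraction matches ``censoring_rate_target``.
* Finally each cohort's matrix passes through its own strictly increasing
  transform (identity / affine / power) emulating platform differences;
  within-sample ranks are untouched by construction.

All randomness flows from one seed through named substreams
(SeedSequence spawn keys per stage and cohort), so identical
(config, seed) inputs give bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import ExpressionCohort, SurvivalTable, GeneSet, ValidationError
from .pairs import OrientedPair, A_GT_B, A_LT_B

# ---------------------------------------------------------------------------
# monotone transform registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Transform:
    fn: Callable[[np.ndarray], np.ndarray]
    increasing: bool


MONOTONE_TRANSFORMS: Dict[str, _Transform] = {
    "identity": _Transform(lambda x: x, True),
    "affine": _Transform(lambda x: 2.2 * x + 1.5, True),
    "power13": _Transform(lambda x: np.power(x, 1.3), True),  # positive domain
    "log_shift": _Transform(lambda x: np.log2(x + 1.0), True),
    "cube": _Transform(lambda x: x ** 3, True),
    "negate": _Transform(lambda x: -x, False),
}


def apply_monotone_transform(cohort: ExpressionCohort, transform_id: str) -> ExpressionCohort:
    """Apply a named strictly increasing transform to the whole matrix.

    Within-sample ranks are unchanged; a decreasing transform id raises.
    """
    if transform_id not in MONOTONE_TRANSFORMS:
        raise ValidationError(f"unknown transform {transform_id!r}")
    tr = MONOTONE_TRANSFORMS[transform_id]
    if not tr.increasing:
        raise ValidationError(f"transform {transform_id!r} is not strictly increasing")
    x = cohort.values.to_numpy()
    y = tr.fn(x)
    # empirical strictness check on the data's own range
    u = np.unique(x.ravel())
    if np.any(np.diff(tr.fn(u)) <= 0) or not np.all(np.isfinite(y)):
        raise ValidationError(
            f"transform {transform_id!r} is not strictly increasing on the data range"
        )
    return ExpressionCohort(
        cohort_id=cohort.cohort_id,
        values=pd.DataFrame(y, index=cohort.gene_ids, columns=cohort.sample_ids),
        gene_type=cohort.gene_type,
        sample_group=cohort.sample_group,
    )


# ---------------------------------------------------------------------------
# configuration and truth
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohorts.

    Defaults mirror the three-cohort gastric-cancer design the package
    targets: cohort totals 348 / 300 / 191 (tumor + adjacent normal), a
    51-gene pathway set, and ~50% censoring. Geometry parameters are in
    log2 expression units; with ``noise_sd`` 0.6 the planted pairs hold
    their normal ordering in ~97% of normals and the reversed ordering in
    ~90% of tumors, leaving a ~10% informative minority per indicator.
    """

    n_lncrna: int = 80
    n_mrna: int = 300
    n_pathway_genes: int = 51
    n_true_pdls: int = 16
    n_planted_pairs: int = 4
    n_tumor: Sequence[int] = field(default_factory=lambda: [300, 260, 160])
    n_normal: Sequence[int] = field(default_factory=lambda: [48, 40, 31])
    n_cohorts: int = 3
    coupling_strength: float = 0.9
    beta_range: Tuple[float, float] = (0.7, 1.4)
    censoring_rate_target: float = 0.5
    baseline_hazard: float = float(np.log(2.0) / 730.0)  # median ~2 years, days^-1
    weibull_shape: float = 1.0
    noise_sd: float = 0.6
    # planted-pair geometry (log2 units); see module docstring
    pair_offset_normal: float = 0.8
    pair_offset_tumor: float = 0.55
    member_shift: float = 1.0
    band_spacing: float = 1.8
    band_base: float = 7.2
    #: per-gene probability of a rank-breaking probe swap (off by default)
    rank_noise_rate: float = 0.0
    cohort_transform_ids: Sequence[str] = field(
        default_factory=lambda: ["identity", "affine", "power13"]
    )

    def __post_init__(self) -> None:
        if self.n_pathway_genes > self.n_mrna:
            raise ValidationError("n_pathway_genes cannot exceed n_mrna")
        if self.n_true_pdls > self.n_lncrna:
            raise ValidationError("n_true_pdls cannot exceed n_lncrna")
        if 2 * self.n_planted_pairs > self.n_true_pdls:
            raise ValidationError(
                "more planted pairs than pair slots: need 2*n_planted_pairs <= n_true_pdls"
            )
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValidationError("coupling_strength must lie in [0, 1]")
        if not 0.0 < self.censoring_rate_target < 1.0:
            raise ValidationError("censoring_rate_target must lie in (0, 1)")
        if self.noise_sd < 0 or self.baseline_hazard <= 0:
            raise ValidationError("noise_sd must be >= 0 and baseline_hazard > 0")
        if len(self.n_tumor) != self.n_cohorts or len(self.n_normal) != self.n_cohorts:
            raise ValidationError("n_tumor and n_normal must have n_cohorts entries")
        if len(self.cohort_transform_ids) < self.n_cohorts:
            raise ValidationError("need one transform id per cohort")
        if min(self.n_tumor) < 1 or min(self.n_normal) < 0:
            raise ValidationError("cohort sizes must be positive")


@dataclass
class SimulationTruth:
    true_pdl_ids: List[str]
    planted_pairs: List[OrientedPair]  # tumor orientation
    true_betas: Dict[Tuple[str, str, str], float]  # pair.key -> log-hazard coefficient
    cohort_transforms: Dict[str, str]
    rng_seed: int


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _calibrate_censoring_bound(rates: np.ndarray, shape: float, target: float) -> float:
    """Upper bound u of the Uniform(0, u] censoring law such that the mean
    probability of censoring equals ``target``.

    For C ~ U(0, u] and T with survival S(t) = exp(-r t^shape),
    P(censored) = E_C[S(C)] = (1/u) int_0^u S(t) dt, averaged over the
    per-sample rates r; monotone decreasing in u, solved by bisection.
    """

    def mean_censor(u: float) -> float:
        t = np.linspace(0.0, u, 2049)
        surv = np.exp(-np.outer(rates, t**shape))
        return float(np.trapezoid(surv, t, axis=1).mean() / u)

    lo, hi = 1.0, 10.0
    while mean_censor(hi) > target and hi < 1e9:
        hi *= 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if mean_censor(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_cohorts(
    cfg: SimulationConfig, seed: int
) -> Tuple[List[ExpressionCohort], List[SurvivalTable], SimulationTruth]:
    """Generate the multi-cohort dataset and its planted ground truth."""
    lnc_ids = [f"LNC{i:04d}" for i in range(cfg.n_lncrna)]
    mrna_ids = [f"MRNA{i:04d}" for i in range(cfg.n_mrna)]
    pathway_ids = mrna_ids[: cfg.n_pathway_genes]
    pdl_ids = lnc_ids[: cfg.n_true_pdls]
    planted_genes = pdl_ids[: 2 * cfg.n_planted_pairs]
    extra_pdls = pdl_ids[2 * cfg.n_planted_pairs :]
    null_lnc = lnc_ids[cfg.n_true_pdls :]

    rng_base = _stream(seed, 0)
    genes = lnc_ids + mrna_ids
    gene_pos = {g: i for i, g in enumerate(genes)}

    # --- baselines (log2 scale) -------------------------------------------
    baseline_n = pd.Series(0.0, index=genes)
    baseline_t = pd.Series(0.0, index=genes)
    planted_pairs: List[OrientedPair] = []
    for p in range(cfg.n_planted_pairs):
        center = cfg.band_base + p * cfg.band_spacing
        ga, gb = planted_genes[2 * p], planted_genes[2 * p + 1]
        baseline_n[ga] = center - cfg.pair_offset_normal  # A below B in normals
        baseline_n[gb] = center + cfg.pair_offset_normal
        baseline_t[gb] = baseline_n[gb] + cfg.member_shift  # both rise in tumors,
        baseline_t[ga] = baseline_t[gb] + 2.0 * cfg.pair_offset_tumor  # A overtakes
        a, b = sorted((ga, gb))
        orient = A_GT_B if a == ga else A_LT_B  # tumor state: expr(ga) > expr(gb)
        planted_pairs.append(OrientedPair(a, b, orient))

    # non-planted coupled lncRNAs sit in a disjoint band below the planted ones
    for i, g in enumerate(extra_pdls):
        baseline_n[g] = baseline_t[g] = 4.2 + 0.25 * i
    # null lncRNAs and mRNAs: static baselines over the full dynamic range
    for g, v in zip(null_lnc, rng_base.uniform(6.0, 15.0, size=len(null_lnc))):
        baseline_n[g] = baseline_t[g] = v
    for g, v in zip(mrna_ids, rng_base.uniform(6.0, 14.0, size=len(mrna_ids))):
        baseline_n[g] = baseline_t[g] = v

    # loadings on the latent pathway factor
    loading = np.zeros(len(genes))
    for g in pdl_ids + pathway_ids:
        loading[gene_pos[g]] = 1.2 * cfg.coupling_strength

    # per-pair hazard coefficients
    beta_rng = _stream(seed, 1)
    betas = beta_rng.uniform(*cfg.beta_range, size=cfg.n_planted_pairs)
    betas *= beta_rng.choice([-1.0, 1.0], size=cfg.n_planted_pairs)
    true_betas = {pp.key: float(b) for pp, b in zip(planted_pairs, betas)}

    gene_type = pd.Series(["lncRNA"] * len(lnc_ids) + ["mRNA"] * len(mrna_ids), index=genes)
    cohorts: List[ExpressionCohort] = []
    survivals: List[SurvivalTable] = []
    transforms: Dict[str, str] = {}

    for c in range(cfg.n_cohorts):
        cid = f"cohort{c}"
        n_t, n_n = cfg.n_tumor[c], cfg.n_normal[c]
        samples = [f"{cid}_T{i:04d}" for i in range(n_t)] + [
            f"{cid}_N{i:04d}" for i in range(n_n)
        ]
        group = pd.Series(["tumor"] * n_t + ["normal"] * n_n, index=samples)

        rng = _stream(seed, 2, c)
        z = rng.standard_normal(n_t + n_n)
        is_tumor = np.array([True] * n_t + [False] * n_n)
        base = np.where(
            is_tumor[None, :],
            baseline_t.to_numpy()[:, None],
            baseline_n.to_numpy()[:, None],
        )
        vals = (
            base
            + loading[:, None] * z[None, :]
            + cfg.noise_sd * rng.standard_normal((len(genes), n_t + n_n))
        )
        if cfg.rank_noise_rate > 0:
            # optional robustness knob: per-gene probe scrambles that break ranks
            swap = rng.random(len(genes)) < cfg.rank_noise_rate
            vals[swap] = vals[np.ix_(swap, rng.permutation(n_t + n_n))]
        # the log2 baselines keep values positive except for ~1e-6 tail events
        vals = np.maximum(vals, 1e-3)
        values = pd.DataFrame(vals, index=genes, columns=samples)

        # --- survival for tumor samples -----------------------------------
        surv_rng = _stream(seed, 3, c)
        tumor_cols = samples[:n_t]
        eta = np.zeros(n_t)
        for pp in planted_pairs:
            xa = values.loc[pp.gene_a, tumor_cols].to_numpy()
            xb = values.loc[pp.gene_b, tumor_cols].to_numpy()
            ind = (xa > xb) if pp.orientation == A_GT_B else (xa < xb)
            eta += true_betas[pp.key] * ind.astype(float)
        rates = cfg.baseline_hazard * np.exp(eta)
        t_event = (-np.log(surv_rng.uniform(size=n_t)) / rates) ** (1.0 / cfg.weibull_shape)
        u_cens = _calibrate_censoring_bound(rates, cfg.weibull_shape, cfg.censoring_rate_target)
        c_time = surv_rng.uniform(0.0, u_cens, size=n_t)
        survivals.append(
            SurvivalTable(
                pd.DataFrame(
                    {
                        "time": np.minimum(t_event, c_time),
                        "event": (t_event <= c_time).astype(int),
                    },
                    index=tumor_cols,
                ),
                endpoint="OS",
            )
        )

        # --- cohort-specific monotone distortion --------------------------
        tid = cfg.cohort_transform_ids[c]
        tr = MONOTONE_TRANSFORMS[tid]
        if not tr.increasing:
            raise ValidationError(f"cohort transform {tid!r} must be increasing")
        transforms[cid] = tid
        values = pd.DataFrame(tr.fn(values.to_numpy()), index=genes, columns=samples)
        cohorts.append(ExpressionCohort(cid, values, gene_type, group))

    truth = SimulationTruth(
        true_pdl_ids=list(pdl_ids),
        planted_pairs=planted_pairs,
        true_betas=true_betas,
        cohort_transforms=transforms,
        rng_seed=seed,
    )
    return cohorts, survivals, truth


def pathway_gene_set(cfg: SimulationConfig, name: str = "SYNTH_PATHWAY") -> GeneSet:
    """The gene set matching the simulated pathway mRNAs."""
    return GeneSet(name, frozenset(f"MRNA{i:04d}" for i in range(cfg.n_pathway_genes)))
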