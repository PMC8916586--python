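"""Pipeline-wide thresholds and tuning knobs.

A single :class:`PipelineConfig` travels through every stage so that the
thresholds quoted for the published analysis (85% stable/reversal support,
60% qualification, |PES| > 0.995, FDR < 0.05, top-3 CV partners, 10-fold
cross-validation) live in one place and can be overridden from YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value violates its documented domain."""


@dataclass
class PipelineConfig:
    #: minimum fraction of normal samples sharing one ordering for a stable pair
    stable_frac: float = 0.85
    #: minimum fraction of tumor samples showing the opposite ordering (reversal)
    reversal_frac: float = 0.85
    #: strict lower bound on tumor support for final qualification ("more than 60%")
    qualify_frac: float = 0.60
    #: |enrichment score| threshold for calling a pathway-coupled lncRNA
    pes_abs_threshold: float = 0.995
    #: Benjamini-Hochberg FDR threshold for the permutation test
    fdr_threshold: float = 0.05
    #: univariate Cox screen p-value threshold (training cohort)
    cox_p_threshold: float = 0.05
    #: partners retained per anchor in the coefficient-of-variation pruning
    top_cv_partners: int = 3
    #: random gene-set permutations for the enrichment null
    n_permutations: int = 999
    #: folds for the LASSO Cox cross-validated deviance
    lasso_folds: int = 10
    #: master seed for every stochastic stage
    rng_seed: int = 0
    #: horizons (in years) for time-dependent AUC
    auc_years: Sequence[float] = field(default_factory=lambda: [1.0, 3.0, 5.0])
    #: correlation method for the lncRNA-mRNA ranking
    correlation_method: str = "spearman"
    #: weight exponent on |correlation| in the enrichment running sum
    weight_exponent: float = 1.0
    #: minimum number of normal samples required for stable-pair detection
    min_normal_samples: int = 5
    #: smallest admissible fraction per risk group when scanning for a cutoff
    min_group_frac: float = 0.10
    #: require the Cox screen p-value in every cohort (not just training)
    require_p_all_cohorts: bool = False
    #: bootstrap draws for the concordance-index confidence interval
    n_bootstrap: int = 2000
    #: declared scale of the expression input ("log2" or "linear")
    expression_scale: str = "log2"

    def __post_init__(self) -> None:
        for name in ("stable_frac", "reversal_frac", "qualify_frac"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigError(f"{name} must lie in (0, 1], got {v!r}")
        if self.top_cv_partners < 1:
            raise ConfigError("top_cv_partners must be >= 1")
        if self.lasso_folds < 3:
            raise ConfigError("lasso_folds must be >= 3")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be positive")
        if self.correlation_method not in ("spearman", "pearson"):
            raise ConfigError(
                f"correlation_method must be 'spearman' or 'pearson', got "
                f"{self.correlation_method!r}"
            )
        if self.expression_scale not in ("log2", "linear"):
            raise ConfigError("expression_scale must be 'log2' or 'linear'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["auc_years"] = list(self.auc_years)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a config from YAML; keys absent from the file keep defaults."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
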