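"""Readers, writers, and validated in-memory containers.

Expression travels as a genes x samples matrix with per-gene type labels
(lncRNA vs mRNA) and per-sample group labels (tumor vs normal). Survival is
a per-sample table of follow-up time (days) and an event indicator. All
formats are plain text: TSV for matrices/tables (gzip transparently
supported via pandas), one-symbol-per-line or GMT for gene sets, JSON for
fitted models. Missing values in expression are rejected outright — the
downstream rank logic has no NA semantics.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MODEL_SCHEMA_VERSION = 1


class ValidationError(ValueError):
    """An input artifact violates a structural invariant."""


def _check_unique(ids: Iterable[str], what: str) -> None:
    idx = pd.Index(ids)
    if idx.has_duplicates:
        dups = sorted(set(idx[idx.duplicated()]))
        raise ValidationError(f"duplicate {what} ids: {dups}")


@dataclass
class ExpressionCohort:
    """A validated expression matrix with gene-type and sample-group labels.

    values is genes x samples; gene_type maps every gene to 'lncRNA' or
    'mRNA'; sample_group maps every sample to 'tumor' or 'normal'.
    """

    cohort_id: str
    values: pd.DataFrame
    gene_type: pd.Series
    sample_group: pd.Series

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene")
        _check_unique(self.values.columns, "sample")
        if not np.issubdtype(np.asarray(self.values).dtype, np.number):
            raise ValidationError("expression values must be numeric")
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            g, s = np.argwhere(np.isnan(arr))[0]
            raise ValidationError(
                f"missing value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}; NAs are not permitted"
            )
        if (arr < 0).any():
            raise ValidationError("expression values must be non-negative")
        missing_type = self.values.index.difference(self.gene_type.index)
        if len(missing_type):
            raise ValidationError(f"genes without a type annotation: {sorted(missing_type)}")
        missing_group = self.values.columns.difference(self.sample_group.index)
        if len(missing_group):
            raise ValidationError(f"samples without a group label: {sorted(missing_group)}")
        self.gene_type = self.gene_type.reindex(self.values.index)
        self.sample_group = self.sample_group.reindex(self.values.columns)
        bad_types = set(self.gene_type.unique()) - {"lncRNA", "mRNA"}
        if bad_types:
            raise ValidationError(f"unknown gene types: {sorted(bad_types)}")
        bad_groups = set(self.sample_group.unique()) - {"tumor", "normal"}
        if bad_groups:
            raise ValidationError(f"unknown sample groups: {sorted(bad_groups)}")
        if not (self.sample_group == "tumor").any():
            raise ValidationError("cohort must contain at least one tumor sample")

    # -- convenience views -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def lncrna_ids(self) -> pd.Index:
        return self.values.index[self.gene_type == "lncRNA"]

    @property
    def mrna_ids(self) -> pd.Index:
        return self.values.index[self.gene_type == "mRNA"]

    @property
    def tumor_samples(self) -> pd.Index:
        return self.values.columns[self.sample_group == "tumor"]

    @property
    def normal_samples(self) -> pd.Index:
        return self.values.columns[self.sample_group == "normal"]

    def subset(self, genes=None, samples=None) -> "ExpressionCohort":
        vals = self.values
        if genes is not None:
            missing = pd.Index(genes).difference(vals.index)
            if len(missing):
                raise ValidationError(f"unknown gene ids: {sorted(missing)}")
            vals = vals.loc[list(genes)]
        if samples is not None:
            vals = vals[list(samples)]
        return ExpressionCohort(
            cohort_id=self.cohort_id,
            values=vals,
            gene_type=self.gene_type,
            sample_group=self.sample_group,
        )


@dataclass
class SurvivalTable:
    """Follow-up times (days), event indicators, optional clinical covariates."""

    data: pd.DataFrame  # index = sample_id; columns: time, event, covariates...
    endpoint: str = "OS"

    def __post_init__(self) -> None:
        if self.endpoint not in ("OS", "RFS"):
            raise ValidationError(f"endpoint must be 'OS' or 'RFS', got {self.endpoint!r}")
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise ValidationError(f"survival table lacks a {col!r} column")
        _check_unique(self.data.index, "sample")
        bad_t = self.data.index[~(self.data["time"] > 0)]
        if len(bad_t):
            raise ValidationError(f"non-positive follow-up time for samples: {list(bad_t)}")
        bad_e = self.data.index[~self.data["event"].isin([0, 1])]
        if len(bad_e):
            raise ValidationError(f"event indicator not in {{0,1}} for samples: {list(bad_e)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def time(self) -> pd.Series:
        return self.data["time"].astype(float)

    @property
    def event(self) -> pd.Series:
        return self.data["event"].astype(int)

    @property
    def covariates(self) -> pd.DataFrame:
        return self.data.drop(columns=["time", "event"])

    def subset(self, samples) -> "SurvivalTable":
        missing = pd.Index(samples).difference(self.data.index)
        if len(missing):
            raise ValidationError(f"samples absent from survival table: {sorted(missing)}")
        return SurvivalTable(self.data.loc[list(samples)].copy(), endpoint=self.endpoint)


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _read_label_file(path, what: str) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment=None)
    if df.shape[1] != 2:
        raise ValidationError(f"{what} file {path} must have two tab-separated columns")
    ser = pd.Series(df[1].values, index=df[0].values)
    _check_unique(ser.index, what)
    return ser


def read_expression(path, gene_type_path, sample_group_path, cohort_id: str) -> ExpressionCohort:
    """Read a genes x samples TSV plus its gene-type and sample-group maps."""
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    _check_unique(raw.index, "gene")
    _check_unique(raw.columns, "sample")
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna()
    if bool(bad.to_numpy().any()):
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"non-numeric cell at gene {raw.index[g]!r}, sample {raw.columns[s]!r}: "
            f"{raw.iloc[g, s]!r}"
        )
    gene_type = _read_label_file(gene_type_path, "gene")
    sample_group = _read_label_file(sample_group_path, "sample")
    return ExpressionCohort(cohort_id, values.astype(float), gene_type, sample_group)


def write_expression(cohort: ExpressionCohort, path, gene_type_path, sample_group_path) -> None:
    # repr-level float formatting keeps the round trip exact
    cohort.values.to_csv(path, sep="\t", float_format="%.17g")
    cohort.gene_type.to_csv(gene_type_path, sep="\t", header=False)
    cohort.sample_group.to_csv(sample_group_path, sep="\t", header=False)


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def read_gene_set(path, format: str = "plain", name: Optional[str] = None) -> GeneSet:
    """Read a gene set from a plain symbol list or a GMT line.

    Duplicated symbols are deduplicated with a warning.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise ValidationError(f"gene set file {path} is empty")
    if format == "plain":
        symbols = lines
        set_name = name or "gene_set"
    elif format == "GMT":
        fields = lines[0].split("\t")
        if len(fields) < 3:
            raise ValidationError("GMT line needs name, description and >=1 member")
        set_name = name or fields[0]
        symbols = fields[2:]
    else:
        raise ValidationError(f"unknown gene set format {format!r}")
    if len(symbols) != len(set(symbols)):
        dups = sorted({s for s in symbols if symbols.count(s) > 1})
        logger.warning("gene set %s contains duplicated symbols %s; deduplicating", set_name, dups)
    return GeneSet(set_name, frozenset(symbols))


def write_gene_set(gene_set: GeneSet, path) -> None:
    with open(path, "w") as fh:
        for sym in sorted(gene_set.members):
            fh.write(sym + "\n")


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def read_survival(path, endpoint: str = "OS") -> SurvivalTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SurvivalTable(df, endpoint=endpoint)


def write_survival(table: SurvivalTable, path) -> None:
    table.data.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# fitted models (JSON)
# ---------------------------------------------------------------------------

def write_model(model, path) -> None:
    """Serialize a SignatureModel as structured JSON (exact coefficients)."""
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "training_cohort": model.training_cohort,
        "lasso_lambda": model.lasso_lambda,
        "cutoff": model.cutoff,
        "seed": model.seed,
        "pairs": [
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "orientation": p.orientation,
                "coefficient": float(c),
            }
            for p, c in zip(model.pairs, model.coefficients)
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_model(path):
    from .pairs import OrientedPair
    from .signature import SignatureModel

    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ValidationError(f"unknown model schema version {version!r}")
    pairs = [
        OrientedPair(d["gene_a"], d["gene_b"], d["orientation"]) for d in payload["pairs"]
    ]
    coefs = [d["coefficient"] for d in payload["pairs"]]
    return SignatureModel(
        pairs=pairs,
        coefficients=coefs,
        cutoff=payload.get("cutoff"),
        training_cohort=payload.get("training_cohort", ""),
        lasso_lambda=payload.get("lasso_lambda"),
        seed=payload.get("seed"),
    )


# ---------------------------------------------------------------------------
# pair sets (TSV)
# ---------------------------------------------------------------------------

def write_pairs(pairs, path) -> None:
    rows = [
        {
            "gene_a": p.gene_a,
            "gene_b": p.gene_b,
            "orientation": p.orientation,
            "support_normal": p.support_normal,
            "support_tumor": p.support_tumor,
        }
        for p in pairs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_pairs(path):
    from .pairs import OrientedPair

    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        sn = None if pd.isna(row.support_normal) else float(row.support_normal)
        st = None if pd.isna(row.support_tumor) else float(row.support_tumor)
        out.append(OrientedPair(row.gene_a, row.gene_b, row.orientation, sn, st))
    return out
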