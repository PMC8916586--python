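"""Relative-expression-ordering (REO) gene pairs.

The pipeline converts expression to within-sample ranks, finds *stable*
pairs (one ordering in >= 85% of normal samples), keeps the subset whose
ordering flips in >= 85% of tumor samples (*reversal* pairs), filters for
members deregulated in the same direction, prunes partners by the
coefficient of variation of the per-sample rank difference, re-checks
tumor support against a strict 60% qualification rule, and finally encodes
each pair as a binary per-sample indicator (1 iff gene_a > gene_b).

Everything downstream of the rank transform depends on the data only
through within-sample orderings, so all outputs are invariant under any
strictly increasing per-sample transform of expression — the property that
makes the resulting signatures portable across platforms.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionCohort, ValidationError

logger = logging.getLogger(__name__)

A_GT_B = "A_gt_B"
A_LT_B = "A_lt_B"
_OPPOSITE = {A_GT_B: A_LT_B, A_LT_B: A_GT_B}


@dataclass(frozen=True)
class OrientedPair:
    """An unordered gene pair stored canonically (gene_a < gene_b) with an
    orientation flag carrying the direction and support fractions."""

    gene_a: str
    gene_b: str
    orientation: str
    support_normal: Optional[float] = None
    support_tumor: Optional[float] = None

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValidationError(f"pair members must differ, got {self.gene_a!r} twice")
        if self.gene_a > self.gene_b:
            raise ValidationError(
                f"pairs are stored with gene_a < gene_b lexicographically; "
                f"got ({self.gene_a!r}, {self.gene_b!r})"
            )
        if self.orientation not in _OPPOSITE:
            raise ValidationError(f"unknown orientation {self.orientation!r}")

    @property
    def key(self):
        """Identity including orientation (used for intersections)."""
        return (self.gene_a, self.gene_b, self.orientation)

    @property
    def genes(self):
        return (self.gene_a, self.gene_b)

    def opposite(self) -> "OrientedPair":
        return replace(self, orientation=_OPPOSITE[self.orientation])


@dataclass
class RankMatrix:
    """Within-sample ranks (columns), 1 = smallest, ties = average rank."""

    ranks: pd.DataFrame  # genes x samples

    @property
    def gene_ids(self) -> pd.Index:
        return self.ranks.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.ranks.columns

    @property
    def n_samples(self) -> int:
        return self.ranks.shape[1]


@dataclass
class PairIndicatorMatrix:
    """Binary pairs x samples matrix.

    An entry is 1 iff the pair's stated (tumor) orientation holds strictly
    in that sample — for an ``A_gt_B`` pair, 1 iff expr(gene_a) >
    expr(gene_b); ties encode as 0. In the field's usual exposition the
    greater-in-tumor gene is relabeled "lncRNA-A" so the indicator reads
    "1 iff A > B"; with canonical lexicographic storage the orientation
    flag carries that relabeling instead.
    """

    pairs: List[OrientedPair]
    indicators: pd.DataFrame  # pairs (index "geneA|geneB") x samples, int8

    @property
    def sample_ids(self) -> pd.Index:
        return self.indicators.columns

    def values_for(self, pair: OrientedPair) -> np.ndarray:
        label = f"{pair.gene_a}|{pair.gene_b}"
        if label not in self.indicators.index:
            raise ValidationError(f"pair {label} absent from indicator matrix")
        return self.indicators.loc[label].to_numpy()


@dataclass(frozen=True)
class DeregulationDirection:
    gene_id: str
    direction: str  # up / down / unchanged
    median_rank_tumor: float
    median_rank_normal: float


@dataclass(frozen=True)
class PartnerCV:
    anchor_id: str
    partner_id: str
    cv: float


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def rank_transform(
    cohort: ExpressionCohort,
    gene_subset: Sequence[str],
    sample_group: Optional[str] = None,
) -> RankMatrix:
    """Column-wise (within-sample) average ranks over ``gene_subset``.

    ``sample_group`` restricts columns to 'tumor' or 'normal' samples.
    """
    if len(gene_subset) == 0:
        raise ValidationError("gene_subset must be non-empty")
    missing = pd.Index(gene_subset).difference(cohort.gene_ids)
    if len(missing):
        raise ValidationError(f"unknown gene ids: {sorted(missing)}")
    vals = cohort.values.loc[list(gene_subset)]
    if sample_group is not None:
        keep = cohort.sample_ids[cohort.sample_group == sample_group]
        vals = vals[keep]
    ranks = rankdata(vals.to_numpy(), axis=0, method="average")
    return RankMatrix(pd.DataFrame(ranks, index=vals.index, columns=vals.columns))


def _ordering_fractions(ranks: RankMatrix):
    """frac_lt[i, j] = fraction of samples with rank(gene_i) < rank(gene_j).

    Genes come out sorted lexicographically; ties count toward neither
    orientation, so frac_lt + frac_lt.T <= 1.
    """
    order = np.argsort(ranks.gene_ids)
    ids = ranks.gene_ids[order]
    R = ranks.ranks.to_numpy()[order]
    G = R.shape[0]
    frac_lt = np.empty((G, G))
    for i in range(G):
        frac_lt[i] = (R[i] < R).mean(axis=1)
    return ids, frac_lt


def find_stable_pairs(
    ranks_normal: RankMatrix, stable_frac: float, min_normal_samples: int = 5
) -> List[OrientedPair]:
    """Pairs with one fixed ordering in >= ``stable_frac`` of normal samples."""
    if ranks_normal.n_samples < min_normal_samples:
        raise ValidationError(
            f"stable-pair detection needs >= {min_normal_samples} normal samples, "
            f"got {ranks_normal.n_samples}"
        )
    ids, frac_lt = _ordering_fractions(ranks_normal)
    out: List[OrientedPair] = []
    G = len(ids)
    for i in range(G):
        for j in range(i + 1, G):
            if frac_lt[i, j] >= stable_frac:
                out.append(OrientedPair(ids[i], ids[j], A_LT_B, support_normal=frac_lt[i, j]))
            elif frac_lt[j, i] >= stable_frac:
                out.append(OrientedPair(ids[i], ids[j], A_GT_B, support_normal=frac_lt[j, i]))
    return out


def pair_support(ranks: RankMatrix, pair: OrientedPair) -> float:
    """Fraction of samples satisfying the pair's stated orientation (ties count
    toward neither orientation)."""
    try:
        ra = ranks.ranks.loc[pair.gene_a].to_numpy()
        rb = ranks.ranks.loc[pair.gene_b].to_numpy()
    except KeyError as exc:
        raise ValidationError(f"pair gene {exc.args[0]!r} absent from rank matrix") from exc
    if pair.orientation == A_GT_B:
        return float((ra > rb).mean())
    return float((ra < rb).mean())


def find_reversal_pairs(
    ranks_tumor: RankMatrix,
    stable_pairs: Sequence[OrientedPair],
    reversal_frac: float,
) -> List[OrientedPair]:
    """Stable pairs whose *opposite* ordering holds in >= ``reversal_frac`` of
    tumor samples; returned with the tumor orientation."""
    if not stable_pairs:
        raise ValidationError("stable_pairs must be non-empty")
    out: List[OrientedPair] = []
    for sp in stable_pairs:
        flipped = sp.opposite()
        support = pair_support(ranks_tumor, flipped)
        if support >= reversal_frac:
            out.append(replace(flipped, support_tumor=support))
    return out


def deregulation_directions(
    ranks_tumor: RankMatrix, ranks_normal: RankMatrix
) -> List[DeregulationDirection]:
    """Per-gene direction of deregulation by median within-sample rank."""
    if not ranks_tumor.gene_ids.sort_values().equals(ranks_normal.gene_ids.sort_values()):
        raise ValidationError("tumor and normal rank matrices cover different gene universes")
    med_t = ranks_tumor.ranks.median(axis=1)
    med_n = ranks_normal.ranks.median(axis=1)
    out = []
    for gene in ranks_tumor.gene_ids:
        diff = med_t[gene] - med_n[gene]
        direction = "up" if diff > 0 else ("down" if diff < 0 else "unchanged")
        out.append(DeregulationDirection(gene, direction, float(med_t[gene]), float(med_n[gene])))
    return out


def filter_same_direction(
    pairs: Sequence[OrientedPair], directions: Sequence[DeregulationDirection]
) -> List[OrientedPair]:
    """Keep pairs whose members are both 'up' or both 'down'."""
    dmap: Dict[str, str] = {d.gene_id: d.direction for d in directions}
    missing = {g for p in pairs for g in p.genes} - set(dmap)
    if missing:
        raise ValidationError(f"directions missing for genes: {sorted(missing)}")
    return [
        p
        for p in pairs
        if dmap[p.gene_a] == dmap[p.gene_b] and dmap[p.gene_a] != "unchanged"
    ]


def partner_cv(ranks_tumor: RankMatrix, anchor: str, partner: str) -> float:
    """Coefficient of variation over tumor samples of the per-sample rank
    difference rank(anchor) - rank(partner); zero mean maps to +inf."""
    d = ranks_tumor.ranks.loc[anchor].to_numpy() - ranks_tumor.ranks.loc[partner].to_numpy()
    mean = d.mean()
    sd = d.std(ddof=1) if d.size > 1 else 0.0
    if mean == 0.0:
        logger.warning("zero mean rank difference for (%s, %s); CV set to +inf", anchor, partner)
        return float("inf")
    return float(sd / abs(mean))


def partner_cv_prune(
    pairs: Sequence[OrientedPair], ranks_tumor: RankMatrix, top_k: int
) -> List[OrientedPair]:
    """Keep, per anchor gene, only its ``top_k`` partners by descending CV.

    Every gene acts as anchor for the pairs containing it; a pair survives if
    it is retained from either side.
    """
    if top_k < 1:
        raise ValidationError("top_k must be >= 1")
    by_anchor: Dict[str, List[PartnerCV]] = {}
    for p in pairs:
        for anchor, partner in ((p.gene_a, p.gene_b), (p.gene_b, p.gene_a)):
            by_anchor.setdefault(anchor, []).append(
                PartnerCV(anchor, partner, partner_cv(ranks_tumor, anchor, partner))
            )
    kept = set()
    for anchor, entries in by_anchor.items():
        entries.sort(key=lambda e: (-e.cv, e.partner_id))
        for e in entries[:top_k]:
            kept.add(frozenset((anchor, e.partner_id)))
    return [p for p in pairs if frozenset(p.genes) in kept]


def qualify_pairs(
    pairs: Sequence[OrientedPair], ranks_tumor: RankMatrix, qualify_frac: float
) -> List[OrientedPair]:
    """Retain pairs whose tumor orientation holds in strictly more than
    ``qualify_frac`` of tumor samples (support recomputed from the ranks)."""
    out = []
    for p in pairs:
        support = pair_support(ranks_tumor, p)
        if support > qualify_frac:
            out.append(replace(p, support_tumor=support))
    return out


def encode_pairs(source, pairs: Sequence[OrientedPair]) -> PairIndicatorMatrix:
    """Binary encoding: 1 iff the pair's stated orientation holds strictly
    (ties encode as 0). ``source`` is an ExpressionCohort or RankMatrix."""
    if isinstance(source, ExpressionCohort):
        mat, columns = source.values, source.sample_ids
    elif isinstance(source, RankMatrix):
        mat, columns = source.ranks, source.sample_ids
    else:
        raise TypeError("source must be an ExpressionCohort or RankMatrix")
    rows, labels = [], []
    for p in pairs:
        for g in p.genes:
            if g not in mat.index:
                raise ValidationError(f"gene {g!r} required by pair encoding is missing")
        va = mat.loc[p.gene_a].to_numpy()
        vb = mat.loc[p.gene_b].to_numpy()
        hit = (va > vb) if p.orientation == A_GT_B else (va < vb)
        rows.append(hit.astype(np.int8))
        labels.append(f"{p.gene_a}|{p.gene_b}")
    ind = pd.DataFrame(np.asarray(rows), index=labels, columns=columns)
    return PairIndicatorMatrix(list(pairs), ind)


def enumerate_pairs(gene_ids: Sequence[str]) -> List[tuple]:
    """All n(n-1)/2 unordered pairs in canonical (sorted) order."""
    ids = sorted(set(gene_ids))
    if len(ids) != len(gene_ids):
        raise ValidationError("gene ids must be unique")
    if len(ids) < 2:
        raise ValidationError("need at least two genes to form pairs")
    return list(itertools.combinations(ids, 2))


def intersect_pair_sets(pair_sets: Sequence[Sequence[OrientedPair]]) -> List[OrientedPair]:
    """Pairs present in every set with identical orientation.

    Supports on the returned pairs are those of the first set.
    """
    if len(pair_sets) < 2:
        raise ValidationError("need at least two pair sets to intersect")
    keys = set.intersection(*({p.key for p in ps} for ps in pair_sets))
    return [p for p in pair_sets[0] if p.key in keys]
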