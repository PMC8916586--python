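"""End-to-end multi-cohort orchestration.

Wires the stages together: pathway-coupled lncRNA discovery on the
training cohort, per-cohort stable/reversal pair detection with direction,
CV and qualification filters, cross-cohort intersection, binary encoding,
univariate Cox screens with direction consistency, LASSO Cox fitting on
the training cohort, per-cohort risk scores, cutoffs and groups, and
evaluation reports. A manifest records config, seed, and input digests so
reruns are reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import enrichment, evaluate, pairs as pairmod, signature as sigmod
from .config import PipelineConfig
from .io import (
    ExpressionCohort,
    GeneSet,
    SurvivalTable,
    ValidationError,
    write_model,
    write_pairs,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunManifest:
    config: dict
    seed: int
    input_digests: Dict[str, str]
    stages: List[dict] = field(default_factory=list)
    outputs: Dict[str, str] = field(default_factory=dict)

    def record(self, stage: str, **info) -> None:
        self.stages.append({"stage": stage, "timestamp": _time.time(), **info})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)
            fh.write("\n")


@dataclass
class PipelineResult:
    manifest: RunManifest
    pes_results: list
    pdl_ids: List[str]
    reversal_sets: Dict[str, list]
    common_pairs: list
    final_pairs: list
    model: sigmod.SignatureModel
    scores: Dict[str, sigmod.RiskScoreVector]
    cutoffs: Dict[str, float]
    reports: Dict[str, evaluate.EvaluationReport]


def _digest(cohort: ExpressionCohort) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(cohort.values.to_numpy()).tobytes())
    h.update(",".join(cohort.sample_ids).encode())
    return h.hexdigest()[:16]


def _cohort_pair_set(
    cohort: ExpressionCohort,
    pdl_ids: Sequence[str],
    cfg: PipelineConfig,
) -> list:
    """Stable -> reversal -> same-direction -> CV-pruned -> qualified pairs
    for one cohort, over the pathway-derived lncRNA pair universe.

    Ranks for pair comparisons use the PDL subset; deregulation directions
    and partner CVs are computed on ranks over the full lncRNA field.
    """
    if not len(cohort.normal_samples):
        raise ValidationError(f"cohort {cohort.cohort_id!r} has no normal samples")
    all_lnc = list(cohort.lncrna_ids)
    ranks_norm_all = pairmod.rank_transform(cohort, all_lnc, sample_group="normal")
    ranks_tum_all = pairmod.rank_transform(cohort, all_lnc, sample_group="tumor")
    pdl_list = [g for g in pdl_ids if g in cohort.gene_ids]
    ranks_norm = pairmod.RankMatrix(ranks_norm_all.ranks.loc[pdl_list])
    ranks_tum = pairmod.RankMatrix(ranks_tum_all.ranks.loc[pdl_list])

    stable = pairmod.find_stable_pairs(
        ranks_norm, cfg.stable_frac, min_normal_samples=cfg.min_normal_samples
    )
    if not stable:
        return []
    reversal = pairmod.find_reversal_pairs(ranks_tum, stable, cfg.reversal_frac)
    if not reversal:
        return []
    directions = pairmod.deregulation_directions(ranks_tum_all, ranks_norm_all)
    same_dir = pairmod.filter_same_direction(reversal, directions)
    pruned = pairmod.partner_cv_prune(same_dir, ranks_tum_all, cfg.top_cv_partners)
    return pairmod.qualify_pairs(pruned, ranks_tum, cfg.qualify_frac)


def run_full_pipeline(
    cohorts: Sequence[ExpressionCohort],
    survivals: Sequence[SurvivalTable],
    gene_set: GeneSet,
    cfg: Optional[PipelineConfig] = None,
    training_cohort: Optional[str] = None,
    outdir: Optional[str] = None,
    fixed_cutoff: bool = False,
) -> PipelineResult:
    """Run the full multi-cohort analysis.

    ``training_cohort`` defaults to the first cohort. With
    ``fixed_cutoff=True`` the training cutoff is transferred to validation
    cohorts instead of being re-estimated per cohort.
    """
    cfg = cfg or PipelineConfig()
    if len(cohorts) != len(survivals):
        raise ValidationError("need one survival table per cohort")
    by_id = {c.cohort_id: c for c in cohorts}
    surv_by_id = {c.cohort_id: s for c, s in zip(cohorts, survivals)}
    training_cohort = training_cohort or cohorts[0].cohort_id
    if training_cohort not in by_id:
        raise ValidationError(f"unknown training cohort {training_cohort!r}")

    manifest = RunManifest(
        config=cfg.to_dict(),
        seed=cfg.rng_seed,
        input_digests={c.cohort_id: _digest(c) for c in cohorts},
    )

    def _stage(name, fn, *args, **kwargs):
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:  # annotate with the stage name, keep partials
            raise StageError(name, exc) from exc
        manifest.record(name)
        return out

    # 1. pathway-coupled lncRNA discovery (training cohort)
    pes_results = _stage(
        "identify_pdls", enrichment.identify_pdls, by_id[training_cohort], gene_set, cfg
    )
    pdls = enrichment.pdl_ids(pes_results)
    if len(pdls) < 2:
        raise StageError(
            "identify_pdls",
            ValidationError(f"found {len(pdls)} pathway-coupled lncRNAs; need >= 2"),
        )
    manifest.record("pdl_universe", n_pdls=len(pdls))

    # 2. per-cohort pair pipeline and cross-cohort intersection
    reversal_sets = {
        c.cohort_id: _stage(f"pair_pipeline[{c.cohort_id}]", _cohort_pair_set, c, pdls, cfg)
        for c in cohorts
    }
    if len(cohorts) > 1:
        common = _stage(
            "intersect_pair_sets", pairmod.intersect_pair_sets, list(reversal_sets.values())
        )
    else:
        common = list(reversal_sets[training_cohort])
    if not common:
        raise StageError(
            "intersect_pair_sets", ValidationError("no pairs shared across cohorts")
        )
    manifest.record("common_pairs", n_pairs=len(common))

    # 3. encoding and univariate screens per cohort (tumor samples)
    indicators = {}
    screens = {}
    for c in cohorts:
        tum = c.subset(samples=c.tumor_samples)
        ind = _stage(f"encode[{c.cohort_id}]", pairmod.encode_pairs, tum, common)
        indicators[c.cohort_id] = ind
        screens[c.cohort_id] = _stage(
            f"cox_screen[{c.cohort_id}]",
            sigmod.univariate_cox_screen,
            ind,
            surv_by_id[c.cohort_id],
        )

    # 4. consistent pairs + LASSO Cox on the training cohort
    final_pairs = _stage(
        "select_consistent_pairs", sigmod.select_consistent_pairs, screens, training_cohort, cfg
    )
    if len(final_pairs) < 2:
        raise StageError(
            "select_consistent_pairs",
            ValidationError(f"only {len(final_pairs)} consistent pairs; LASSO needs >= 2"),
        )
    train_ind = pairmod.encode_pairs(
        by_id[training_cohort].subset(samples=by_id[training_cohort].tumor_samples),
        final_pairs,
    )
    model = _stage(
        "fit_lasso_cox",
        sigmod.fit_lasso_cox,
        train_ind,
        surv_by_id[training_cohort],
        cfg,
        training_cohort,
    )

    # 5. scores, cutoffs, groups, evaluation per cohort
    scores: Dict[str, sigmod.RiskScoreVector] = {}
    cutoffs: Dict[str, float] = {}
    reports: Dict[str, evaluate.EvaluationReport] = {}
    train_cutoff: Optional[float] = None
    ordered = [training_cohort] + [c.cohort_id for c in cohorts if c.cohort_id != training_cohort]
    for cid in ordered:
        sc = _stage(
            f"risk_score[{cid}]", sigmod.risk_score, model, indicators[cid]
        )
        if fixed_cutoff and train_cutoff is not None:
            cut = train_cutoff
        else:
            cut = _stage(
                f"optimal_cutoff[{cid}]",
                sigmod.optimal_cutoff,
                sc,
                surv_by_id[cid],
                cfg.min_group_frac,
            )
        if cid == training_cohort:
            train_cutoff = cut
            model.cutoff = cut
        grouped = sigmod.assign_groups(sc, cut)
        scores[cid] = grouped
        cutoffs[cid] = cut
        reports[cid] = _stage(
            f"evaluate[{cid}]",
            evaluate.evaluate_cohort,
            cid,
            grouped,
            surv_by_id[cid],
            cfg.auc_years,
            None,
            cfg.n_bootstrap,
            cfg.rng_seed,
        )

    # 6. optional file outputs
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_pairs(common, out / "common_pairs.tsv")
        write_model(model, out / "model.json")
        for cid, rep in reports.items():
            rep.to_json(out / f"report_{cid}.json")
            manifest.outputs[f"report_{cid}"] = str(out / f"report_{cid}.json")
        manifest.outputs["model"] = str(out / "model.json")
        manifest.outputs["common_pairs"] = str(out / "common_pairs.tsv")
        manifest.to_json(out / "manifest.json")

    return PipelineResult(
        manifest=manifest,
        pes_results=pes_results,
        pdl_ids=pdls,
        reversal_sets=reversal_sets,
        common_pairs=common,
        final_pairs=final_pairs,
        model=model,
        scores=scores,
        cutoffs=cutoffs,
        reports=reports,
    )
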