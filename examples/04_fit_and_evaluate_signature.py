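"""Fit a LASSO Cox pair signature on the training cohort and evaluate it.

Candidate pairs pass a univariate Cox screen (p < 0.05 in training, hazard
direction consistent across cohorts), then an L1-penalized Cox model with
10-fold cross-validated partial-likelihood deviance selects the final
pairs. Patients are split at the maximally selected log-rank cutpoint and
the model is evaluated by log-rank test, 1/3/5-year AUC and Harrell's C.
"""

import lncpairs as lp

sim_cfg = lp.SimulationConfig()
cohorts, survivals, truth = lp.simulate_cohorts(sim_cfg, seed=1)
cfg = lp.PipelineConfig(rng_seed=1, n_bootstrap=500)

result = lp.run_full_pipeline(cohorts, survivals, lp.pathway_gene_set(sim_cfg), cfg)

print(f"pathway-coupled lncRNAs: {len(result.pdl_ids)}")
print(f"cross-cohort reversal pairs: {len(result.common_pairs)}")
print(f"screened, direction-consistent pairs: {len(result.final_pairs)}\n")

print("fitted signature (pair, coefficient):")
for pair, coef in zip(result.model.pairs, result.model.coefficients):
    print(f"  {pair.gene_a} vs {pair.gene_b}: {coef:+.4f}")
print(f"lambda* = {result.model.lasso_lambda:.4f}, "
      f"training cutoff = {result.model.cutoff:.4f}\n")

for cid, rep in result.reports.items():
    aucs = ", ".join(f"{int(y)}y {a:.3f}" for y, a in rep.auc_by_year.items())
    lo, hi = rep.c_index_ci
    print(f"{cid}: log-rank p {rep.km_logrank_p:.2e}; AUC {aucs}; "
          f"C-index {rep.c_index:.3f} (95% CI {lo:.3f}-{hi:.3f})")
# A C-index above 0.5 with a small log-rank p in the two validation cohorts
# shows the rank-pair signature transfers across simulated platforms.
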