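# Methods

This note documents the statistical procedures implemented in `lncpairs`,
the design choices made where the methodology is genuinely open, the
synthetic-data generator's construction, and the package's limitations.

## Enrichment-based lncRNA discovery

For lncRNA ℓ, all mRNAs are ranked in descending order of correlation with
ℓ across tumor samples. Spearman correlation is the default: it makes the
ranking — and with it the whole pipeline — invariant under strictly
increasing per-sample transforms; Pearson is available by flag. Zero-variance
lncRNAs cannot be ranked and raise an error (inside `identify_pdls` they are
assigned ES 0, p 1). Zero-variance mRNAs receive correlation 0. Ties in
correlation are broken lexicographically by gene id so orderings are
deterministic.

The enrichment score is the classic weighted Kolmogorov–Smirnov running
sum: walking the ranked list, a pathway gene ("hit") increments the sum by
|r|^w normalized by the total hit weight, any other gene decrements it by
1/(N − N_h); ES is the signed extreme deviation and lies in [−1, 1]. The
weight exponent defaults to w = 1, the convention of the standard GSEA
implementations. The score is the raw ES, not a normalized NES: the
operative threshold |ES| > 0.995 only makes sense on a statistic bounded
by 1.

Significance is assessed per lncRNA against a null of random gene sets of
the same size drawn without replacement from the ranked universe
(`n_permutations` = 999 by default), two-sided on |ES| with the add-one
estimator p = (1 + #{|ES_null| ≥ |ES_obs|}) / (n_perm + 1), so p is never
zero and is exactly uniform on its support under the null. Permutation
streams are keyed to the lncRNA's sorted identifier, making results
invariant to the row order of the input matrix. q-values are
Benjamini–Hochberg across all lncRNAs; BH is implemented in-package (a
ten-line step-up) and cross-checked against `statsmodels` in the tests.

## The pair pipeline

Expression is converted to within-sample (column-wise) ranks, average rank
for ties. Pair detection only uses the order of the two genes involved, so
it is indifferent to whether ranks are computed over the lncRNA field or
the pathway-derived subset; deregulation directions and partner CVs are
computed on ranks over **all** lncRNAs (the gene's standing in the full
field), while pair support uses the pathway-derived subset.

* **Stable pairs**: one ordering in ≥ `stable_frac` (default 0.85) of
  normal samples. The threshold is inclusive (the rule is "in 85% of
  samples"). Within-sample ties count toward neither orientation. At
  least `min_normal_samples` (default 5) normals are required.
* **Reversal pairs**: the subset of stable pairs whose *opposite*
  ordering holds in ≥ `reversal_frac` (default 0.85) of tumors; the
  output carries the tumor orientation.
* **Direction filter**: a gene's deregulation direction is the sign of
  the change in its median within-sample rank between tumors and normals;
  pairs whose members disagree (or include an "unchanged" member) are
  dropped.
* **CV pruning**: for each anchor gene, partners are ranked by the
  coefficient of variation (sd/|mean|, sample sd) of the per-sample rank
  difference rank(anchor) − rank(partner) over tumors, descending, ties
  broken by partner id; the top `top_cv_partners` (default 3) per anchor
  survive, and a pair is kept if retained from either side. A zero mean
  difference maps to CV = +∞ (maximal variability). The quantity whose CV
  is taken is not fully pinned down by the originating methodology; this
  choice captures per-tumor heterogeneity of the pair relationship, which
  is the stated purpose of the step.
* **Qualification**: tumor support of the stored orientation is
  recomputed and must exceed `qualify_frac` (default 0.60) *strictly*
  ("more than 60%"). With default thresholds this is implied by the
  reversal rule; both knobs are kept independent because the procedure
  treats them as separate steps.
* **Encoding**: the binary indicator is 1 iff the pair's stated tumor
  orientation holds strictly in a sample; ties encode 0. Pairs are stored
  canonically (gene_a < gene_b lexicographically) with an orientation
  flag, which carries the conventional relabeling "lncRNA-A = the gene
  greater in tumors".

Cross-cohort harmonization happens only at the intersection step: a pair
must appear in every cohort's qualified set with the same tumor
orientation. Each cohort's own normals anchor its stable pairs.

## Signature model

The univariate screen fits one Cox proportional-hazards model per pair
(lifelines, Efron tie handling) and reports Wald p and 95% CI. Constant
indicators are skipped with a warning; at least 10 events are required.
Selection requires p < `cox_p_threshold` (default 0.05) in the training
cohort — demanding it in all cohorts is a config option
(`require_p_all_cohorts`), as the originating description supports either
reading — plus an identical sign of log HR in every cohort (HR = 1
anywhere excludes).

The LASSO Cox model uses the coxnet path (scikit-survival, 100 λ values,
`alpha_min_ratio` 1e-4). λ* minimizes the k-fold (default 10)
cross-validated partial-likelihood deviance in the Verweij–Van Houwelingen
form, dev_k(λ) = −2·[ℓ(all; β_k(λ)) − ℓ(train_k; β_k(λ))], with a Breslow
partial log-likelihood computed in-package. Folds are stratified by event
status and seeded from `rng_seed`; λ at the minimum (not the 1-SE rule) is
used, matching the stated rule of the original procedure. Pairs with
non-zero coefficients at λ* constitute the signature; the risk score is
the plain linear combination with no intercept.

The cutpoint is the maximally selected log-rank statistic: every midpoint
of sorted unique scores leaving ≥ `min_group_frac` (default 10%) of
samples per side is scored by a two-group log-rank chi-square (vectorized
in-package; lifelines is the oracle in tests) and the maximizer is
returned, ties resolved toward the lower cutoff. Pair-indicator scores are
heavily discrete — a k-pair signature takes at most 2^k values, with mass
concentrated because reversal indicators are majority-one — so a cohort
may admit no split meeting the floor; the implementation then falls back
to the least imbalanced candidate splits (warning logged) so that both
groups are always non-empty. Group assignment is high ⇔ score > cutoff
(strict). No multiplicity correction is applied to the downstream log-rank
p for having optimized the cutpoint; this matches common practice and is a
known limitation. Validation cohorts re-estimate their own cutoff by
default; `fixed_cutoff=True` transfers the training cutoff instead — the
original procedure is ambiguous between the two, so both are provided.

## Evaluation

* **KM/log-rank**: lifelines product-limit curves and the two-group
  log-rank test.
* **Time-dependent AUC**: the cumulative/dynamic estimator with IPCW
  censoring adjustment (scikit-survival). Under zero censoring it reduces
  exactly (to 1e-10, ties included) to the Mann–Whitney AUC of the binary
  outcome "event by t"; the tests assert this reduction. Horizons are
  supplied in years; 1 year = 365.25 days throughout.
* **Concordance**: Harrell's C over usable pairs (scikit-survival), CI by
  seeded percentile bootstrap (default 2000 draws). The estimator was
  validated against exhaustive pair enumeration for n ≤ 30.
* **Calibration**: a one-covariate Cox model on the score (Breslow
  baseline) predicts survival at the horizon; samples are binned into
  equal-size score bins (tertiles by default) and mean predicted is
  compared with KM-observed survival per bin. A constant score collapses
  to the marginal KM; degenerate bins are merged with a warning.
* **Two-group comparisons**: Wilcoxon rank-sum (exact when both groups
  ≤ 50 without ties, otherwise normal approximation with continuity
  correction) and Fisher's exact test; 2×2 via scipy, 2×k (k > 2) by
  in-package enumeration of all tables with the observed margins under
  the multivariate hypergeometric null.

## Synthetic cohort generator

The generator emulates a three-cohort tumor/normal study with planted
ground truth. Defaults are the study conditions used throughout the tests:
cohort totals 348 / 300 / 191 (tumor/normal 300/48, 260/40, 160/31), a
51-gene pathway set among 300 mRNAs, 80 lncRNAs of which 16 are
pathway-coupled, 4 planted reversal pairs, ~50% censoring, exponential
event times with baseline hazard ln2/730 per day (median survival two
years in the low-risk state), and per-pair log-hazard coefficients of
magnitude 0.7–1.4 with random signs.

Construction, on a log2 intensity scale with i.i.d. Gaussian noise
(`noise_sd` = 0.6):

* A latent pathway activity z ~ N(0,1) per sample; pathway mRNAs and all
  coupled lncRNAs load on z with loading 1.2·`coupling_strength`. The
  shared loading makes z cancel in within-pair differences, so pair
  support fractions depend only on the baseline geometry and `noise_sd`.
* Planted pair p occupies a band centered at c_p: in normals member A
  sits at c_p − 0.8 and member B at c_p + 0.8, so P(A < B) =
  Φ(1.6/(0.6·√2)) ≈ 0.97. In tumors both members rise — B by 1.0, A to
  1.1 above B — giving P(A > B) = Φ(1.1/(0.6·√2)) ≈ 0.90. Both members
  therefore gain rank against the static null-lncRNA field (direction
  "up" for both), while their mutual ordering flips. The ~10% of tumors
  without the reversal are the informative minority that carries the
  survival signal — an unavoidable feature of any reversal rule at 85%,
  which forces indicators to be majority-one.
* Band centers are spaced 1.8 apart. A cross-pair combination (A_p, B_q)
  changes ordering between normals and tumors only if the center gap lies
  in (−2·0.55, 2·0.8) = (−1.1, 1.6); spacing 1.8 keeps every cross-pair
  gap outside this window, so no non-planted pair flips even in the
  noiseless limit, and with noise the near-boundary combinations are far
  from the 0.85 stability threshold. Non-planted coupled lncRNAs sit in a
  disjoint band below the planted ones (they are crossed by nothing);
  null lncRNAs and mRNAs draw static baselines uniform on [6, 15] and
  [6, 14].
* Tumor event times are Weibull (shape 1 = exponential by default) with
  rate `baseline_hazard`·exp(Σ_p β_p x_ps), x_ps the realized indicator.
  Censoring is uniform on (0, u] with u solved by bisection so that the
  expected censoring fraction E[(1 − e^{−λu})/(λu)] averaged over samples
  hits `censoring_rate_target`; the empirical fraction lands within ±0.05
  for n ≥ 200.
* Each cohort's matrix finally passes through its own strictly increasing
  transform (identity, affine, power 1.3) emulating platform differences.
  An optional per-gene `rank_noise_rate` (default 0) scrambles a fraction
  of genes across samples to model rank-breaking probe artifacts; it is
  off by default so that REO-invariance properties are exact.

All randomness derives from a single seed through named `SeedSequence`
substreams (per stage and cohort), so identical (config, seed) inputs are
bitwise reproducible. Values are floored at 1e-3 to guard the ~1e-6
Gaussian tail that would otherwise produce a negative intensity.

What the generator does **not** emulate: correlated gene-gene structure
beyond the single pathway factor, heavy-tailed or count-based expression
noise, batch effects that are not monotone within a sample, missing
values, or competing risks. Passing tests on this generator certifies the
machinery (rank logic, invariances, estimator calibration, recovery under
a correctly specified hazard), not performance on real tumor data.

## Problem sizes used in the test suite

Unit tests run on scaled-down cohorts (40 lncRNAs / 120 mRNAs, cohorts of
~110–150 tumors) chosen so that each planted effect remains comfortably
detectable at the smaller n; the acceptance-level suites use the default
study conditions for planted-structure recovery (50 seeds), 1000-replicate
calibration suites for the permutation p and the univariate Cox screen,
and 50 replicates for LASSO sign recovery at n = 400 with 3 informative
among 23 pairs.

## Known limitations

* The direction filter depends on median ranks over the full lncRNA
  field; genes at the extreme top of the dynamic range cannot rise
  further and may be scored "unchanged", dropping otherwise valid pairs.
* The optimized cutpoint's log-rank p is not corrected for the maximal
  selection.
* The permutation null randomizes gene sets, not samples; coexpression
  within the pathway set is therefore not reflected in the null.
* Fisher's exact enumeration for 2×k tables is exponential in k and
  intended for small clinical contingency tables.
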