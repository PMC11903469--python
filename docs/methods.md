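# Methods

This note documents the models, numerical procedures and design choices
behind `gesig`, and what the synthetic-cohort experiments do and do not
establish about behavior on real data.

## Discovery model

For each endpoint (DOR, EFS, PFS) we maximize the elastic-net penalized
Breslow log partial likelihood

    log PL(β) − α ( r Σ_j |β_j| + (1 − r)/2 Σ_j β_j² ),      r = 0.9,

over standardized gene expression (per-gene mean 0, variance 1 with
denominator n, computed on the endpoint's eligible samples). The penalty is
applied to the likelihood itself, not the likelihood divided by n; the
scikit-survival/glmnet convention maps onto ours via α_ours = n · α_glmnet.
Coefficients are reported on both the standardized and the original
expression scale (β_raw = β / sd).

Assumptions inherited from the Cox model: proportional hazards per gene,
log-linear effects of (standardized) expression on the hazard, and
non-informative censoring. Ties are handled with the Breslow approximation
throughout — it is the convention of the penalized-Cox lineage and the
variant that our brute-force oracles evaluate exactly. Efron ties,
stratified and time-varying models are out of scope.

### Solver

The optimizer is proximal Newton on an active set:

1. At the current β, build the exact second-order expansion of the Breslow
   partial likelihood (gradient `g = Xᵀ(e − μ)` and Hessian
   `H = Σ_k d_k [S2_k/S0_k − (S1_k/S0_k)(S1_k/S0_k)ᵀ]`, computed in
   O(n·p_active²) via reverse cumulative sums over the sorted risk sets).
2. Solve the penalized quadratic subproblem restricted to the active set by
   cyclic coordinate descent with soft-thresholding (numba-compiled kernel;
   a pure-Python fallback runs when numba is absent).
3. Step-halve toward the previous iterate whenever the true penalized
   objective would decrease (slack 1e−10 relative), making the objective
   trajectory monotone by construction.
4. Sweep the KKT conditions over all features and admit violators into the
   active set; convergence requires a max coefficient change below `tol`
   (default 1e−7) *and* an empty violator set.

An earlier implementation used the conventional diagonal-weight IRLS
surrogate; its linear contraction (~0.75 per iteration on correlated
designs) made the honest 1e−7 coefficient criterion needlessly expensive,
while the exact-Hessian subproblem converges quadratically in a handful of
outer iterations and passes the same oracle and KKT checks. `max_iter`
(default 1e5) caps total coordinate sweeps; hitting it returns a fit flagged
non-converged with a warning.

The α grid is log-spaced over `[α_max·ratio_min, α_max]` with
`α_max = max_j |score_j(0)| / r` (so the first grid point yields the all-zero
solution); defaults n_alphas = 100, ratio_min = 0.01. The desk-scale
analyses and the acceptance script use shorter paths (n_alphas = 20–30,
ratio_min = 0.02–0.05), which we found indistinguishable for selection
purposes at these problem sizes.

### Cross-validation

α is selected by fivefold cross-validation on Harrell's C-index of the
held-out linear predictor, folds assigned by a seeded shuffle stratified on
the event indicator (refolded with an offset seed, up to 10 times, if a
training fold would contain no events). The criterion is the mean of
per-fold C values — per-fold averaging is fold-exchangeable and directly
verifiable, and is recorded in the CV result together with the fold
assignment. The default rule picks the α attaining the maximal mean C with
ties resolved toward the larger α (sparser model). A `selection="1se"`
option implements the usual one-standard-error rule. Note a structural
fact we document rather than hide: on signal-free data the held-out C at
α_max is exactly 0.5 (constant predictor), while the maximum over a path of
noisy C estimates exceeds 0.5 in most replicates, so *any* max-type rule —
including 1-SE — selects a non-trivial model on pure noise in a
non-negligible fraction of replicates. The pipeline's protection against
hallucinated signatures is therefore not the per-endpoint fit but the
sign-consistent intersection across the three endpoints (see below).

### Signatures

Per endpoint, the model is refit at the CV-selected α on the full eligible
subset ("cv-then-refit"); transcripts with β < 0 are favorable, β > 0
unfavorable, exact zeros excluded. The favorable signature is the
intersection of the three per-endpoint favorable lists (likewise
unfavorable). DOR models are fit on responders only (DOR is undefined
otherwise); EFS/PFS use all samples with endpoint data. Discovery is run on
the treated arm's pretreatment samples; evaluation may target any arm.
Modeling consumes linear normalized counts by default; an opt-in
`log_transform` flag applies log2(x+1) before standardization.

## Scoring and stratification

A signature score is the mean of per-gene z-scores with gene means and
standard deviations (denominator n − 1; recorded in the output so the
alternative is a one-flag change) computed over *all* samples passed to the
scorer — the scoring population, which every result records as a scope
note. For the main evaluations the scoring population pools both arms'
pretreatment samples; for the progression comparison it pools pretreatment
and at-progression samples. Scores are mean-zero over their scoring
population by construction (asserted to 1e−10).

Median split: score > median → "high", score ≤ median → "low". When results
are subgrouped (e.g. by cell of origin), the median and the gene means/SDs
always come from the entire dataset, never per subgroup.

## Survival statistics

All statistics are implemented from their defining formulas:

- Kaplan–Meier product-limit curves; at a tied time, events precede
  censorings (a subject censored at t remains at risk for events at t).
- Two-group unweighted (Mantel–Haenszel) log-rank with hypergeometric
  variance; p from χ²(1).
- Unstratified two-group Cox HR via Newton–Raphson on the one-covariate
  Breslow partial likelihood; Wald 95% CI with z = 1.959964. Monotone
  likelihood (score bounded away from zero, |β| escaping) is reported as a
  diverged fit with no numeric CI rather than a huge spurious HR.
- Harrell's C over usable pairs (the earlier time is an observed event);
  predictor ties count 0.5; time-tied pairs are unused; no IPCW correction.
- Per-gene univariate screens in median-split (> median = high) or
  continuous (standardized expression) mode; zero-variance genes are
  skipped and listed.
- Spearman's ρ as Pearson correlation of mid-ranks; exact permutation p for
  n ≤ 10, t-approximation on n − 2 df above.
- Wilcoxon rank-sum: exact enumeration of group assignments (symmetric
  null, mid-ranks) when n_x + n_y ≤ 12 without ties, otherwise the
  tie-corrected normal approximation with continuity correction; two-sided.

No multiplicity adjustment is applied anywhere, by design.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
any assay chemistry:

- **Expression**: per-gene log-normal values, log-scale locations uniform on
  [log 20, log 2000] and dispersions uniform on [0.3, 0.8] (spanning the
  dynamic range of normalized linear counts); genes inside each planted
  program share a latent pairwise correlation (`block_correlation`, default
  0.3); background genes are independent. A `panel_seed` lets two sample
  sets (e.g. pretreatment and at-progression) share the same gene panel.
- **Outcomes**: exponential event times with hazard
  `h0_e · exp(Σ_j β_j z_j)` on standardized log-expression of the planted
  genes, so proportional hazards hold exactly and configured effects are
  scale-free. Defaults: 5 protective genes at β = −0.8, 5 hazardous at
  +0.8, baseline hazard ln2/180 per day (180-day median at lp = 0), EFS
  hazard inflated 1.25× over PFS (EFS events are a superset of
  progressions), independent exponential censoring at 1/600 per day (~70%
  events).
- **Endpoint coupling** uses a Gaussian copula on the event-time quantiles
  with correlation `endpoint_coupling` (default 0.9): endpoints are
  independent at 0, share their quantile (identical per-sample ranking) at
  1, and every marginal stays exactly exponential at any coupling. We chose
  the copula over a shared gamma frailty because only the copula satisfies
  the coupling = 1 degenerate case exactly while keeping exponential
  marginals and proportional hazards.
- **Response**: responder flags are Bernoulli with probability
  logistic(logit(responder_fraction) − 0.5·z_unfavorable), a weak
  anti-correlation with the hazardous program; DOR exists only for
  responders (default responder fraction 0.8).
- **Arms**: an optional comparator arm (`soc_fraction`) whose planted
  effects are scaled by `soc_effect_multiplier` (0 = purely predictive
  signal, 1 = equally prognostic).
- Defaults target the study scale: 134 samples, 200-gene panel.

What the generator does **not** emulate: batch effects, probe chemistry or
normalization artifacts, gene–gene correlation outside the planted blocks,
non-proportional hazards, informative censoring, or treatment-mechanism
differences beyond the arm effect multiplier. Passing tests therefore show
the pipeline is correct and well calibrated under its own assumptions; they
do not show robustness to violations of those assumptions in real cohorts.

## Cohort handling

Expression and clinical TSVs are validated strictly (unique ids, finite
non-negative values, times > 0, events in {0,1}); DOR fields are forced
unavailable for non-responders regardless of file content; dates must be
ISO-8601 to avoid locale ambiguity. Sample QC keeps samples with coding-read
fraction strictly greater than 0.10 (the rule removes "≤ 10%") and leaves
samples without the metric untouched. Duplicate pretreatment samples per
subject resolve to the latest collection date, then the lower molecular
batch id; a full tie is fatal rather than silently arbitrary, and the rule
is applied uniformly to both arms. Progression samples are never
deduplicated against pretreatment ones.

## Problem sizes and determinism

The test suite and acceptance script run at desk scale, chosen to finish
comfortably on one CPU while keeping the statistical checks meaningful:
planted-recovery at n = 400 samples × 200 genes over 20 seeds (~70 s),
null calibration over 200 replicates of n = 100 × 30 (~10 s), the arm
contrast over 6 replicates of n = 500 × 100, and solver-oracle agreement on
instances small enough for exhaustive grid search. Every stochastic step
takes an explicit seed; a discovery/evaluation run is byte-identical across
replays given the same cohort, configuration and seed, and full runs write
a manifest (inputs, digests, settings, seed, package version) for replay.

## Known limitations

- Breslow-only ties; no Efron option.
- Harrell's C without IPCW, so heavy censoring biases C toward optimism in
  all arms equally; it is used only for model selection, not reported as an
  estimate of discrimination.
- The per-endpoint CV-selected models deliberately over-select (the C-index
  optimum is dense); interpretability rests on the cross-endpoint
  intersection, and single-endpoint transcript lists should not be read as
  signatures.
- On signal-free data the discovery intersection is near-empty only when
  the endpoints carry independent noise; strongly coupled endpoints can
  propagate the same false selections across all three fits, so small
  intersections on real data (where endpoints are highly correlated) are
  weaker evidence than the independent-endpoint null suggests.
- Exact numeric replication of third-significant-figure hazard ratios from
  other software may differ with tie corrections or CI variants.
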