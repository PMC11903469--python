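# gesig — tumor gene-expression signatures for CAR T-cell outcome

`gesig` re-implements, as a tested and reusable pipeline, the discovery and
evaluation of tumor gene-expression signatures (GES) associated with outcome
after CD19-directed CAR T-cell therapy (axicabtagene ciloleucel) in
relapsed/refractory large B-cell lymphoma. It is aimed at computational
biologists and biostatisticians who want to run, audit, or stress-test this
class of analysis: penalized multivariate survival modeling over a gene
panel, cross-endpoint signature derivation, signature scoring, and
median-split survival stratification.

## The method

Given a normalized expression matrix (NanoString normalized linear counts or
linear TPM; genes × samples) and per-sample censored endpoints — duration of
response (DOR, responders only), event-free survival (EFS) and
progression-free survival (PFS) — the pipeline:

1. **Fits an elastic-net penalized Cox model per endpoint**, maximizing

   ```
   log PL(β) − α ( r Σ_j |β_j| + (1−r)/2 Σ_j β_j² )
   ```

   with mixing `r = 0.9`, Breslow tie handling, genes standardized to mean 0
   and unit variance, and `α` chosen by fivefold cross-validation on
   Harrell's concordance index (C-index). The solver is proximal Newton
   with an exact Hessian on an active set; the penalized subproblem is
   solved by cyclic coordinate descent with soft-thresholding.

2. **Intersects the selected transcripts across endpoints by sign**:
   transcripts with negative coefficients (HR < 1) for *all three* endpoints
   form the favorable signature; positive ones (HR > 1) the unfavorable
   signature.

3. **Scores each signature per sample** as the mean of z-scored expression,

   ```
   score_s = (1/m) Σ_i (Count_is − u_i) / σ_i
   ```

   with gene means `u_i` and standard deviations `σ_i` computed over all
   samples of the scoring population.

4. **Stratifies by the median** (score > median → "high", ≤ median → "low";
   for subgroup analyses the median always comes from the entire dataset)
   and compares groups with Kaplan–Meier curves, the log-rank test and an
   unstratified two-group Cox hazard ratio with Wald 95% CI. Per-gene
   univariate Cox screens, two-signature cross-classification,
   cell-of-origin subgroup analyses, Spearman correlation and pre- versus
   at-progression Wilcoxon comparisons round out the reported statistics.

All survival and rank statistics are implemented from their defining
formulas in `gesig.survstats` (lifelines / scikit-survival / scipy serve as
independent cross-checks in the test suite), so every reported number is
traceable.

A synthetic cohort generator (`gesig.simulate`) plants known favorable and
unfavorable gene programs acting log-linearly on exponential hazards of
three coupled endpoints, so the entire pipeline is testable end-to-end
without any data download.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
cohort (400 pretreatment samples, 200 genes, 5 planted protective + 5
planted hazardous genes at |β| = 0.8, effects confined to the treated arm):

```
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_discover_signatures.py --seed 1
python analysis/03_evaluate_signatures.py
python analysis/04_univariate_screen.py
python analysis/05_combined_and_subgroups.py
python analysis/06_progression_shift.py
```

Discovery (script 02) prints:

```
discovery population: 240 treated pretreatment samples
  DOR: alpha=14.3, held-out C=0.901, selected 19 favorable / 8 unfavorable transcripts
  EFS: alpha=16, held-out C=0.908, selected 17 favorable / 9 unfavorable transcripts
  PFS: alpha=19.2, held-out C=0.912, selected 8 favorable / 5 unfavorable transcripts
favorable intersection (5): ['FAV001', 'FAV002', 'FAV003', 'FAV004', 'FAV005']
unfavorable intersection (5): ['UNF001', 'UNF002', 'UNF003', 'UNF004', 'UNF005']
recovered 5/5 planted protective genes with 0 false positives
```

Each per-endpoint model selects more transcripts than were planted, but the
sign-consistent intersection across DOR/EFS/PFS recovers exactly the planted
programs. Evaluation (script 03) then shows the predictive-not-prognostic
contrast — strong stratification in the treated arm, null behavior in the
comparator arm whose outcomes do not depend on the programs:

```
  favorable/axi-cel/EFS: HR 0.27 (0.19-0.39), log-rank p = 2.7e-14
  favorable/SOC/EFS:     HR 1.13 (0.78-1.62), log-rank p = 0.52
  unfavorable/axi-cel/EFS: HR 4.03 (2.83-5.73), log-rank p = 1e-16
  unfavorable/SOC/EFS:     HR 1.32 (0.92-1.90), log-rank p = 0.13
```

Here `HR 0.27` means the high-favorable-score group has ~4× lower
instantaneous event risk; the log-rank p-values compare the high/low KM
curves. The univariate screen (script 04) places all 10 planted genes in its
top 10, illustrating that multivariate selection and univariate association
agree on strong planted signal while the signatures outperform single genes
in general.

## Published signature lists

The reported 6-gene favorable and 17-gene unfavorable signatures ship as
bundled lists, with the RNA-seq (gene-level) variants that drop the CD45
isoform transcripts:

```python
from gesig import load_published_signature
load_published_signature("ges6")   # CD19, PTPRC-RA, CCL22, KLRK1, SIGLEC5, SOX11
load_published_signature("ges17")  # IL18R1, GPC4, ..., SLC16A1
load_published_signature("ges5")   # ges6 minus PTPRC-RA
load_published_signature("ges16")  # ges17 minus PTPRC-RO
```

To score a real export (e.g. GEO accession GSE248835) rather than a
simulated cohort: flatten the series-matrix text file — tab-delimited with
`!`-prefixed metadata lines — into the two-file schema used here by taking
the expression block (first column gene/probe id, header = sample ids) as
`expression.tsv` with a `gene_id` first-column header, and assembling
`clinical.tsv` with one row per sample and columns `sample_id, subject_id,
arm, timepoint, collection_date, batch_id, coding_read_fraction, coo,
hgbl_flag, double_expressor_flag, myc_rearranged_flag, responder_flag,
dor_time, dor_event, efs_time, efs_event, pfs_time, pfs_event` (empty cell =
missing; times in days). Then:

```
gesig score --expression expression.tsv --signature ges6 --out scores.tsv
gesig evaluate --expression expression.tsv --clinical clinical.tsv \
      --signature ges6 --endpoint EFS
```

The `gesig` CLI also exposes `simulate`, `discover`, `screen`,
`compare-progression` and `run` (a full run with a replayable manifest);
exit codes are 0 (ok), 2 (validation error), 3 (convergence/statistical
error).

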