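# sitmir

Pipeline for linking **device-measured prolonged-sitting patterns** to
**differential expression of cardiovascular-disease-related microRNAs** in
endothelial-cell-derived extracellular vesicles (EC-EVs), for biostatisticians
and physical-activity epidemiologists working with hip-accelerometer minute
epochs, participant covariates, and qPCR Ct matrices.

## What it does

1. **Accelerometry** — Choi-style non-wear detection (≥90-min zero runs with a
   2-min spike tolerance flanked by 30 zeros), sitting bouts (maximal runs of
   sit-labelled wear minutes, no minimum, no tolerance), MVPA (wear minutes
   ≥ 1952 cpm), and per-participant daily means over adherent days (≥10 h wear,
   ≥4 days).
2. **Phenotyping** — cohort-wide quartile cross-tabulation of mean sitting-bout
   duration and MVPA: *Interrupted Sitters* (IS: bout Q1 × MVPA Q1) vs *Super
   Sitters* (SS: bout Q4 × MVPA Q1); augmented IS+/SS+ add Hispanic women from
   MVPA Q2 at the same bout extremes. RNA pooling plans (3 per pool, one pool
   of 2 when the group size is 2 mod 3, parent studies spread across pools).
3. **Expression** — pooled Ct as −log2 of mean linear abundance; relative
   expression 2^−ΔCt against the array control panel (screening) or
   SNORD61 + cel-miR-39 (validation).
4. **Causal weighting** — covariate-balancing propensity score (CBPS): logistic
   π_β(x) with β solving the just-identified ATE balance moments
   (1/n) Σᵢ [Tᵢ/π(xᵢ) − (1−Tᵢ)/(1−π(xᵢ))] xᵢ = 0,
   stabilized (and arm-normalized) inverse-probability weights, PMM
   chained-equations imputation, and standardized-difference / weighted-KS
   balance diagnostics.
5. **Effects** — weighted ATE per miR with a stratified bootstrap that *refits
   the propensity model in every resample*; standardized ATE = ATE / bootstrap
   SD; two-step screening (top 10 by |standardized ATE|, keep the 5 with the
   largest unweighted SD); validation significance when the 95% CI excludes
   zero; Pearson correlations and a weighted group × ethnicity interaction
   regression (HC0 errors).
6. **Enrichment** — one-sided Fisher's exact tests of pooled miR target genes
   against user-supplied GMT pathways.
7. **Synthetic cohorts** — a generator with known ground truth (latent sitting
   propensity driving bout durations, confounded covariates, 84-assay Ct
   matrices with planted effects) used throughout the tests.

## Worked example

The two-step candidate selection applied to a reported top-10 screening table
(standardized ATEs and unweighted SDs for ten CVD miRs):

```python
>>> from sitmir.datasets import SCREENING_TOP10
>>> from sitmir.effects import rank_and_select
>>> sel = rank_and_select(SCREENING_TOP10)
>>> sel.ranked[["std_ate", "unweighted_sd", "std_ate_rank"]].head(3)
             std_ate  unweighted_sd  std_ate_rank
mir
miR-199a-5p     5.44           1.53             1
let-7d-5p       5.33           1.94             2
miR-142-3p      5.29           2.21             3
>>> sel.selected
['miR-133b', 'miR-140-5p', 'miR-142-3p', 'let-7d-5p', 'miR-199a-5p']
```

miR-199a-5p ranks first by standardized ATE and miR-133b seventh, but the SD
filter removes the three low-variance assays (miR-155-5p, miR-424-5p,
let-7e-5p) whose tiny expression spread inflates their standardized effect, so
the five retained candidates are the large-SD members of the top ten. Applying
the zero-exclusion rule to the reported validation intervals flags miR-133b,
let-7d-5p, and miR-142-3p as significant.

A full synthetic run, end to end:

```bash
sitmir synth --config cohort.yaml --out bundle/
sitmir screen --epochs bundle/epochs.csv --covariates bundle/covariates.csv \
              --ct bundle/ct_screening.csv --boot 1000 --seed 7 --out run/
sitmir validate --groups run/groups.csv --covariates bundle/covariates.csv \
                --summaries run/summaries.csv --ct bundle/ct_validation.csv \
                --mirs run/selected.json --out run/
```

or in one step from a cohort config: `sitmir run --cohort-config cohort.yaml --out run/`.

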