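# immunoscreen

Prognostic immune gene-signature screening for chemotherapy-treated
breast cancer cohorts.

Tumors with pre-existing T-cell activation ("hot" tumors) tend to do
better after chemotherapy. This package implements the transcriptomic
screening procedure used to find and combine the immune genes behind
that effect in triple-negative breast cancer (TNBC): it takes a gene ×
sample log2 expression matrix plus a clinical table (relapse-free
survival, pCR, subtype, treatment, covariates) and asks, gene by gene
and signature by signature, whether high expression predicts 5-year
relapse-free survival — while accounting for the multiple testing its
own optimizations create. It is written for computational biologists
analyzing microarray or RNA-seq cohorts with survival endpoints.

## What it computes

- **Responder ROC screen.** Patients relapsing before the horizon
  (default 60 months) are non-responders; patients relapse-free with
  follow-up ≥ horizon are responders (censored earlier: excluded).
  Each gene is compared between groups with a Mann-Whitney ROC
  analysis: AUC = U/(n₁n₀) = P(responder value > non-responder value)
  (+ ½ ties), a two-sided p (exact permutation enumeration when both
  groups ≤ 8, tie-corrected normal approximation otherwise), and the
  strongest cutoff maximizing Youden's J = TPR − FPR.
  Benjamini-Hochberg FDR across genes gates significance at q < 0.10.
- **Minimal-p survival cutoff.** For Kaplan-Meier/Cox reporting, every
  distinct expression value between the lower and upper quartiles is
  tried as a low/high threshold; the split minimizing the log-rank p
  is selected, the hazard ratio with 95% CI comes from a Cox fit
  (Efron ties) on the binary indicator, and BH FDR over all derived
  cutoffs corrects the optimization-induced optimism.
- **Mean-expression signatures.** A gene set is scored as the
  per-sample mean of its members' log2 expression; exhaustive or
  greedy combination search ranks every candidate set by responder
  AUC. The four published immune signatures (HLA, IFN-γ, expanded
  immune, CTL) ship as builtins.
- **Multivariate Cox.** The dichotomized signature is adjusted for
  nodal status, grade and age in a joint proportional-hazards fit.
- **Synthetic cohorts.** A latent-factor generator (planted genes load
  on one immune-activation factor; relapse times follow proportional
  hazards on that factor; pCR independent by default) provides ground
  truth for every stage, including named presets that mirror the
  original study's cohort sizes (n = 164 discovery, n = 114
  confirmation).

## Worked example

```bash
python examples/05_full_pipeline.py
```

runs the full screen on a simulated 164-patient TNBC-like cohort
(paper-like preset, seed 1) and prints:

```
cohort: 164 samples, 87 events, 109 responders / 55 non-responders

gene ROC screen: 7 significant genes; top:
  gene      auc  p_value    fdr_q
  IDO1 0.714429 0.000008 0.001511
 STAT1 0.676564 0.000227 0.019708
 HLA-E 0.670726 0.000364 0.019708
  GZMB 0.669725 0.000394 0.019708
CXCL13 0.663053 0.000663 0.026501

signature survival:
      signature       hr   ci_low  ci_high        min_p        fdr_q
combined_immune 0.338605 0.218202 0.525448 4.280384e-07 2.006616e-05
       headline 0.285405 0.167618 0.485961 8.836570e-07 3.427576e-05
top_combination 0.235076 0.136231 0.405640 1.631410e-08 8.305113e-07

multivariate Cox (headline signature + clinical covariates):
     covariate       hr   ci_low  ci_high   wald_p
signature_high 0.282081 0.165560 0.480611 0.000003
  nodal_status 1.399606 0.895375 2.187794 0.140184
         grade 1.017651 0.775859 1.334796 0.899402
           age 1.002388 0.983090 1.022065 0.809934

pCR screen: mean AUC 0.502 (0 significant) — pCR is simulated independent
of the immune factor, so ~0.5 and none is expected.
```

Reading the numbers: all significant genes are planted immune genes
(AUC > 0.5: higher expression in responders). The headline 4-gene
signature IDO1+LAG3+STAT1+GZMB splits the cohort at its minimal-p
cutoff into arms with hazard ratio 0.29 (high expression protective),
an association that survives adjustment for nodal status, grade and
age — while the same genes show no association with pCR, which the
generator draws independently of the immune factor.

The other scripts in `examples/` demonstrate each capability in
isolation (simulation, per-gene ROC, cutoff scan + KM export,
combination search). The same analyses are available from the shell:

```bash
immunoscreen simulate --preset paper-like --seed 1 \
    --expression-out expr.tsv --clinical-out clin.csv
immunoscreen screen --expression expr.tsv --clinical clin.csv --out report/
immunoscreen roc  --expression expr.tsv --clinical clin.csv --gene STAT1
immunoscreen scan --expression expr.tsv --clinical clin.csv --gene STAT1
```

## Input formats

- Expression: UTF-8 TSV, header `gene<TAB>sample1<TAB>...`, cells
  numeric or `NA`; duplicate gene symbols are mean-collapsed.
- Clinical: CSV with `sample_id,rfs_time,rfs_event` (months, 0/1) and
  optional `pcr,subtype,treatment,nodal_status,grade,age`.
- Signatures: `name<TAB>comma,separated,genes` per line.

See `docs/methods.md` for the statistical model, parameter defaults,
and the design decisions behind each stage.
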