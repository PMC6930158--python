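# Methods

This note documents the statistical procedures implemented in
`immunoscreen`, the defaults and the reasoning behind them, what the
synthetic cohort generator does and does not emulate, and the known
limitations of the approach.

## The screening procedure

The pipeline operationalizes a common clinical-transcriptomics
question — *does high expression of an immune gene (or gene set)
predict relapse-free survival after chemotherapy?* — as four chained
analyses on one cohort object (expression matrix inner-joined to a
clinical table by sample ID, never by column position).

### 1. Responder dichotomy and Mann-Whitney ROC

Relapse-free survival (RFS, months) is dichotomized at a horizon
(default 60 months): event before the horizon → non-responder;
event-free with follow-up ≥ horizon → responder; censored before the
horizon → excluded with reason `censored-before-horizon`. Exclusion
(rather than counting early-censored patients as responders) is the
conservative choice because their 5-year status is genuinely unknown;
the horizon is configurable.

Each gene is compared between the groups by the Mann-Whitney U
statistic. The reported AUC is U/(n₁n₀), i.e. the probability that a
random responder's value exceeds a random non-responder's, counting
ties as half. Direction is never folded: AUC < 0.5 (high expression
in non-responders) is reported as-is. The two-sided p-value uses
exact permutation enumeration over all label assignments when both
groups have ≤ 8 samples (valid under ties), and otherwise the normal
approximation with the standard tie-corrected variance and no
continuity correction — the behaviour of mainstream implementations
at the cohort sizes this pipeline targets. Groups need ≥ 3 samples
each; an all-constant comparison returns AUC 0.5, p 1 with a
`degenerate` flag.

The "strongest cutoff" maximizes Youden's J = TPR − FPR over
midpoints between consecutive distinct pooled values, for the rule
"predict responder when value > cutoff"; ties break toward the lower
cutoff. FPR/TPR are reported at that cutoff.

Across genes, Benjamini-Hochberg step-up q-values
(q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ p₍ⱼ₎·m/j, stable under ties) gate significance at
q < 0.10. Genes analyzable on fewer than 20 non-missing samples are
flagged `low_n`; unanalyzable genes are reported with a reason, never
silently dropped. Missing expression values are excluded pairwise per
gene, never imputed.

The same machinery screens pathological complete response (pCR = 1 as
the responder class); pCR is a binary endpoint, so no horizon or
censoring logic applies.

### 2. Minimal-p-value survival cutoff

For Kaplan-Meier and Cox reporting a gene must be dichotomized. The
scan considers every distinct observed value v with Q1 ≤ v < Q3
(type-7 linear-interpolation quartiles — stated explicitly because
candidate eligibility depends on the convention) and splits the
cohort at "high = value > v", which guarantees each arm keeps at
least a quartile of the patients. The per-cutoff statistic is the
two-group log-rank test (computed by a vectorized routine that
evaluates all splits of one cohort in a few matrix products); the
best cutoff is the argmin of p, ties toward the lower cutoff. The
hazard ratio and 95% CI at the best cutoff come from a Cox fit on the
binary indicator.

Trying every cutoff inflates the minimal p far above its nominal
level (measured ≈ 0.29 rejection at α = 0.05 under a global null).
The correction is BH FDR over all of the scan's per-cutoff p-values;
the gene-level verdict uses the q of the minimal-p cutoff at the
0.10 level. By default FDR runs within each gene's own scan; a
pooled-across-genes scope is available (`fdr_scope="pooled"`) since
the pooling convention is a genuine free choice. Under the null
preset the within-gene default yields an average discovery rate of
≈ 0.05 ≤ 0.10.

Log-rank p for the scan and KM display, Cox Wald statistics for
HR/CI: the two coincide asymptotically (and the Cox *score* test
equals the log-rank test exactly for a binary covariate without
ties), matching the dual reporting style common in survival
screening tools.

### 3. Survival machinery

- **Kaplan-Meier**: product-limit estimate; censoring decrements the
  risk set without a step. Curves export as (time, survival, at-risk)
  tables.
- **Log-rank**: standard hypergeometric O−E and variance per distinct
  event time, χ² on 1 df.
- **Cox proportional hazards**: Newton-Raphson maximization of the
  Efron partial likelihood (Efron tie handling is the robust default
  for the 0.1-month time grid the generator produces), convergence at
  1e-9 on the coefficient change, max 100 iterations, step-halving to
  guarantee ascent. Wald 95% CI = exp(coef ± 1.96·SE); the global
  score test at β = 0 is reported alongside. Constant or collinear
  designs raise a singular-design error; monotone likelihood (perfect
  separation) is detected via runaway coefficients or a broken
  information matrix and returned as a flagged non-converged fit,
  never as silent output. Fits require n_events ≥ k + 1.

These are implemented in-package because the cutoff scan needs a
many-splits log-rank that per-call libraries make impractically slow,
and because the fit contract above (ties, tolerance, flags) is part
of the package's reproducibility surface; `lifelines` serves as an
independent cross-check in the test suite (coefficients and standard
errors agree to ~1e-5, log-rank to 1e-9).

### 4. Signatures and combination search

A signature score is the per-sample arithmetic mean of the gene set's
log2 values (`raw_mean`, the default — "mean expression" taken
literally), with NaN skipped per sample. A `zscore_mean` mode
standardizes each gene across samples first, making the score
invariant to per-gene affine rescaling; it is offered because
cross-gene intensity scales differ on real arrays.

Combination search ranks candidate gene sets by their score's
responder AUC. Exhaustive mode evaluates every subset with
min_size ≤ |S| ≤ max_size; greedy mode evaluates all pairs, seeds on
the best pair, and repeatedly extends the current set by the single
AUC-maximizing gene (recording every evaluated extension, stage =
subset size) until all genes are included. Records sort by AUC
descending, ties by p ascending then lexicographic gene set, and
carry BH q-values over all recorded p-values. Published combination
tables of this kind resemble a greedy expansion; both modes are
provided rather than reverse-engineering any specific row list.

Signature survival analysis applies the cutoff scan to the score
vector (a singleton signature reproduces the gene-level scan
bitwise). Multivariate Cox dichotomizes the signature at its
scan-selected cutoff and fits it jointly with nodal status, grade
(ordinal 1–3) and age on complete cases.

The builtin signatures are the four published immune sets (HLA;
IFN-γ; expanded immune, 18 genes; CTL) plus the ten-gene combined set
and the headline IDO1+LAG3+STAT1+GZMB set. The symbol ISGF-3 is
stored under its canonical gene name IRF9 (the complex ISGF3 is the
STAT1/STAT2/IRF9 trimer; expression arrays measure IRF9).

### 5. Pipeline

`run_screen` chains the stages (labels → gene ROC → gene scans →
combinations → signature survival → multivariate Cox → pCR) and
writes a stable report directory of TSVs. Combinations are built only
over the genes individually significant in the ROC screen — the same
rule the combination table construction implies — which also prevents
a selection bias: seeding the search with the best-looking null genes
would make many null combinations appear significant. Reports are
byte-identical for identical config + seed; wall-clock data lives
only in the side `run.log`. Stage failures abort with the stage name;
partial output directories are never left behind (stage-then-rename).

## The synthetic cohort generator

Per patient i, a latent immune-activation factor aᵢ ~ N(0,1). Planted
gene g: x₍gᵢ₎ = μ_g + λ·aᵢ + ε, noise gene: x₍gᵢ₎ = μ_g + ε, with
ε ~ N(0, σ) and μ_g ~ U(4, 10) log2 units. Relapse times are Weibull
(exponential by default, shape exposed) with rate h₀·exp(β·aᵢ);
censoring is administrative at C months (optionally uniform over a
window); observed times are rounded to 0.1 months — enough mass ties
to exercise Efron handling without degenerate grids. pCR is
Bernoulli(rate) independent of aᵢ by default, or logistic in aᵢ in
linked mode. Clinical covariates are drawn independently of the
factor: nodal status Bernoulli(0.35), grade {1,2,3} at
(0.15, 0.35, 0.50) (TNBC skews high-grade), age ⌊N(52, 11)⌉ clipped
to 25–85. Everything is reproducible from one seed.

Defaults: n = 164 samples (the discovery-cohort size), 200 genes with
the ten-gene combined set planted, λ = 1, σ = 1, β = −0.9 per factor
SD (protective), h₀ = 0.006 events/month, C = 120 months, pCR rate
0.30. h₀ and C were chosen so that roughly half the cohort relapses
within follow-up (≈ 87 events at n = 164) — typical of early TNBC
RFS — and so that per-gene responder AUCs land in the 0.63–0.71 range
actually observed for immune genes in such cohorts. Presets:
`paper-like` (defaults), `null` (β = 0), `pcr-null` (survival-linked
expression, independent pCR), `small-sample` (n = 114, the
confirmation-cohort size) and `combo-recovery` (headline four genes
planted among ten total, β = ln 0.4, for combination-search recovery
studies).

What the generator does **not** emulate: probe-level microarray
noise, batch and platform effects, cross-cohort normalization,
multiple co-regulated immune programs, covariates correlated with
immune state, and informative censoring. Passing tests therefore
demonstrate that the statistics behave correctly under the stated
single-factor proportional-hazards model — not that any particular
gene set is prognostic in real cohorts.

## Numerical choices and degenerate inputs

- Quartiles: numpy default linear interpolation (type 7).
- Scan ties: first (lowest) cutoff wins; ROC cutoff ties likewise.
- BH ties: stable sort; equal p receive equal q.
- Exact MW enumeration bounded at 8 per group (≤ 12,870 assignments).
- Cox overflow guard: η is shifted by its maximum (cancels exactly in
  the Efron likelihood and its derivatives).
- Constant expression vectors: no-cutoff error in the scan,
  degenerate flag in ROC.
- Genes with < 2 finite values are rejected at matrix construction;
  < 20 analyzable samples flags `low_n` (ROC) or fails the scan.

## Known limitations

- The minimal-p cutoff is optimized and its hazard ratio is therefore
  optimistic even after the FDR gate; the q-value controls the
  discovery rate, not the HR bias. External validation at a fixed
  cutoff remains necessary.
- Nested mean-expression signatures differ by tiny true AUC margins
  (adding or dropping one gene from a k-gene set changes the score's
  noise by ~1/k), so at n ≈ 164 many combinations are statistically
  interchangeable near the top of the ranking; the search reliably
  finds *a* near-optimal signature, not a unique one. Simulation at
  these conditions shows the exact planted set tops the exhaustive
  ranking only rarely, while its hazard-ratio direction is recovered
  essentially always — expect the same on real data.
- Proportional hazards is assumed, not checked; no competing risks or
  time-dependent covariates.
- Cross-platform harmonization of multi-cohort inputs is upstream of
  this package, as is probe-to-gene collapsing (duplicate symbols in
  the input are mean-collapsed as a convenience, with a log note).

## Problem sizes used in the shipped checks

Oracle equivalences run on 1000 random instances (AUC, BH) and 200
random small cohorts (cutoff scan); calibration and recovery studies
use 20–50 seeded replicates of the presets above; the Cox consistency
check uses one n = 2000 two-group cohort with true HR 2. These sizes
put Monte-Carlo error well below the asserted tolerances while
keeping the full suite fast.
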