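# Methods

This note documents the models and procedures implemented in `mrde`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic cohort does and does not emulate.

## Differential expression engine

Counts for gene *g*, sample *j* are modelled as negative binomial with mean
`μ_gj = s_j · exp(x_jᵀ β_g)` and variance `μ + α_g μ²`, where `s_j` is a
median-of-ratios size factor and `α_g` a per-gene dispersion. Three designs
are supported:

* **all-patients** — intercept + patient indicators (drop-first) + a tumour
  indicator; the tumour coefficient is tested. Patient blocking absorbs
  between-patient baseline differences, so what remains of a
  subgroup-restricted effect is its *cohort-average* — a gene up 4-fold in a
  third of patients has an average log2 effect of ~0.7, below the |log2FC| > 1
  call threshold. This dilution, not a significance failure, is the main
  mechanism by which the cohort-level analysis misses subgroup genes.
* **per-patient** — intercept + tumour indicator within one patient
  (≥2 tumour regions + exactly 1 normal required; others are skipped with a
  warning).
* **between-groups** — intercept + group + patient-nested-in-group
  indicators + one tumour indicator per group; the tested contrast is the
  difference of the two tumour effects. Rank is checked after construction
  and aliased columns are named in the error.

**Fitting.** Per-gene GLMs are fitted by iteratively reweighted least
squares, batched across genes (the design is shared, so the weighted
normal equations are solved as a stacked batch with BLAS); log-link, size
factors as offsets, working-response initialisation from
`log((y+0.5)/s)`, convergence at max |Δβ| < 1e-6 or 50 iterations.
Non-converged genes are flagged and their p-value set to 1. The Wald
statistic uses the observed-information standard error of the contrast;
coefficients and SEs are reported in log2 by base conversion, p-values are
two-sided normal tails clipped to [1e-300, 1], and BH adjustment is applied
within each analysis independently (per patient, per design). A tiny ridge
(1e-9) stabilises the normal equations; an optional Normal(0, 4) log2-scale
ridge prior is available behind a flag for separable designs but is off by
default — reported fold changes are plain maximum likelihood, and no
posterior LFC shrinkage is performed: the call rule operates on the raw
estimates, which keeps the decision boundary transparent.

**Dispersions.** Gene-wise method-of-moments estimates come from the
residual variance of size-factor-normalized counts around the least-squares
design fit: `α_g = (s² − ξ·μ̄)/μ̄²` with `ξ = mean(1/s_j)` the Poisson part,
floored at 1e-8. A robust (Huber) regression of `α_g` on `1/μ̄` gives the
trend `α(μ) = a₀ + a₁/μ` (coefficients clamped non-negative), and the final
value blends gene and trend estimates on the log scale with weight 0.5 on
the trend. When residual degrees of freedom are ≤ 1 — every per-patient
design — the trend is used outright: 3–6 samples cannot support gene-wise
variance estimation, and sharing information through the trend is what makes
the per-patient Wald test usable at all.

**Normalizations.** `mor_log2` is `log2(count/s_j + 1)`. `tmm_cpm_log`
(used for classifier features) implements trimmed-mean-of-M-values factors:
the reference sample is the one whose upper-quartile of library-scaled
counts is closest to the cohort mean; M-values are trimmed 30% and A-values
5% from each tail; the factor is the precision-weighted mean M (asymptotic
binomial weights); factors are normalized to geometric mean 1 and the output
is `log2(CPM + 0.5)` on effective library sizes. `shifted_log` (display
only) is the shifted log on median-of-ratios counts. Count filtering keeps
genes with ≥1 count in ≥ceil(0.3·n) samples and is applied once, globally,
before all analyses (configurable).

## DEPC, AP/NAP, thresholds, permutation null

`depc_up(g)` counts patients whose per-patient analysis calls *g* up
(likewise down); the universe is the outer union of the per-patient tables
with absent genes counting as "none". Genes with ≥1 call in a direction are
**AP** if the all-patients analysis calls them in the same direction, else
**NAP**. The subgroup-gene threshold is `mean + 2·sample SD` of the DEPC
values; the mean/SD are computed over genes with DEPC ≥ 1 (including the
all-zero mass would collapse the threshold toward zero — exposed as
`--threshold-universe {nonzero,all}`), and the comparison is inclusive
(`depc ≥ threshold`) so the all-equal edge case selects everything rather
than nothing.

The permutation null redistributes the adjacent-normal samples uniformly at
random over patients (fixed points allowed), re-runs the per-patient
analysis and DEPC, and compares the observed curve of `#genes with DEPC ≥ t`
against the permutation mean ± SD. With correct pairing, patient-specific
baselines cancel and only genuine dysregulation is called; with a wrong
normal, the between-patient baseline difference masquerades as fold change
in *many* patients at once, inflating high-DEPC counts and depleting the
low-DEPC band where genuinely patient-specific genes live.

## Co-clustering and patient groups

Per-patient calls over the selected gene subset become a categorical matrix
(+1/0/−1). The latent block model assigns rows (genes) to L clusters and
columns (patients) to K clusters with block-specific category distributions
θ_lk over the three categories. Fitting is classification EM: alternate
hard row and column assignments maximizing the complete-data log-likelihood,
with θ updated as category frequencies smoothed by a 0.5 pseudo-count per
category (a Dirichlet(1.5) MAP step that keeps pure blocks off the log(0)
boundary) and mixing proportions as cluster frequencies. The quantity that
is guaranteed non-decreasing under these updates is the penalized objective
(complete log-likelihood + 0.5·Σ log θ); the fit records both it and the
plain complete-data log-likelihood, and convergence is a relative change
below 1e-8. Empty clusters are re-seeded with the worst-fitting item.
Twenty random restarts are run and the best objective kept; a fixed seed
makes the whole fit deterministic. K = L = 3 by default (patient clusters
are the scientific contract; the gene-side count is a symmetric default), and
no model selection over K is attempted.

Cluster labels are canonical: clusters sorted by ascending mean number of +1
cells per patient become PG0, PG1, …, so "PG(K−1) is the up-regulation-rich
group" holds by construction across seeds and restarts. The pipeline's
between-groups DE contrasts the two largest groups.

## Survival and clinical statistics

The weighted log-rank statistic is
`(Σᵢ wᵢ (Oᵢ − Eᵢ))ᵀ V⁻ (Σᵢ wᵢ (Oᵢ − Eᵢ))` over distinct event times, with
the usual hypergeometric per-time covariance, df = K−1. Weights: 1
(log-rank), `S̃(tᵢ⁻)` (Peto-Peto) or `S̃(tᵢ⁻)·nᵢ/(nᵢ+1)` (modified
Peto-Peto, the default), where `S̃(t⁻) = Π_{t_j<t} (1 − d_j/(n_j+1))` is the
left-continuous pooled survival estimate. The modified form emphasises early
differences; the cost is efficiency under proportional hazards — at a true
hazard ratio of 2 with 40 subjects per group its power is ≈0.75 where the
unweighted log-rank reaches ≈0.87 (both figures reproduced by R's
`survdiff`), a known property of the weight family documented here because
the test suite measures it. Kaplan-Meier estimation delegates to lifelines.

Wilcoxon rank-sum uses exact enumeration for tie-free pooled samples of ≤12
and otherwise midranks with a continuity-corrected normal approximation; the
one-sided direction must always be passed explicitly. Clinical association
tables use Fisher's exact test when any expected cell is <5 (Monte-Carlo
with margin-preserving Patefield sampling and a plus-one correction for
tables beyond 2×2), else Pearson's chi-square. The chi-square goodness-of-fit
test reports standardized residuals `(O−E)/√E`, whose squares sum to the
statistic.

## Enrichment

Over-representation is the inclusive hypergeometric upper tail `P(X ≥ k)`
for overlap k between a query of n genes and a set of K genes in a
background of N, BH-corrected across sets. The background defaults to the
genes surviving the count filter; it is a required argument in the CLI so
the choice is always explicit.

## TND classifier

Each tumour sample yields one instance: its normalized (TMM CPM-log)
expression minus the patient's normal sample, restricted to the feature
genes — differencing removes the patient baseline, which is exactly the
nuisance that defeats cohort-level analysis, and is what allows transfer to
an external cohort with different baselines. The network is four linear
layers (defaults 327→200→100→50→k; the hidden widths taper from the feature
count and are configurable — depth, activations and initialisation are
fixed, widths are a free choice), ReLU on the first three (Kaiming-normal
init), softmax head (Xavier-normal init), SGD with learning rate 0.01 and
momentum 0.9, cross-entropy loss, 500 epochs at batch size 32. Splits are
70/30 at instance level (multiple instances of one patient may straddle the
split; `--split-by-patient` is the conservative alternative), a split
missing a class is resampled, and the patient's group label is copied to all
its instances. Aggregation over trials: per-instance label counts vs the
uniform expectation `n_trials/k` via chi-square goodness of fit, BH across
instances, argmax standardized residual on significance (ties to the lowest
group index), otherwise "unassigned". The implementation is a small numpy
network — at these sizes a forward/backward pass is a handful of dense
matmuls and trains in milliseconds per epoch on one CPU.

## Synthetic cohort generator

The generator is the package's study stand-in: 90 patients, one
adjacent-normal plus 2–5 tumour-region samples each (uniform), 2000 genes.
Gene-level log-means are Normal(4.6, 1.2²) (natural log of expected counts,
median ≈100); each patient draws a baseline around the gene mean with SD 0.8
— pervasive between-patient variability, present for *all* genes — raised to
2.0 for the subgroup-restricted stratum, comfortably above the 2× separation
the high-variance mechanism requires after count noise compresses the
empirical ratio. Gene classes: 1% cohort-wide up (+2 log2FC in every
tumour), 1% cohort-wide down (−2), 5% subgroup-restricted up (+2 only in the
targeted patient group), 93% null. Patients fall into 3 latent groups with
probabilities (0.467, 0.4, 0.133) (multinomially, so tests never depend on
one fixed composition); subgroup genes target a group with probabilities
proportional to group membership but with the smallest group zeroed,
emulating a quiescent third group. On top of the planted classes, each
(gene, patient) pair independently receives a private ±2 log2 tumour effect
with probability 0.05 — per-patient analyses of real tumours find far more
dysregulated genes per patient than any shared core explains, and this
sparse private dysregulation is what populates the low-DEPC band that the
pairing-permutation contrast depends on. Counts are gamma-Poisson with
dispersion 0.05 on log-normal library factors (SD 0.2). Recurrence times
are exponential with per-group hazards (1/350, 1/550, 1/900 days, ordered so
up-regulation-rich groups recur faster), censored at 1500 days; two binary
covariates (sex- and HBV-like) and one log-normal continuous marker are
generated with group-biased parameters, enough to exercise the association
report without modelling a clinic.

What the generator does *not* emulate: read-level noise, isoform structure,
GC/length bias, clonal phylogenies within tumours, realistic gene-gene
correlation, or calibrated effect-size distributions — the defaults are
chosen for testability. Consequently, passing recovery tests demonstrate
that the pipeline's inference machinery is correct and calibrated under its
own model assumptions, not that real cohorts will yield comparable recovery
rates.

## Numerical and scaling choices

* Linear predictors are clipped to ±50 before exponentiation; all-zero genes
  are reported as log2FC 0 with p = 1.
* Size factors require at least one all-positive gene row; a pseudo-reference
  fallback (geometric means over positive entries of genes expressed in ≥half
  the samples) is available and is the default inside the per-patient runner,
  where subsets are small.
* All randomness flows from one seed; pipeline stages derive seeds as
  `sha256(seed:stage) mod 2³¹`, recorded in the run manifest.
* Test and acceptance problem sizes: the cohort-level recovery checks run at
  the full default 90×2000; DE calibration uses 16-patient/500-gene null
  cohorts over several seeds; the permutation study uses 20 patients × 10
  permutations; co-clustering recovery uses 300×60 matrices over 10 seeds;
  classifier benchmarks use 50-feature separable instances at 100 trials
  with 60 epochs (the separable benchmark converges long before the
  500-epoch production default).

## Known limitations

* No posterior LFC shrinkage (apeglm/ashr-style); raw MLE fold changes mean
  low-count genes can show large, noisy |log2FC| — mitigated by the joint
  padj + |log2FC| call rule, but not eliminated.
* No Cook's-distance outlier handling or independent filtering.
* The modified Peto-Peto default trades power under proportional hazards for
  early-difference sensitivity (figures above).
* The per-patient design leans entirely on the dispersion trend; patients
  with unusually noisy tumours inherit the cohort-typical trend and may be
  anti-conservative.
* Monte-Carlo Fisher p-values have ~1/√n_mc resolution (default 1e5 draws).
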