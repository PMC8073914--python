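# Methods

## The model

`driverscope` treats driver discovery as a conjunction of screens over a
gene-level multi-omics cohort. The unit of evidence is the gene–sample
pair; the binary variation profile `V[g, s] = 1` iff sample `s` carries
a non-neutral GISTIC call (any of −2, −1, +1, +2) or at least one
non-silent somatic mutation in gene `g`. Variation frequency is the row
mean of `V` over the profiled sample set. The OR-union is monotone by
construction: adding mutation data can never lower a gene's frequency.

### Candidate screen

The four criteria are conjunctive filters with the following exact
conventions:

* **Dominant CNA direction.** `k` = number of amplified samples among
  the `n` non-neutral ones; the two-sided exact binomial p at p₀ = 0.5
  sums the probabilities of all outcomes whose point mass does not
  exceed the observed one. ±1 and ±2 codes weigh equally — the test is
  about direction counts, not magnitude. Two-sidedness is a package
  convention (the symmetric exact test); the threshold (0.05) is
  inclusive.
* **Prevalence.** Strictly more than 75% of tumours with detectable
  expression. The check is scale-free: log2(x+1) > 0 ⇔ raw x > 0.
* **Concordance.** Carriers (CNA-binary = 1, mutation-only carriers
  excluded — the criterion is about dosage) vs wild type, two-sided
  rank-sum, p ≤ 0.05, and the median difference must point the way the
  dominant direction predicts. An empty group fails the criterion with
  a degenerate p of 1.
* **Frequency.** Strictly greater than 0.1, computed on the CNA ∪
  mutation union.

No multiplicity correction is applied within the screen; the selection
burden sits in the survival stage, and both thresholds are
configurable.

### KD calling

The DE stage is a two-group rank-sum per gene with BH adjustment,
calling a gene DE at fdr ≤ 0.05 **and** p ≤ 0.01; an adapter accepts
any precomputed external DE table with (gene, p, fdr) columns. With
several DE tables the default combination is the union of called genes
(configurable to intersection), then intersected with the candidates.

Each surviving gene splits the cohort by copy-number status (carriers =
CNA-binary 1; mutations do not enter the grouping). OS and DFS are
compared by the log-rank test; the KD rule is min(p_OS, p_DFS) < 0.05 —
either endpoint suffices, which matches reporting genes by one endpoint
only. The rule is monotone in α. Under independent null endpoints the
expected KD rate among tested genes is 1 − 0.95² ≈ 0.0975; no
cross-gene multiplicity correction is applied, so this null rate is the
honest interpretation floor for any KD list. Genes whose carrier or
wild-type group falls below `min_group_size` (default 5) are skipped
with a logged reason.

A calibration caveat measured during development: the asymptotic
log-rank is mildly liberal for carrier groups near the minimum group
size (rejection ≈ 0.055 at 5–12 carriers of 265; identical in an
independent implementation), and well calibrated at the ≥ ~30-carrier
groups the pipeline actually tests (candidates must have frequency
> 0.1). Null-calibration checks therefore measure the survival stage on
genes with the screened frequency profile.

### Dysregulation network

Only cataloged (regulator, KD gene) pairs are ever scored — the catalog
is an input, not an inference. Pearson r over the complete-case sample
intersection of the two panels; BH once across the pooled miRNA + TF
candidate set (per-class pooling available); retention at padj ≤ 0.05
with the miRNA sign constraint r < 0 (a miRNA can only repress its
target; TF edges carry the sign of r). The retained set is invariant to
candidate-edge input order, and on small panels equals an independent
brute-force recomputation (asserted in the tests).

### Drug response

Spearman rho between IC50 and expression per (drug, gene) over ≥ 5
complete-case cell lines; rank-based, so raw vs log IC50 is immaterial.
Labels at raw p ≤ 0.05 (a BH option exists): positive → resistance,
negative → sensitivity. Cross-panel concordance is the sign-agreement
fraction among pairs significant in both panels.

### Signature grouping

Patient dissimilarity d(i,j) = 1 − Pearson r of the two samples'
KD-expression vectors; hierarchical clustering with average linkage by
default (Ward available) — average linkage respects the correlation
metric without Euclidean assumptions. The tree is cut at k = 1…k_max
(default 10) and WSS is computed in KD-expression space about cluster
means; cuts are nested, so the curve is non-increasing and reaches 0 at
k = n (k_max ≤ n is allowed for exactly this check; k_max > n is an
error). The elbow is automated as the k maximizing the second
difference of the WSS curve — a seed-stable stand-in for the visual
choice — and can be overridden with `k_override`/`--k`. Group prognosis
uses the k-group log-rank, pairwise tests against a configurable
reference group (no multiplicity correction by default), and a Cox
model with group dummies vs the reference, continuous age, stage
dummies vs stage I, and lymph-node count, Efron tie handling.

## Statistical kernels

* Rank-sum: exact permutation distribution when the smaller group has
  ≤ 8 observations and the pooled sample is tie-free, otherwise the
  normal approximation with tie and continuity corrections. The switch
  point balances exactness against cost and is configurable.
* Binomial: exact, two-sided by the minimum-likelihood convention,
  symmetric at p₀ = 0.5.
* BH: step-up, order-preserving, capped at 1. Note BH is *not*
  idempotent in general (re-adjusting an adjusted vector can only raise
  values); the tests assert the properties that actually hold.
* Log-rank: the observed-minus-expected chi-square over pooled event
  times with hypergeometric covariance, supporting k ≥ 2 groups;
  written in-package because the screens call it tens of thousands of
  times, and cross-checked in the tests against lifelines and a
  permutation null.
* Cox: lifelines partial-likelihood fit with Efron ties; a separate
  hand-written score test at β = 0 reproduces the classic equivalence
  with the two-group log-rank on untied data (asserted to 1e−6).

Degenerate inputs never produce silent numbers: constant vectors,
empty groups and zero-event cohorts return flagged results with p = 1,
and downstream stages skip flagged pairs with a logged reason.

## The synthetic-cohort generator

The generator emulates the statistical structure the screens assume,
not the biology of any particular tumour type:

* **CNA.** Planted drivers draw carriers at a per-gene frequency
  (default range 0.15–0.4) in one dominant direction, 90% low-level
  (±1) and 10% high-level (±2) events. Passengers carry symmetric
  sparse noise (rate 0.05 per gene–sample). Mutation indicators are
  background Bernoulli (rate 0.01 non-silent, plus 0.005 silent records
  that the spectrum must ignore).
* **Expression.** Gaussian on the log2 scale with unit within-group
  variance around gene-level baselines (mean 5) — the screens are
  rank/normal based, so count-level realism adds nothing the tests
  could detect. Driver carriers shift by 1 SD in the CNA direction;
  passengers are expression-independent of their CNA noise (null by
  construction). Drivers additionally shift 1 SD against the matched
  control panel (default 30 normals) so the DE stage has signal. A 5%
  fraction of passenger genes is zero-inflated (40% dropout) to give
  the prevalence filter something to reject; planted drivers are
  excluded from this fraction, since a driver is by construction an
  expressed gene.
* **Survival.** Exponential event times with per-sample hazard λ₀ ·
  HR^(number of prognostic-driver CNAs carried); λ₀ = ln 2 / 24 per
  month (24-month baseline median), HR = 2, half the drivers
  prognostic. OS and DFS are independent draws (which is what makes the
  1 − 0.95² null rate exact for the generator). Censoring is uniform
  administrative on (0, c) with c solved in closed form so the cohort
  event rate hits a target (default 0.5). Clinical covariates (age,
  stage, lymph nodes, histology) are survival-independent by default;
  90% of tumours have clinical follow-up, mirroring the usual
  genomic-n > clinical-n gap.
* **Regulators.** Each driver gets 2 true miRNA edges (planted r =
  −0.5) and 1 TF edge (|r| = 0.4, one sign per TF so hubs act
  consistently); regulators are reused across genes so hubs arise. A
  regulator with k targets is built from the standardized mean of its
  targets, so its attained per-target correlation shrinks by roughly
  1/√k. The catalog adds 200 decoy pairs with no constructed
  association.
* **Drugs.** 38 cell lines × 24 drugs; planted Spearman associations
  are realized through a Gaussian copula (latent Pearson
  2·sin(π·ρ_s/6)); IC50 is exponentiated to stay positive.

What passing tests on these cohorts do **not** show: robustness to
batch effects, probe-level microarray artifacts, non-proportional
hazards, confounded clinical covariates, or allele-level mutation
spectra — none of which the generator models.

## Problem sizes used in the checks

Recovery and calibration are asserted at the default study conditions
(300 tumours × 2000 genes, 30 drivers, 10 seeds for recovery; 265 ×
2000 over 20 seeds for the null screens, with the survival-stage null
measured on 300 screened-frequency genes per cohort; 38-line drug
panels; 265-sample 4-cluster signatures). These sizes keep the full
suite to a few minutes on one CPU while leaving every assertion
binomially well-powered; the acceptance script uses the same conditions
with 5–10 seeds per quantity.

## Known limitations

* The DE stage is a rank-sum substitute, not a count-model fit; for
  real RNA-seq counts an external DESeq2/edgeR/limma table via the
  adapter is the better route.
* No proportional-hazards diagnostics, frailty or stratified Cox.
* The elbow rule picks the sharpest WSS flattening; on unstructured
  data (no real clusters) the maximum second difference is noise, and
  the override should be used.
* Sample-ID normalization is truncation-based; cohorts with genuinely
  conflicting barcode dialects need pre-mapping.
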