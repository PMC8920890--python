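# Methods

`burstlnc` re-implements, end to end and on synthetic data with known ground
truth, the computational machinery for characterizing lncRNA transcription
from allele-resolved single-cell RNA-seq: two-state burst-kinetics inference
and hypothesis testing, expression-matched variability permutation tests,
decay-calibrated absolute burst timescales, cis-interaction discovery from
allelic imbalance and allelic coordination, and cell-state association.

## The two-state (telegraph) model

A promoter switches ON with rate `k_on` and OFF with rate `k_off`, and
transcribes at rate `k_syn` while ON; all rates are expressed in units of the
mRNA degradation rate. At steady state the RNA copy number is Beta-Poisson:

    x ~ Poisson(k_syn * p),   p ~ Beta(k_on, k_off)

Derived quantities: burst frequency = `k_on`, burst size = `k_syn / k_off`,
mean = `k_syn * k_on / (k_on + k_off)`. Burst frequency converts to absolute
time through the decay rate: with half-life `t_half`, the degradation rate is
`lambda = ln 2 / t_half` per hour and the expected time between bursts is
`1 / (k_on * lambda)` hours.

### Likelihood evaluation

The marginal pmf is the integral of the Poisson pmf against the Beta density.
It is evaluated by Gauss–Jacobi quadrature, whose weight function *is* the
Beta kernel, so endpoint singularities for shape parameters below one are
handled exactly. Nodes and weights come from the Golub–Welsch eigenvalue
construction on the Jacobi recurrence (`scipy.linalg.eigh_tridiagonal`),
which is roughly an order of magnitude faster than the library node routine
and makes the optimizer inner loop affordable. The node count adapts to the
sharpest feature of the integrand (50 nodes baseline, growing like
`2*sqrt(k_syn)` and `2*sqrt(k_on + k_off)`, capped at 600); a closed-form
confluent-hypergeometric expression serves as fallback for evaluations the
quadrature cannot represent in floating point. Against fine adaptive
numerical integration with peak bracketing, absolute pmf error is below
1e-8 across the full parameter range the optimizer can visit (and ~1e-13
in the typical range).

### Maximum-likelihood fitting

Per gene and allele, the summed log-pmf over cells is maximized in
log-parameter space with bounded L-BFGS-B, `k_on, k_off in [1e-3, 1e3]`,
`k_syn in [1e-2, 1e4]`. The gradient is analytic and reuses the likelihood's
quadrature rule: with `g_i` the posterior weight of node `p_i` given a
count,

    d logpmf / d k_on  = E_g[ln p] - psi(k_on) + psi(k_on + k_off)
    d logpmf / d k_off = E_g[ln(1-p)] - psi(k_off) + psi(k_on + k_off)
    d logpmf / d k_syn = E_g[x / k_syn - p]

(verified against finite differences to <1e-3 relative everywhere). When a
shape parameter is below one its derivative integrand is log-singular at an
endpoint and the Gauss rule misses it; that component falls back to a
central difference of the objective. Starts: the factorial-moment
(Peccoud–Ycart) estimator plus a fixed `{0.1, 1, 10}^3` grid. Polishing all
28 grid points is wasteful, so grid points are screened by objective value
and only the best three are polished alongside the moment start. Cells whose total count is
observed but whose allelic assignment is missing are excluded; true zeros
(no molecules at all) are kept. Genes need at least 1 molecule in at least
5 cells to be fit.

### Bootstrap confidence intervals

Cells are resampled with replacement (assignment-missing cells excluded from
the frame) and each replicate refit. Every replicate starts from a fresh
log-uniform random initialization — sampling the kinetic space of starts —
*and* from the full-data point estimate as an anchor, keeping the better of
the two. The anchor exists because about a third of pure random starts land
in spurious local optima whose estimates sit orders of magnitude away and
would corrupt the 2.5/97.5 percentile CIs. More than 20% replicate failures
flag the fit unstable. Default 1,000 replicates; the validation experiments
use 80–100, which is enough for percentile CIs at the tested coverage.

### Post-inference filters

A fitted gene×allele passes when: ≥1 molecule in ≥5 cells; burst size in
(0.2, 50); burst frequency in (0.01, 30); mean expression in (0.01, 100);
and bootstrap `CI_high / CI_low` below 10^1.5 for both size and frequency.

### Likelihood-ratio test

For a change in burst frequency (or size) between two samples, the free
model fits all three rates per sample; the null shares the tested parameter
while the remaining rates stay sample-specific. Because the samples decouple
given the shared value, the constrained optimum is found by profiling: a
five-point grid between the two free estimates (±0.3 in log space) followed
by bounded scalar minimization, with warm-started two-parameter inner fits.
`lambda_LR = -2[l(theta0) - l(theta_hat)]` is referred to chi-squared with
1 d.f.; the decision thresholds are 3.84 (one-sided) and 7.68 (two-sided).
The 7.68 value is twice the one-sided threshold, a convention kept as
printed even though it is not the chi-squared 0.975 quantile (5.02); the
chi-squared survival p-value is reported alongside. Null calibration at 300
cells per sample puts the one-sided rejection rate near its nominal 5%.

### Inference-spread simulation

Given a reference fit and an observed mean fold-change `r`, frequency mode
sets `k_on <- r * k_on` and size mode `k_syn <- r * k_syn` (with `k_off`
fixed, the burst size scales by `r`); each of `n_sim` simulations draws the
experiment's cell count from the Beta-Poisson sampler and refits, producing
the cloud of estimates expected if the change were purely frequency or
purely size.

## Variability (CV²) machinery

CV² is the sample variance (n−1 denominator) over the squared mean, zeros
included over all QC-passing cells. Analyses are restricted to
non-imprinted, autosomal, separated transcriptional units. Each lncRNA is
matched to the `k = 10` protein-coding genes nearest in mean expression
(with replacement across lncRNAs); each of 10,000 permutations samples one
matched mRNA per lncRNA, and p is the frequency of permutations whose
median sampled CV² strictly exceeds the median lncRNA CV². All-tied inputs
are degenerate (p = 0 under strict '>') and flagged. Ranking against 100
matched mRNAs splits the pool 50 above / 50 below the lncRNA's mean. The
subsampling power analysis repeats the test 100 times per lncRNA count and
reports detection at the 50% and 95% criteria. Ties everywhere break by
lexicographic gene id.

## Decay normalization and fitting

Expression is first normalized per gene to its own t = 0 level; control
genes with known half-lives in (1, 8) h then set a per-timepoint, per-sample
normalization factor — the median of observed over expected
`exp(-k_control * t)` — correcting library-scaling distortions. Controls
with half-lives under 2 h are excluded at the 7 h and 10 h time points,
where their expected levels are too small to calibrate against. Per-gene
decay `y = a * exp(-k t)` is fitted by nonlinear least squares in original
space, initialized from the log-linear slope, so amplitudes away from one
are handled. Genes pass with half-life < 10 h (and burst duration < 72 h
downstream). Default time points {0, 2, 4, 7, 10} h.

## Cis-interaction discovery

Eligibility: ≥3 allelic reads in ≥20 cells, non-imprinted, autosomal,
allowed biotypes; candidate pairs are all lncRNA–mRNA pairs with TSSs
within 500 kb. Two routes:

- **Allelic score** (population level): per-gene allelic imbalance
  `AI = CAST/(CAST+C57) - 0.5` from reads aggregated over cells; pair score
  `AI_lnc + AI_mRNA - |AI_lnc - AI_mRNA|` ("diff" read as absolute
  difference — the only reading that makes the score a coordination
  measure). The null relocates each lncRNA to 1,000 random gene positions
  (drawn once, shared by all lncRNAs, each with ≥2 eligible genes in
  window) and re-pairs its AI with every eligible mRNA there;
  p = fraction of random pairs scoring ≥ the real score (ties count against
  the pair; no pseudocount — the minimum attainable p is reported).
  Significance at p < 0.05.
- **Fisher coordination** (single cell, per allele): detection is ≥3 allelic
  reads on that allele; the 2×2 co-detection table over cells is tested
  two-sided (BH-adjusted across pairs). The same relocations give each
  lncRNA a background of adjusted random-pair p-values; a pair is
  significant when adjusted p_real < 0.01 and fewer than 1% of its random
  pairs beat it. Calls are made per allele and summarized as union.

For ranking, alleles are aligned to the lncRNA's dominant allele before
scoring, so pairs jointly skewed toward C57 rank positive alongside jointly
CAST-skewed pairs, and discordant pairs rank negative.

## Cell-state association

Counts are normalized as `ln(1 + count/total * 1e4)`. Variable genes are
ranked by variance of trend-standardized values (local regression of log10
variance on log10 mean, z-scores clipped at sqrt(n_cells)); the top 50
cell-cycle genes feed PCA, and a principal curve (iterative
projection–smoothing, Hastie–Stuetzle) in the top-3 PC space assigns each
cell an arc-length coordinate. Two initializations are tried — PC1 for
linear structure and the angular position in the PC1–PC2 plane for closed
cell-cycle-like structure — keeping the one with the smaller projection
error. Phases are segmented by the dominant 15-cell rolling-mean marker
(Gas1 → G0, Ccnd1 → G1, Ccne2 → G1/S, Ccnb1 → G2/M; ties toward the earlier
phase in cycle order). Phase-specific genes come from one-way ANOVA
(BH-adjusted p < 0.01) with fold induction top-phase over rest. The
apoptosis route fits CV² against reciprocal mean with a gamma GLM
(identity link), ranks genes by observed/fitted CV², sends the top 75
apoptosis-list members to PCA and clusters cells with PAM k-medoids
(k = 3 by default; implemented here as BUILD+SWAP since no installed
library provides PAM). Differential expression between apoptosis clusters
uses a rank-sum test with BH adjustment as a documented stand-in for the
original external tool. Guilt-by-association retains genes with
|Spearman rho| ≥ 0.1 to the target (double-zero cells excluded per pair,
≥10 shared-expression cells) whose correlation sign is consistent with
their knockdown direction.

## Synthetic-data generators

The generators define the study conditions all tests run under:

- **Allelic dataset**: per-gene kinetics from log-normal priors (mRNA-like
  medians: `k_on` 2, burst size 6, `k_off` 10; sigma 0.5 on the log scale),
  chosen so the post-inference filter windows retain >90% of genes. The
  lncRNA-like class multiplies `k_on` by 0.25 and burst size by 0.5 — the
  fourfold frequency and twofold size shifts the pipeline is meant to
  recover. Both alleles share a gene's kinetics and are simulated
  independently; per-molecule binomial SNP capture produces the
  assignment-missing pattern (capture probability 1.0 by default for
  inference tests; lower it for sensitivity runs).
- **Cis pairs**: the lncRNA and mRNA of a pair share their latent promoter
  state in a fraction rho of cells per allele, coupled comonotonically
  through a common uniform quantile so the marginals are exactly preserved.
  Coordinated allelic imbalance is planted by scaling the allelic `k_syn`
  (total mean preserved). Dataset defaults keep planted pairs a small
  minority of eligible mRNAs (10 linked lncRNAs among 60, six background
  mRNAs per locus), as in real data where cis-linked pairs are rare — at
  high planted density the relocation null itself becomes contaminated.
- **Decay time course**: `a * exp(-lambda t)` with optional per-timepoint
  scale distortions and log-normal noise; control genes are the subset with
  true half-lives in (1, 8) h.
- **Cell cycle**: cells on a circular latent coordinate; marker means peak
  in their phase arc with a von Mises-shaped bump; optional planted
  phase-specific genes among a Poisson noise background.

What the generators do *not* emulate: transcript-length/GC bias, doublets,
batch effects, empirical depth variation, or bursty kinetics of the
cell-cycle markers themselves. Passing tests therefore demonstrate that the
machinery recovers the structures it assumes, at realistic sizes — not that
real libraries satisfy those assumptions.

## Validation experiment sizes

The validation suite (`burstlnc.validation`, exercised by
`tests/test_acceptance.py` and `scripts/acceptance.py`) runs at sizes chosen
for a single CPU: bootstrap coverage over 100 genes (40 in the script) at
1,000 cells with 80 replicates; class-ratio recovery over 60+60 genes at
500 cells; LRT calibration over 300 null replicates at 300 cells per sample
and power over 50–60 replicates at 1,000 cells; inference spread over
60–100 simulations; CV² null uniformity over 50 runs at 1,000 permutations;
cis discovery at 200 random placements; decay over 30 genes; state
association over 400 cells with 500 null genes. Tolerances are those stated
with each check, never adjusted to the sizes.

## Known limitations

- The LRT's asymptotic chi-squared reference is approximate at a few hundred
  cells; its measured size sits near, not exactly at, the nominal level.
- The principal curve is open; on a closed cell-cycle loop the coordinate
  has a seam where the curve begins and ends.
- The bootstrap treats cells as exchangeable; structured heterogeneity
  (e.g., cell-cycle phase) is not stratified.
- Burst-duration conversion assumes the decay rate measured in bulk applies
  uniformly across cells and alleles.
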