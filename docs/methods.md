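# Methods

## Model

One curve is fitted per drug–cell-line pair to all dose–response points
pooled across datasets. The dose axis is log2 of the concentration in µM —
the natural scale for the base-2 logistic

    f(x) = 1 / (1 + 2^(-k (x - a))),

whose center `a` is then directly the log2 IC50, and for the center's prior
(mean 0 on the log2 scale puts the prior median IC50 at 1 µM). Responses are
normalized inhibition fractions: 0 at the negative-control (untreated) level,
1 at the positive-control (fully inhibited) level, computed as
`(neg − signal) / (neg − pos)` and clipped to [0, 1]. The likelihood is
Student-t with scale σ and degrees of freedom ν so that single aberrant wells
— frequent in pooled multi-dataset data — do not drag the curve.

The hierarchy, in the precision parameterization (variance = 1/precision):

| parameter | prior | role |
|---|---|---|
| a | Normal(a_µ, sd a_σ) | curve center, log2 µM |
| a_µ | Normal(0, precision 1) | shared center location |
| a_σ | Uniform(0.01, 5) | center spread; absorbs cross-dataset discordance |
| k | Gamma(shape k_r, rate k_λ) | slope, constrained positive |
| k_r | Normal(1, precision 0.01), truncated > 0 | slope shape hyperprior |
| k_λ | Normal(2, precision 0.01), truncated > 0 | slope rate hyperprior |
| σ | Uniform(0.01, 0.1) | t scale (response units) |
| ν | Normal(250, precision 0.001), truncated > 0 | t dof; 250 ≈ near-Gaussian unless data demand tails |

The normal hyperpriors on ν, k_r and k_λ formally admit negative values that
lie outside the support of a t dof or gamma parameter; they are truncated to
(0, ∞) as the minimal correction. The truncation constants are fixed, so the
log-posterior omits them; the uniform priors keep their normalization so the
density matches an externally coded term-by-term sum exactly.

## Sampler

Adaptive Metropolis-within-Gibbs: one Gaussian random-walk update per
parameter per sweep, 3 chains × 5000 sweeps with 500 burn-in. Proposal scales
adapt toward 44% acceptance in 50-sweep windows **during burn-in only**, so
the retained draws come from a fixed kernel. Initialization is deterministic:
`a` at the dose whose observed response is closest to 0.5, `k = 1`,
`σ = 0.05`, `ν = 250`, hyperparameters at their prior means (a_σ at its
mid-bound). Per-chain RNG streams are spawned from the master seed via
`numpy.random.SeedSequence`, making every fit bit-reproducible.

Point estimates are the argmax of a Silverman-bandwidth Gaussian KDE on a
512-point grid over the pooled post-burn-in draws (per-chain modes would be
ambiguous to combine). Intervals are 95% highest-density intervals: the
shortest window of the sorted draws containing ⌈0.95 n⌉ samples, leftmost on
ties. Convergence is monitored by classic split R̂ on `a` and `k`; values
above 1.05 raise a `poor_convergence` flag but results are still returned —
in a batch over many pairs a flagged fit is information, not an error.
`run_mcmc` can pin any subset of parameters (`frozen=`), which is how the
reduced-model quadrature oracle conditions on σ, ν and the hyperparameters.

## Sensitivity scores

All five scores are deterministic functions of (a, k) and the observed dose
window [x_min, x_max], so each is evaluated on every posterior draw to give a
95% HDI; the reported point value uses the posterior-mode parameters.

* IC50 = a; IC90 = a + log2(9)/k.
* AUC = mean of f over [x_min, x_max]. The window is the pair's observed
  pooled range, and normalizing by its width puts AUC in (0, 1) and makes it
  comparable across pairs; since f is inhibition, higher AUC = more
  sensitive. The public `auc` computes a ≥1001-point trapezoid per its
  contract; per-draw scoring uses the closed-form antiderivative
  log2(1 + 2^{k(x−a)})/k (numerically a shifted softplus), which agrees with
  the trapezoid to < 1e−6.
* Einf = f(x_max). The logistic's asymptote is always 1, so "maximal
  response" is only informative restricted to the tested range. The value is
  clamped to the open interval (0, 1) where floats would saturate.
* EC50 solves f(x) = Einf/2: a − log2(2/Einf − 1)/k.

IC90 and EC50 are reported even when they land outside the tested window,
with an extrapolation flag — resistant pairs necessarily extrapolate.

## Biomarker associations

Inputs are the per-pair pooled IC50s, a mutant-flag table (non-silent coding
mutations at allele frequency ≥ 0.2, inclusive; any passing call makes the
(gene, cell line) mutant) and a genes × cell-lines TPM matrix. Mutation
effects use the two-sided Wilcoxon rank-sum test, run only when both the
mutant and wild-type groups hold at least 10 cell lines; the effect size is
the median IC50 difference (mutant − wild-type, log2 µM; negative = mutants
more sensitive), with the rank-biserial correlation alongside. Expression
effects use Spearman correlation (robust to the outliers that wreck Pearson
on IC50s), gated at ≥ 10 overlapping cell lines of which ≥ 5 express the
gene at TPM ≥ 1 — below that the gene is noise-floor background. Any
cancer-type restriction is applied **before** the gates, so the thresholds
refer to the cohort actually tested. Rank-sum p-values are exact
(enumeration-equivalent) for tie-free combined sizes ≤ 14, otherwise the
normal approximation with tie and continuity corrections. Scans append
Benjamini–Hochberg q-values per test type as a convenience; raw p-values are
the primary output and are always retained. Gated-out pairs are returned as
skipped records with the reason, never dropped silently.

## Synthetic data

`simulate_experiment` inverts the fitting model: y = clip(f(x; a + shift_d,
k) + σ·t_ν, 0, 1) on per-dataset dose grids. Defaults emulate the pooling
regime of the public screens: one 9-point grid over [−4, 4] and one 7-point
grid over [−2, 6] log2 µM (offset windows, so pooling broadens the observed
range), σ = 0.05, ν = 250, one replicate per dose. A per-dataset center
shift (e.g. +2 log2 units) produces the discordance regime.
`simulate_cohort` plants drug–gene structure: Bernoulli(0.5 by default)
mutant flags shifting IC50 additively, log-normal TPM (log-mean 2, log-sd 1,
so a typical gene is clearly expressed while the lower tail exercises the
TPM gate) entering IC50 through its standardized log level, Gaussian IC50
noise of sd 0.5 log2 µM — effect sizes and noise chosen to match what a
40-line pharmacogenomic cohort with a strong biomarker looks like.
`simulate_cohort_experiments` then emits one dose–response experiment per
cell line centered at its true IC50, which is what lets the full
simulate → fit → biomarkers pipeline run end to end.

What the generator does **not** emulate: assay-chemistry differences between
real datasets, plate/batch effects, heteroscedastic noise across the dose
range, correlated mutations or co-expression between genes, and real
cancer-type structure. Passing tests therefore demonstrate correctness of
the inference machinery under the stated model, not robustness to every
artifact of real screens.

## Numerical choices and degenerate inputs

* Logistic evaluation goes through the overflow-safe sigmoid; µM
  back-transforms saturate to inf/0 rather than overflow (near-flat fits can
  put extrapolated IC90s at astronomically large log2 doses).
* Normalized responses outside [0, 1] are clipped (out-of-range policy for
  control-normalized signals is a convention; clipping is reported per read).
* Replicate wells are kept as individual points — the likelihood handles
  replication; averaging would discard the within-dose spread.
* A pair with one point (or one distinct dose) is fitted but flagged
  `low_information`; constant responses leave the slope pinned at its lower
  support edge and the center unidentified, which the flags and wide HDIs
  surface.
* Exact float round-tripping of CSVs (`%.17g` on write, `round_trip` parsing
  on read) is what makes the pipeline byte-reproducible.
* Known bias: because simulated (and real, control-normalized) responses are
  clipped to [0, 1], wells near the asymptotes are pulled slightly inward,
  biasing the fitted top of the curve down by a hair. Center (IC50) coverage
  is unaffected in testing (≥ 18/20 at nominal 95%), but tight functionals
  like AUC show mild undercoverage (16/20 in the fixed-seed recovery suite).

## Problem sizes

The test and acceptance runs use the settings above throughout: recovery and
discordance checks run 20 simulated experiments / 20 paired experiments at
the full 3 × 5000 MCMC settings (~1 s per fit); the quadrature oracle uses a
1401 × 1200 (a, k) grid; null calibration runs 600 association tests on a
40-line, 300-null-gene cohort; the byte-determinism check runs the pipeline
twice over a 24-line cohort at reduced iterations (600), since byte identity
is independent of chain length.
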