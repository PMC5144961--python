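# Methods

This note records the statistical models, the numerical choices, and the
limits of what the synthetic-data tests demonstrate.

## Design semantics

A hemiclone line clones a haploid chromosome complement: X-lines share one
X copy, A-lines share one AII+AIII pair. Among-line variance V_L therefore
estimates **half** the additive genetic variance carried by the cloned
complement in diploid condition, so V_A = 2·V_L — except for X-lines
measured in males, where the cloned X is hemizygous and V_A = V_L. These
conversion rules, the phenotypic sum V_P = V_L + V_V + V_R, the
mean-standardized CV_A = √V_A/mean, and r_MF = Cov_MF/√(V_LF·V_LM) are the
package's derived-statistics layer (`quantgen`). All derived quantities
are computed **per retained posterior sample** and only then summarized;
plug-in values from posterior means are exposed separately
(`quantgen.plug_in_cell`) because published tables mix both conventions.

Cross-model contrasts (X vs. A) come from independently fitted chains, so
samples are paired by a seeded random permutation (`chain_difference`),
and ratio posteriors — which inherit heavy right tails from near-zero
denominators — are summarized by median and interquartile range, with
non-positive denominators dropped and counted rather than clamped.

## Lifespan model

Individual lifespan, one record per fly, is Gaussian with sex-specific
grand means, centered batch dummies crossed with sex (intercept = grand
mean), a line random effect with unstructured 2×2 cross-sex covariance G,
per-sex vial variances, and per-sex residual variances; vial and residual
cross-sex covariances are structurally zero because a vial and a fly carry
one sex only. Because the vial effect absorbs genotype-by-batch
interaction (one vial per line × batch), the line variance is a clean
between-line component.

### Gibbs sampler

All responses are Gaussian, so with parameter expansion every conditional
is conjugate and the sampler is blocked Gibbs (`mixed_model.run_gibbs`):
fixed effects | line effects (working scale) | expansion scales | line
covariance (inverse-Wishart) | vial effects/scales/variances | residual
variances. Parameter expansion writes u = Λη with Λ = diag(λ_F, λ_M),
λ_s ~ N(0, 10⁶), η ~ N(0, G_w), G_w ~ IW(ν = 2, identity scale); the
reported G = ΛG_wΛ is positive semidefinite by construction for every
retained sample. Residual variances carry IW(ν = 0.002, scale 1) priors.
The expansion keeps mixing healthy when a line variance is near zero
(the female X is the relevant case). The prior scale matrices are not
dictated by the design, so identity scales were adopted and a sensitivity
hook (`PriorSpec.line_nu`) is provided; posterior line-variance means move
by far less than one posterior SD between ν = 0.002 and ν = 3 on
study-condition data.

Fixed effects, line effects and vial effects are constant within a vial,
so the sampler runs on vial-level sufficient statistics (count, mean,
within-vial sum of squares; `design.build_collapsed`). This makes an
iteration O(vials) rather than O(flies): a 30,000-iteration chain on the
full 16,000-fly, 320-vial line-type dataset takes a few seconds.
Chain lengths: the full-scale convention is 1.1M iterations / 100k
burn-in / thin 1000; the package's desk-scale default
(`ChainConfig.reduced()`) is 30k/5k/25, which retains the same 1000
samples and passes the same convergence bar on study-condition data.

Correctness anchors: (i) on a balanced one-way layout with known residual
variance and the plain inverse-Wishart prior, the sampler's posterior mean
of V_L matches a dense-grid quadrature of the 1-D marginal posterior;
(ii) on full-design simulations at the study-condition components, 95%
credible intervals cover every generative component at nominal rate;
(iii) posterior means agree with REML within 5% on large designs.

### Convergence

`gelman_rubin` implements the classical potential-scale-reduction factor
with the degrees-of-freedom adjustment and an upper 95% limit from the F
quantile of the between/within variance ratio; parameters are flagged
above 1.05. Duplicated (zero-between-variance) chains degenerate to
PSRF ≈ 1 and are reported, not rejected.

## Aging model

The Gompertz hazard µ(t) = α·e^(βt) is fitted per vial from the 48-h
census schedule by maximizing the interval-censored log-likelihood
ℓ = Σ_j d_j·log[S(t_{j−1}) − S(t_j)] + c·log S(t_J),
with S(t) = exp(−(α/β)(e^(βt) − 1)) and a series form below |β| < 1e−8 to
avoid 0/0 at the exponential limit. The right-censoring term is included;
under the reference design essentially all flies die, so it is usually
zero. Optimization is on (log α, β) — enforcing α > 0 and taming the skew
of α — from a 3×3 multi-start grid (β ∈ {0.02, 0.08, 0.2} crossed with
log-α offsets around a moment-matched baseline), Nelder–Mead then a BFGS
polish, because small-cohort likelihoods can be flat in β. Standard
errors come from the finite-difference observed information at the
optimum; `se_alpha` is delta-method transformed from `se_log_alpha`, and
recovery checks compare α on the log scale where the sampling distribution
is near-normal. A fit is `converged` only if the gradient norm is small
and the observed information is positive definite; schedules with deaths
in fewer than two intervals are flagged `beta_unidentifiable`.

Intervals are half-open (start, end] with t = 0 at assay start; the age
origin shifts α's absolute scale but not β. β is reported both per day
and ×100 (the aging analysis scale, which keeps variances well
conditioned). Two-step analysis: per-vial β̂ × 100 values re-enter
`run_gibbs` with the vial term switched off — one code path, one flag.
Gompertz–Makeham and logistic-mortality variants are out of scope.

## REML and likelihood-ratio tests

`reml.reml_fit` maximizes the restricted log-likelihood directly over
log variances and atanh-correlations (validity by construction), with a
Woodbury-style per-line factorization on the same vial-level sufficient
statistics: per line, the vial-mean covariance is
diag(V_V,s + V_R,s/n) + Z G Zᵀ, an 8×8 solve at the full design. Line
types enter as independent blocks of one joint parameter vector, so null
hypotheses that tie parameters across blocks are imposed by
**reparameterization**: X:A female line-variance ratio fixed to a genome
share (euchromatin 18.8% or gene content 15.6%), male X additive variance
equal to female X (V_L,MX = 2·V_L,FX; optionally mean-standardized to
equate CV_A), one shared cross-sex correlation, or a named line variance
pinned at zero. L-BFGS-B is followed by a bounded Nelder–Mead polish;
finite-difference gradients alone leave ~1e−5 relative error, the polish
reaches the ~1e−7 agreement with closed-form balanced-design ANOVA
estimators that the oracle tests require.

LRT: X² = 2(ℓ_full − ℓ_constrained) against χ²_df — the reporting
convention for these variance tests — with the conservative
0.5χ²₀ + 0.5χ²₁ boundary mixture available behind a flag. Under the null
the χ²₁ convention is conservative (empirical size ≈ 1–3% at nominal 5%);
at study-scale line variance (V_L = 15 against V_R ≈ 74, 40 lines) power
is essentially 1. Univariate per-sex × type line-variance tests
(`line_variance_test`) drop the cross-sex correlation entirely, mirroring
the practice of testing single variances in univariate fits.

## Outlier procedure

Female per-vial mean lifespans below 51 d (strict; ties kept) are
flagged, with a histogram dip diagnostic reported alongside since the rule
encodes a visual bimodality judgment. The genetic-association check
removes flagged vials, computes female line means, and compares lines
without a flagged vial against lines with one by a **pooled-variance**
one-tailed t-test (df = n₁ + n₂ − 2; the pooled form is what integer df
of 38/78 for 40/80 lines implies), direction "without > with". The
pipeline runs with and without removal and reports both. Whether the
threshold applies per batch or pooled is not specified by the source
design; pooled per-vial means are used.

## Synthetic data

The generator (`synthetic`) emulates the assay, not the biology of the
crossing scheme: lines are i.i.d. bivariate-normal draws from G (no
recombination, no balancers), vials and residuals are Gaussian, and
default parameters are the published component estimates themselves
(`reference.TABLE1`), so simulated data match the study's variance
structure cell by cell. Specific choices:

* **Batch effects** are not published; defaults are a ±2 d sex-shared
  spread summing to zero — large enough to exercise the fixed-effect
  machinery, small relative to V_R.
* **Negative lifespans** (admitted by the Gaussian model, impossible in
  life) are truncated at 1 d and counted; at study-condition parameters
  this touches a negligible fraction of draws, keeping the Gaussian fits
  essentially exact and interval censoring well defined.
* **Aging cohorts**: per-vial β × 100 is grand mean + line effect + vial
  deviation (variances from the reference aging components); log α is
  drawn conditionally on β with correlation −0.9 (SD 0.6), centered so
  each sex × type reproduces its reference mean lifespan — mirroring the
  strong negative log α–β dependence of demographic data. Fitted vial-level
  residual variances exceed the generative vial deviation by the β̂
  estimation variance; the observed log α̂–β̂ correlation is attenuated
  toward ≈ −0.75 by the same noise.
* **Outlier vials** are injected uniformly at random across lines
  (shift 25 d, floored) — encoding the verified null of no genetic
  association; `genetic_outliers=True` draws affected vials only from the
  shortest-lived 30% of lines, for power checks of the association test.
* **Seeds**: one master seed, children spawned deterministically per
  stage (`numpy` SeedSequence), so identical seed + configuration gives
  byte-identical tables.

What passing tests do **not** show about real data: the generator is the
fitted model, so model misspecification (non-Gaussian lifespans,
heteroscedastic vials, batch-by-line structure beyond the vial effect,
unmeasured common environment) is untested by construction; interval
coverage and LRT calibration statements are statements about the model's
self-consistency at the published parameter values.

## Problem sizes and right-censoring

Test and acceptance runs use the full 40-line, 50-fly design where the
statistic under test depends on it (coverage, LRT calibration, outlier
recovery) and reduced designs elsewhere; chain lengths default to
30k/5k/25. The assay's treatment of flies surviving past the last census
is not documented; the likelihood includes the censoring term, and the
simulator's `max_age` (default 150 d) makes censoring negligible at
realistic parameters.
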