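# Methods

This note documents the statistical machinery implemented in
`stroopdelta`, the choices made where the design was genuinely open, and
what the synthetic validation does and does not establish.

## Problem and data model

The package analyses trial-level reaction times (RTs) from spatial
Stroop experiments in which a lateralized target (a face, a pair of
eyes, or an arrow) points left or right while appearing on the left or
right of the screen; location is task-irrelevant, so trials are
congruent or incongruent. Arrow targets typically show a standard
congruency effect (SCE: incongruent slower), whereas gaze/face targets
can show a reversed effect (RCE: incongruent faster). Because single
studies are underpowered for distributional questions, the intended
input is a pooled multi-study cohort: participants are nested in
studies, and each study contributes one or more target types.

## Preprocessing

The fixed pruning order is: (1) exclude participants whose non-response
proportion is at or above a threshold (default 0.50 — only extreme
cases such as a ≈64% non-responder are meant to be caught; the
threshold is configurable because no canonical value exists);
(2) keep responded trials; (3) keep RTs inside the closed window
[200, 1300] ms ("trimmed" mode; "nontrimmed" keeps all responded
trials as a robustness variant); (4) keep correct responses. The
retained set is order-invariant for these filters; the fixed order only
attributes removals to rules deterministically. Boundary RTs are
retained because the window is defined by removing trials *strictly
faster/slower* than the cut-offs. Cells (participant × target ×
congruency) with fewer than 10 retained trials are excluded from
quantile estimation with a warning.

## Quantile engine

Per-participant condition quantiles use the Hyndman–Fan Type-8
estimator, h = (n + 1/3)p + 1/3 with linear interpolation between order
statistics and h clamped to [1, n]; it is median-unbiased and
distribution-free, which matters for skewed RT data. The default
probability grid is (.1, .3, .5, .7, .9); quartile-style and
decile-style grids ((.125, .375, .625, .875) and (.05, .15, …, .95))
are provided for robustness analyses, and any strictly increasing grid
in (0,1) is accepted. The delta function is the incongruent minus the
congruent quantile at the same probability, per participant; its
abscissa (`mean_rt`) is the mean of the two parent quantiles — the
standard delta-plot x-coordinate. Group curves are vincentized
(arithmetic means of participant-level quantiles or deltas). Ties are
handled by order-statistic interpolation; no jitter is added.

## Mixed models

Three models with study-nested random intercepts are fitted by
restricted maximum likelihood:

- RT model: `q_rt ~ target*congruency + target*qq + congruency*qq +
  (1|study:participant) + (1|study:target) +
  (1|study:target:congruency:qq)`
- delta model: `delta ~ target*qq + (1|study:participant) +
  (1|study:target) + (1|study:target:qq)`
- trend model: `delta ~ target*poly(meanRT, 2) + (1|study:participant)
  + (1|study:target) + (1|study:target:qq)`

`qq` is the quantile probability treated as an unordered factor (five
levels by default); a continuous treatment appears only in the trend
model. The engine (`stroopdelta.mixedlm`) handles arbitrary
random-intercept (variance-components) structures: the residual
variance is profiled out, the variance ratios are optimised on the log
scale by bounded L-BFGS-B (relative tolerance ~1e-12, fixed start with
every component equal to the residual; a derivative-free Powell polish
runs when the quasi-Newton line search stalls at the zero-variance
boundary), and all per-iteration algebra goes through the Woodbury
identity so cost scales with the number of random-effect levels.
Zero-variance (singular) fits are flagged, not fatal — they are the
expected outcome for degenerate test fixtures. The third random term of
the printed trend model groups on a continuous covariate; it is
implemented as a random intercept per study × target × quantile-point
cell, which is its practical effect on these datasets.

Fixed factors are sum-coded, so term-wise F tests on coefficient blocks
are Type-III-style tests and the intercept is the equally weighted
grand mean.

### Degrees of freedom

Denominator df use the Satterthwaite approximation rather than
Kenward–Roger: for a contrast c, df = 2f²/(g'Ag) with f = c'Cov(β̂)c,
g its finite-difference gradient in the variance parameters, and A the
inverse observed REML information (finite-difference Hessian).
Multi-row F tests combine per-eigencontrast df (the Fai–Cornelius
recipe used by lmerTest). Point estimates — coefficients, EMMs, deltas,
contrasts — are unaffected by this choice; only df and hence p values
differ slightly from KR, and the df method is recorded in every output
table and manifest. Components estimated at the boundary are excluded
from nothing; the pseudo-inverse absorbs the singular information
matrix.

### Stepwise reduction

The RT and delta models undergo backward elimination at α = .05 on
term-level F tests: at each step the least significant *removable*
fixed term (not contained in a retained interaction) is dropped and the
model refitted; random terms are never removed; the trend model is
never reduced. The elimination log is persisted in the run manifest.

### EMMs, contrasts and effect sizes

Estimated marginal means average model predictions over the equally
weighted reference grid of factor-level combinations (covariates at
their centered mean); with unbalanced data this deliberately differs
from pooled raw means. Pairwise contrasts use Tukey HSD via the
studentized-range distribution (family size = number of means
compared); one-sample contrasts of delta EMMs against zero use
Bonferroni (both p values and CIs adjusted). Standardized effect sizes
follow the Westfall convention: the contrast divided by the square root
of the sum of *all* variance components including the residual.
Partial eta squared for ANOVA terms is F·df1/(F·df1 + df2).

### Trend analysis

The delta-plot abscissa is centered within target type (published
delta-plot trend analyses rarely specify centering; within-target
centering makes each
target's linear coefficient its slope at its own mean latency and
decorrelates the polynomial terms). An orthonormal quadratic basis (QR
on the centered Vandermonde matrix, signs fixed so leading coefficients
are positive — the same convention as R's `poly`) is fitted; reported
coefficients are back-transformed to the raw scale (ms of delta per ms
and per ms² of meanRT). The two parameterizations are exact
reparameterizations: fitted values agree to 1e-8 by construction, which
the tests verify. Pairwise coefficient differences are
Bonferroni-adjusted within each polynomial degree (three pairs).
Quadratic coefficients are reported with their estimated sign and CI;
no sign is assumed a priori.

## Synthetic cohort generator

The generator exists so every downstream stage can be validated against
closed-form truth. Congruent RTs for a participant × target are
ex-Gaussian, X ~ exG(μ, σ, τ); incongruent RTs are the monotone warp
g(X) = X + δ(F(X)) of an independent draw, with δ(p) = a + bp + cp² a
percentile-indexed congruency shift. Because g is strictly increasing
(verified at construction on a 10⁴-point grid spanning baseline
quantiles 1e-4..1−1e-4; violating profiles are rejected), the
population q-quantile of the incongruent distribution is exactly
Q_cong(q) + δ(q). Additive study and participant offsets (drawn once
per unit) shift both conditions equally and cancel exactly in the
delta. Non-responses are missing RTs; errors follow a flat rate;
contaminated RTs are uniform draws outside the 200–1300 ms window.

Defaults emulate a pooled cohort of the kind the package targets: 11
studies × 64 participants (≈ 700 participants), 48 trials per cell;
baselines arrows (380, 40, 110) ms and face/eyes (460, 45, 140) ms,
placing the social targets ≈ 100 ms slower; profiles arrows
(28, 5, 1) — flat positive, quantile-mean ≈ +31 ms — and face
(11.6, −122.2, 60) / eyes (8.65, −91, 45) — null at p=.1, increasingly
negative and saturating, quantile means ≈ −30 / −22 ms. These defaults
were chosen once to mirror the magnitudes and shapes reported for real
spatial-Stroop cohorts and are illustrative emulation settings, not
empirical claims.

What the generator does *not* emulate: mechanistic evidence
accumulation (no diffusion-model-for-conflict dynamics), RT-dependent
accuracy (conditional accuracy functions), heterogeneous trial counts
within a study, or drifts/sequential effects within a session. Passing
recovery tests therefore show the *pipeline arithmetic and inference*
are correct under a known percentile-shift model, not that any
particular psychological mechanism holds in real data.

## Validation design and problem sizes

- Quantile estimator: equivalence with an independent brute-force
  Type-8 transcription (and numpy's `median_unbiased` rule) on 10³
  random sample/probability pairs at 1e-9.
- Delta recovery: 200 participants × 400 trials/cell with
  δ(p) = 40 − 80p recovers (32, 16, 0, −16, −32) ms within 3 ms by
  vincentized deltas.
- Trend coverage: 50 replicates at 20 participants × 100 trials/cell;
  the 95% CI of the linear coefficient must cover the truth in ≥ 90% of
  replicates. These replicates use zero study/participant offsets so
  the truth is the exact population projection of (meanRT(p), δ(p))
  onto the quadratic basis at the design probabilities; offsets would
  blur the abscissa (their cancellation in delta is tested separately).
- Calibration: 1000 null replicates of a balanced three-condition
  within-participant design (12 participants × 2 replicates); the
  fit→ANOVA rejection rate at α=.05 must lie in [.035, .065].
  Variance-component recovery is checked at 20 studies × 20
  participants × 4 observations (participant SD 40 ms, study SD 30 ms,
  residual 60 ms) within 15% averaged over 50 seeds.
- Cross-check: the REML engine is compared against statsmodels'
  MixedLM (independent implementation) on a nested two-component
  fixture.

All simulation sizes are the package's own validation choices, balanced
between Monte-Carlo resolution and a test suite that runs in minutes on
one core.

## Known limitations

- Satterthwaite, not Kenward–Roger, df (see above); for the small
  numbers of studies typical of pooled cohorts, KR p values can be
  slightly more conservative.
- Random intercepts only; random slopes and crossed (non-nested)
  structures are out of scope.
- The EMM reference grid weights all factor-level combinations equally;
  other weighting schemes for unbalanced multi-study grids are not
  implemented.
- The generator's flat error rate cannot produce accuracy-based
  distributional effects; accuracy enters only as a pruning rule.
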