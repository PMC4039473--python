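# Methods

This note documents the models implemented in cfskit, the parameter
choices that matter, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would want to know.
Every number quoted here is computed by the test suite or the example
scripts; nothing is asserted that the code does not reproduce.

## Stimuli

Three stimulus classes share one display geometry: a bounding square of
7.32° rendered at a configurable pixel density (default 128-px frames,
i.e. ~17.5 px/°), 150 square elements of 0.46°, a 5.5° virtual target
region, 60 Hz.

**Moving Mondrian mask (MMM).** Elements translate at a common speed
(1–8 °/s) along one of six canonical directions (±x, ±y, and the two
diagonals), exactly 25 elements per direction when 150 elements are
used. Colours (red, green, blue, yellow) are distributed as evenly as
possible within each direction group — 25 elements over 4 colours gives
counts (7,6,6,6), and the colour receiving the extra element rotates
across groups so no colour is globally over-represented. Initial
positions are uniform within quadrants under a (38,38,37,37) allocation
(which quadrants receive 38 is seed-randomised); this prevents blank
display regions at trial start. Elements leaving the bounding square
wrap toroidally, preserving their trajectory. Overlap is resolved by
draw order (later list index occludes earlier).

**Regular CFS.** The same element field is redrawn at independent random
(quadrant-balanced) positions with random colours at the refresh rate,
default 10 Hz; each layout is held for round(frame_rate/refresh_rate)
frames — exactly 6 at 60 Hz.

**Target.** A disc of 0.46° diameter traverses right-to-left at its
speed on one of six horizontal paths (three above, three below fixation,
adjacent paths separated by twice the target size, symmetric about
fixation). Contrast ramps linearly from 1/20 of the requested contrast
on frame 1 to full contrast on frame 20 — the simplest monotone ramp —
and stays constant. Trial durations are explicit parameters per
condition (3.6 s for the 3 °/s single-target design; 5.5 s and 2.2 s for
the 2 °/s and 5 °/s designs): the implied traversal distances differ by
~2 % between designs, so no attempt is made to derive duration from
geometry.

Coordinates are continuous degrees, origin at the frame centre, y
upward; rasterisation rounds to the nearest pixel on a 0-based
row-major grid. Colours render at full saturation in the unit RGB cube
on a mid-gray (0.5) background; grayscale conversion uses Rec. 601 luma
weights (0.299, 0.587, 0.114), and the gray rendering path is exactly
the luma of the RGB path. All generators are pure functions of
(parameters, seed).

## Retinotopic adaptation model

**Filters.** Two odd-symmetric (sine-phase) Gabor kernels at 0° and 90°
with envelope s.d. σ = (λ/π)·sqrt(ln2/2)·(2^b+1)/(2^b−1), bandwidth
b = 1 octave by default, kernel side ceil(4σ) forced odd (σ ≈ 2.25 px,
9×9 kernels at the default λ). The nominal tuning target is the Nyquist
frequency of the pixel grid (λ = 2 px), but an antisymmetric kernel
sampled at integer offsets has *zero* energy at Nyquist — sin(πn) = 0
for every integer n — so the default carrier is λ = 4 px, the shortest
wavelength an odd-symmetric integer-grid kernel can represent. λ and b
are configurable.

**Response alphabet.** Per pixel, the larger absolute filter response
wins; if it is below ε the pixel is *none*, otherwise the label is the
winning orientation with the response's sign: five categories in total
(H+, H−, V+, V−, none). ε defaults to 5 % of the bank's peak response to
an ideal full-contrast step edge (computed numerically at bank
construction by probing every edge offset within the kernel support).

**Dynamics.** Each pixel carries four activations (one per non-none
category) starting at 1. Per frame (Δt = 1/60 s), the category matching
the pixel's current label decays multiplicatively by exp(−Δt/τ_d) with
τ_d = 4 s; every other category relaxes toward 1 with factor
exp(−Δt/τ_r), τ_r = 6 s. Both orientation and polarity must repeat for
decay to continue. These discrete updates telescope to the continuous
closed forms exactly: 240 stimulated frames give e⁻¹ of the initial
level, and 360 unstimulated frames recover a fully adapted location to
1 − e⁻¹ (asserted to 1e-12 in the tests). Activations are clamped to
[0, 1]; fields reset to 1 at each trial start (trials are independent).

**Summary statistic.** The default per-trial summary is the adapted
*stimulus strength*: per frame, the mean activation of the currently
driven category over the stimulated locations (1 when nothing is
stimulated), time-averaged over the trial. Higher values mean the mask
keeps landing on fresh detectors (less adaptation). Two variants sit
behind `summary_mode`: `all_categories` (time-averaged mean of the whole
activation field, normalised by pixels × 4) and `final` (the same at the
last frame only).

The default was chosen after measuring both candidates. The
all-categories mean is condition-insensitive to first order: every mask
condition stimulates nearly the same number of pixel-frames per trial,
and each stimulated frame removes nearly the same activation increment,
so conditions differ only through second-order saturation/recovery
terms (~5·10⁻⁵ at desk scale) whose sign flips with resolution and
trial duration. The driven-category strength is first-order sensitive —
it directly measures how adapted the detectors are that the mask is
currently driving — and separates the moving-mask speeds by ~100× the
Monte-Carlo error.

**Measured ordering at desk scale** (128 px, 1 s trials, 99 trials per
condition; the acceptance suite recomputes this): mean strength
0.9645 (1 °/s) < 0.9715 (2) < 0.9741 (3) < 0.9761 (5) < 0.9771 (8 °/s),
regular CFS 0.9699. The monotone increase over moving-mask speeds is
robust at every scale examined (64–256 px, 0.5–3.6 s). Regular CFS,
however, sits between the 2 and 4 °/s masks rather than above the
fastest mask: each 10-Hz layout is held for 6 frames and adapts its own
detectors during the hold, while an 8 °/s sweep (≈2.3 px/frame at desk
scale) lands on effectively fresh detectors every frame. Within this
model class we found no aggregation under which a 10-Hz refreshing mask
out-scores a fast smoothly-sweeping one; treat the CFS-vs-fastest-mask
comparison as model-class-sensitive rather than a settled prediction.
The corresponding clause of the acceptance suite's ordering test is
expected to fail and is left failing rather than weakened.

Simulation defaults: 999 trials per condition at full scale; the
acceptance-scale runs use 99 trials and 1 s, which the tests state
explicitly. 824-px frames (the full-scale geometry implied by 412
cycles/image) are available by setting `pixels_per_degree = 824/7.32`
but are not the default.

## Staircase psychophysics

Levels are log10 contrast with a 0.05 log-unit step, clamped to
[10⁻⁴, 1] contrast. Each staircase starts in an accelerated one-up
one-down regime (every correct response lowers the level) until the
first error, which switches it permanently to the main one-up two-down
regime: up one step after every error, down one step after two
consecutive correct responses. The rule's equilibrium satisfies
p(correct)² = ½, i.e. 70.71 % correct. Reversal levels are recorded at
every direction change.

Sessions run two staircases per condition from distinct start levels
(defaults: maximum contrast and 10⁻² contrast), randomly interleaved;
with six mask conditions and 65 trials per staircase a session is
780 trials, and two blocked target speeds double it to 1,560. Target
paths are balanced within each staircase. Blocking order follows the
supplied target-speed sequence; counterbalance across participants by
permuting it.

Simulated observers use a cumulative Weibull,
p = γ + (1 − γ − λ_l)(1 − exp(−(c/α)^β)), with γ = 0.5 (two-alternative
above/below judgement), slope β = 3.5 and lapse 0.01 by default; any
monotone psychometric works.

**Thresholds** are the mean of a staircase's last 20 trials. Averaging
is done in linear contrast by default (`space="log"` gives the geometric
mean); per-condition thresholds average the condition's staircases, and
normalization divides by the participant's mean threshold (within each
target-speed block), making the per-participant mean exactly 1.

The same linear-contrast default applies when the convergence point is
measured from reversal levels: the staircase's stationary level
distribution is skewed in log units, so the log-average reads 1–3
percentage points below 70.71 % depending on slope (the mean per-trial
percent correct is 70.7–70.8 % regardless), while the linear average is
nearly unbiased (69.1–70.9 % across slopes 1.5–5, measured at 100k
trials).

Within-subject confidence intervals use Cousineau centring (subtract the
participant mean, add the grand mean) with Morey's J/(J−1) bias
correction and a t quantile.

## Hierarchical Bayesian analysis

**Model.** For normalized thresholds y (one value per participant ×
condition cell, and per target speed in the two-way form):

    y ~ t_ν(μ, σ),   μ = β₀ + α_cond + s_subj [+ δ_target + γ_interaction]

with N(0, 10²) on β₀, zero-centred normal priors on each deflection
group with its own spread, half-Cauchy(1) hyperpriors on the spreads and
on σ, and ν ~ Uniform(1, 100) — the t likelihood with learned degrees of
freedom downweights outliers instead of letting them drag the means.

**Sampler.** A Metropolis-within-Gibbs scheme using the
scale-mixture-of-normals representation (y | w ~ N(μ, σ²/w),
w ~ Gamma(ν/2, ν/2)): all location parameters are drawn jointly from
their exact multivariate-normal conditional (Cholesky solve), the
mixture weights from their gamma conditional, and σ, the group spreads
and ν by univariate slice sampling in log space (stepping-out with
shrinkage). Because normalization removes participant scale, the
subject-spread posterior piles up near zero — the classic funnel — so
each spread is additionally re-drawn with its deflections held fixed on
the non-centred scale (an ancillarity–sufficiency interweaving step),
which restores mixing there. Defaults: 4 chains × 2,500 draws after
1,000 warmup; reported results require split-R-hat ≤ 1.01 on every
parameter (a `ConvergenceError` naming the offenders is raised
otherwise; the gate can be disabled for bulk simulation studies, which
also use 2 × 500/300 for speed). At the defaults, max R-hat ≈ 1.004 and
min bulk ESS ≈ 700+ on a 20-participant dataset.

The raw dummy parameterisation is only softly identified; reported
deflections are exact sum-to-zero functions of the cell means computed
draw-by-draw (two-way effects via the standard ANOVA decomposition of
the cell-mean surface), so every reported group sums to zero exactly and
diagnostics are computed on identified quantities.

**Contrasts.** A contrast is the per-draw weighted sum of condition
deflections (optionally within one target level: condition effect plus
interaction). The HDI is the narrowest interval containing
ceil(prob · n) of the draws, found by exhaustive scan over the sorted
sample; conditions are called credibly different iff the interval
excludes zero. All contrasts are functionals of one joint posterior, so
no multiplicity correction is applied — computing them jointly or one at
a time gives identical results.

**Posterior predictive checks** simulate one full replicate dataset per
retained draw from the fitted t likelihood at each cell's location and
report central-interval coverage of the observations (~95–96 % for
well-specified synthetic data).

**Bayes factors** follow the default-prior (scaled-g) ANOVA framework:
sum-to-zero-projected design columns per effect group, each group's
coefficients N(0, g σ²) with g ~ InverseGamma(1/2, r²/2) (r = 0.5 for
fixed-effect groups, r = 1 for the always-included participant nuisance
group), flat prior on the grand mean, Jeffreys on σ². After integrating
the location and scale analytically, the marginal over the g's is
computed by 81-node Gauss–Legendre quadrature in log g over [−15, 15]
for models with at most two g dimensions, and by seeded prior Monte
Carlo (20,000 draws) for the three- and four-group models (additive,
full). Each model label is seeded deterministically from the user seed,
so BF(A,B)·BF(B,A) = 1 holds exactly. Model labels: null, mask_speed,
target_speed, additive, full; the reported table compares each reduced
model against the full (or, one-way, the mask-speed) model, with values
below 1 favouring the reference.

A dense-path oracle — the same two-condition integral evaluated through
an explicit N×N covariance with scipy's adaptive quadrature — agrees
with the production Woodbury-reduced path to better than 1 %.

## Synthetic data generator

Thresholds are generated as

    T_ij = baseline · exp(u_i) · C_j · exp(s·t_df) · outlier_ij

with participant offsets u_i ~ N(0, 0.3²) (large inter-individual
threshold differences are the reason the analysis normalizes),
condition multipliers log C_j = A·exp(−log²(v_j/v₀)/(2w²)) for a moving
mask at speed v_j — a log-Gaussian tuning bump of height A = 0.3
log-units centred on the matched speed v₀ with width w = 0.6 — and
log C = −0.1 for regular CFS (regular CFS suppresses a moving target
somewhat less than baseline); residual noise is Student-t with 5 df
scaled by 0.1 (mildly heavy-tailed, motivating the robust likelihood);
outliers multiply a threshold by e^±1.5 with probability 0.02. The
two-target design re-centres the bump on each target speed and halves
the amplitude in the 5 °/s block, emulating the flattening of the
threshold profile for fast targets. The tuning-curve family and all
magnitudes are modelling choices — no published per-condition threshold
values exist to calibrate against — chosen so that a 5–6 participant
study shows a detectable but not trivial peak.

Because normalization is a within-participant ratio, the multiplicative
participant offsets cancel exactly; the recoverable ground truth is
E[C_j e^ε_j / mean_k C_k e^ε_k] − 1, a deterministic property of the
profile that the generator computes by an internal fixed-seed
Monte-Carlo integral (200k draws, MC error ~10⁻⁴). Outlier contamination
is excluded from the estimand: accommodating outliers is the robust
likelihood's job.

What the generator does *not* emulate: any link between the adaptation
simulation and thresholds (the two are deliberately independent — that
dissociation is the scientific point), serial dependencies between
trials, learning or fatigue, criterion shifts, and the true human effect
sizes. Passing recovery tests therefore demonstrates that the analysis
is calibrated for data with this statistical structure, not that the
human effects have any particular magnitude.

**Observer bank.** Psychometric thresholds α are the same tuning profile
applied to the baseline contrast with per-participant log-normal jitter,
so staircases run against the bank reproduce the profile at the 70.71 %
point (verified end-to-end in the tests).

## Verification strategy

Every numerically substantive path has an independent oracle: the
classifier against a dense per-pixel convolution with explicit padding;
the vectorised field update against a scalar per-category recursion
(exact to 1e-12, property-tested over random label sequences); the
closed-form decay/recovery identities; threshold estimation against
psychometric inversion; the HDI against the defining
narrowest-interval property; the Bayes factor against the dense
covariance path; and the full pipeline against the generator's ground
truth (99-replicate bias, ~94 % HDI coverage, null calibration, BF
calibration). Simulation-scale choices in the tests (128-px frames, 1-s
trials, 99 trials per condition; 2-chain reduced-draw fits in replicate
loops) are stated in the tests themselves.

## Known limitations

- The adaptation model is a single-timescale, single-spatial-frequency
  caricature: no magno/parvo distinction, no spatial-frequency channels
  beyond the single carrier, one decay and one recovery constant.
- The CFS-vs-fastest-mask ordering of the adaptation summary is not
  robust across aggregation choices (see above); conclusions should rest
  on the moving-mask speed gradient, which is.
- The exact Nyquist-carrier filter of the original formulation is not
  representable as an odd-symmetric kernel on the pixel grid; λ = 4 px
  is the closest realisable default.
- JZS Bayes factors for the three- and four-group models are Monte-Carlo
  estimates (reciprocity still exact by shared seeding); quadrature is
  used wherever the dimension allows.
- The staircase convergence measurement inherits a small slope-dependent
  bias from evaluating the psychometric at an averaged level rather than
  averaging p itself; the linear-contrast average keeps it within ~1
  percentage point at the default slope.
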