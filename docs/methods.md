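# Methods

This note documents the models and procedures implemented in
`neuroaudience`, the parameter choices that matter, what the synthetic-data
generator does and does not emulate, and the numerical decisions taken
where the procedure left room.

## EEG engagement scores

**Spectral decomposition.**  Band power is computed per channel in
non-overlapping 1000 ms rectangular windows (short-time Fourier transform
with no taper).  At integer sampling rates the window gives exactly 1 Hz
bin spacing; a band [f_lo, f_hi) collects the half-open set of bins
`ceil(f_lo) <= k < ceil(f_hi)`, so the four canonical bands — theta 4–8,
alpha 8–12, beta 13–30, gamma 31–55 Hz — partition their range despite the
shared printed 8 Hz edge.  Band power is the summed squared spectral
amplitude over the band's one-sided bins.  The choice of a rectangular,
non-overlapping window is deliberate: it makes the per-second values
independent across windows and exactly reproducible by a direct DFT oracle
(tested at 1e-9 relative tolerance).

**Baseline and normalization.**  The per-channel band power of the 1000 ms
black-screen window preceding episode onset is subtracted from every
second (subtraction rather than division: the subsequent z-scoring absorbs
scale, and subtraction is stable when the baseline power is near zero).
Corrected powers are averaged over ROI channel groups (unweighted), then
z-scored over time within participant using the population SD (divisor n).
The fixed order is: band power → baseline subtraction → ROI average →
z-score → score combination → participant average → sigmoid → minute
average.

**Scores.**  Per second: motivation = ½[(z_alpha_R − z_alpha_L) +
(z_beta_L − z_beta_R)]; attention = z_theta − z_alpha (all 15 sites);
memory = (z_theta + z_gamma)/2 (all 15 sites).  The asymmetry is a
z-score *difference*, not a literal left/right ratio: ratios of z-scores
are undefined or unstable near zero and sign-flipping for negative values,
while the difference preserves the intended direction (less left-relative
alpha ⇒ higher approach motivation) and is the dominant convention in the
asymmetry literature.  Note the scores are deliberately not orthogonal:
attention and memory share the theta band, so a latent state that raises
theta moves both.

**10-point scaling.**  Group-averaged raw scores are squashed by
f(x) = 10 / (1 + exp(−(x − c)/s)).  The constants are calibrated per score
from the episode's own group-level series: c = median, s = (√3/π)·SD,
which moment-matches a logistic distribution to the empirical spread so
the output occupies the (0, 10) range without saturation.  Fixed constants
can be supplied instead (e.g., to calibrate across a whole study).
Applying the squashing twice is not idempotent and not meaningful; the
function is strictly monotone, and its output is clamped to the nearest
floating-point values inside the open interval so the strict (0, 10)
bounds survive extreme inputs.  The composite score is the unweighted mean
of the three minute-level group scores (computed at group level; the
per-participant-then-aggregate alternative changes little because the
component scores are themselves defined on group-aggregated series).

**Masking.**  Artifact-masked seconds propagate as NaN and are excluded
from every mean and z-statistic; a minute with more than 50% masked
seconds is flagged missing.

## Audience preparation

The order is fixed and enforced by stage tags (applying a stage out of
order raises): trim omission windows → z-score within episode →
(Twitter: lag alignment) → (viewership: break detrending) →
minute-to-minute diffs → per-segment pooling.  Omitted minutes are
declared outliers, so they are removed *before* normalization; the lag is
a pure re-indexing and is applied after z-scoring.  Trailing minutes that
lose their source value under the lag become missing and are dropped from
pooling, not zero-filled.

Segment pooling averages the diffs whose leading minute lies in the
segment, plus — for Twitter — the first two minutes of the following break
(delayed tweeting about the just-ended content) and — for viewership — the
first break minute (delayed channel switching).  Every diff contributes to
at most one segment.  EEG diffs pool only pairs of adjacent minutes inside
the same segment: the EEG session presents the episode without
commercials, so the diff spanning a break boundary would compare
non-adjacent broadcast content; it is assigned to neither segment.

Viewership detrending: for each break, the within-break change d =
value(last break minute) − value(first break minute) is subtracted from
all later minutes (cumulative across breaks).  On a constructed pure-step
fixture this restores the post-break segment to the pre-break plateau
exactly (tested); single-minute breaks have d = 0 by construction.

Transition minutes are labeled program only if program content occupies
strictly more than 30 s of the minute.

## Inference

Pearson correlations use the t distribution with n − 2 df (two-tailed).
The Fisher r-to-z difference test uses the independent-samples form
z = (atanh r₁ − atanh r₂) / √(1/(n₁−3) + 1/(n₂−3)); one-tailed p on
request.  This form reproduces the published contrast statistics even
though the compared correlations share the 49-segment sample; the proper
shared-sample alternative (the Meng–Rosenthal–Rubin form of Steiger's
test, which needs the correlation between the two non-shared variables) is
provided as `dependent_correlation_difference`.  Partial correlation uses the first-order closed form, equal to
the correlation of OLS residuals (tested to 1e-10 and cross-checked
against pingouin).  Stepwise regression is forward selection with backward
removal on partial t-test p-values, thresholds p_enter = 0.05 and
p_remove = 0.10 (the long-standing default convention of commercial
statistics packages), with statsmodels OLS behind each fit; standardized
betas are raw betas rescaled by sd(x)/sd(y).  Median splits assign ties to
the low half (a 49-row table splits 25/24).  The episode-level one-way
ANOVA applies a square-root transform to raw count-scale minute values
(z-scores can be negative, so the transform belongs on the raw scale; EEG
scores, already bounded, are analyzed untransformed) and Bonferroni
multiplies each pairwise p by the number of pairs, capped at 1.

A caution that the test suite quantifies: the unit of inference is the
segment-mean of minute-to-minute diffs of within-episode-normalized
series, pooled across episodes.  These 49 values are not an i.i.d. sample —
diff means telescope to endpoint differences and share episode-level
structure — so the nominal correlation p-values are somewhat
anticonservative under a true null (empirical false-positive rate near
11% at nominal 5% in null-coupling simulations).  This is a property of
the segment-pooling design itself, not of the implementation; see the
null-calibration notes below.

## Synthetic studies

The generator emulates the deposited study's layout and statistical
structure, with known ground truth.

**Latents.**  Attention, motivation and memory follow independent
stationary AR(1) processes at minute resolution over broadcast minutes
(ρ = 0.5, innovation SD √(1−ρ²) ⇒ unit stationary variance, so coupling
coefficients read as effects per latent SD), held constant within the
minute.  The cross-correlation among the real processes is unknown;
independence is the default and a correlation can be imposed by editing
the traces.

**EEG.**  Per participant, each 1-s frame's spectrum receives complex
Gaussian coefficients on every DFT bin: a 1/f background plus band
carriers (theta and alpha at 4.0, beta 1.5, gamma 0.8 per-bin amplitude
units).  Carrier amplitudes are modulated by the minute's latents with the
sign structure the scores assume: attention ↑ ⇒ alpha ↓ and theta ↑ at all
sites; motivation ↑ ⇒ left alpha ↓ / right alpha ↑ and left beta ↑ /
right beta ↓; memory ↑ ⇒ theta ↑ and gamma ↑ (modulation depth 0.25 per
latent SD, envelopes clipped at 0.05).  Synthesis is per-frame in the
frequency domain rather than by time-domain bandpass filtering: the
analysis itself is frame-wise and rectangular, the two constructions have
the same within-frame band statistics, and the spectral route is an order
of magnitude faster, which the Monte-Carlo calibration experiments need.
A 1-s unmodulated black-screen frame is prepended as the baseline.
Recordings cover the concatenated program minutes only (the session shows
the episode without commercials) and are mapped back to broadcast minutes
through the timeline.

**Audience.**  Viewership minute diffs are b_att·Δattention +
b_mot·Δmotivation + Gaussian noise (defaults 1.0, 0.2, SD 0.5), cumulated
from a base of 3.0M viewers at 30k viewers per latent-SD unit; each break
declines by 2.0 units internally and recovers half at the next segment's
first minute.  Twitter counts are Poisson with log-rate log(150) +
0.3·attention + 0.3·motivation evaluated at the content minute and
emitted ``lag`` minutes later; half of each segment's final-two-minutes
tweet mass is moved into the first two break minutes (binomial thinning,
keeping counts integral).  The coupling defaults were chosen once to
reproduce the reported effect scale (segment-level attention–viewership
correlation near 0.6–0.7 at the 12-participant panel size) and are the
conditions under which the recovery experiments run.

**Geometry.**  Desk scale: 9 episodes × 12 participants, 44 minutes of
program content per episode (the hour-long prime-time format: five or four
3-minute breaks on top, 56–59 broadcast minutes), 128 Hz, the 15 ROI
channels only.  Per-episode omission windows and Twitter lags cycle
through the study's published values; one episode drops EEG for its final
segment, so the default study yields exactly 49 analyzable segments.  The
512 Hz/32-channel geometry is available through the config arguments.

**What the generator does not emulate.**  Real EEG artifacts and their
removal (inputs are assumed cleaned), volume-conduction and electrode
covariance, non-Poisson tweet bursts (retweet cascades), demographic
strata, and any cross-correlation among the three latent processes.
Passing recovery tests therefore demonstrates that the pipeline's
transformations are correct and that its inferences respond to real
couplings at realistic noise levels — not that real recordings meet the
generator's assumptions.

## Recovery experiments and calibration

`run_recovery_experiment` executes the complete pipeline (EEG → scores →
audience prep → segment table → inference) on a generated study and
reports correlations and stepwise models against the known couplings.
Three seeded Monte-Carlo experiments summarize behavior across replicates
(counts kept modest so the default runs finish in minutes; the
streaming ``keep_eeg=False`` mode holds only one episode of EEG at a
time, keeping peak memory near 0.5 GB):

- *Attention-only coupling*: fraction of replicates where the attention
  score is the sole stepwise entrant for viewership (near 0.9 at the
  default geometry).  Because the memory score shares the theta band with
  the attention score, it carries genuine (indirect) signal about the
  attention latent and legitimately enters the model in some replicates —
  increasingly so when segments are short and the attention score is a
  noisy estimate of the latent.  This is a property of the score
  definitions, not a selection bug (the stepwise routine is verified
  against an independent implementation and exhaustive subset search).
- *Motivation-to-Twitter coupling*: fraction of replicates where the
  asymmetry score correlates more with Twitter volume than with
  viewership.
- *Null coupling*: pooled false-positive rate of the segment-level
  correlation tests.  As noted above, the empirical rate exceeds the
  nominal 5% because segment values are not i.i.d.; the pooled rate at
  the default geometry is near 11%.

## Numerical choices and degenerate inputs

Population SD (divisor n) everywhere a z-score is formed; zero-variance
series raise a degenerate-series error rather than returning NaNs.
Constant split variables, |r| = 1 inputs to the Fisher transform, bands
beyond Nyquist, over-long omission windows, and sub-second recordings all
raise typed errors.  Stepwise entry breaks p-value ties by column order;
the predictor that just entered is exempt from the immediately following
removal pass.  All randomness descends from a single seed through
`numpy.random.SeedSequence.spawn`, and regenerating any study with the
same seed is bit-identical (tested).

## Known limitations

- The sigmoid calibration constants of the original analysis are unstated;
  per-episode moment-matching is this package's choice, and minute scores
  are therefore comparable within but not across differently-calibrated
  studies.
- The correlation p-values inherit the anticonservativeness of the
  segment-pooling design (above); treat borderline segment-level
  significance with care.
- EDF files are read (via mne) but not written; EEG output uses the
  delimited-text format with a YAML sidecar.
- The Twitter lag is consumed as a per-episode parameter; the grid-search
  helper over {0, 1, 2} maximizing |segment correlation| is an extension,
  not part of the core procedure.
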