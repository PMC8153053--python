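# Methods

## Scope and model

The package implements a complete analysis chain for picture-encoding
eye-tracking studies: event detection from raw gaze, quality control,
data-driven areas of interest, standardized exploration features, a
mixed-model association with free-recall memory, and a guided-viewing
track in which a moving circle prescribes the scan path. All statistical
machinery operates on synthetic cohorts with known ground truth, so every
claim a test makes is a recovery or calibration statement, not a
comparison with archived human data.

## Event detection

**Velocity-threshold fixation detection.** Velocities are estimated with
the 5-point central-difference kernel
v(t) = (p(t+2) + p(t+1) − p(t−1) − p(t−2)) / (6 Δt), the standard robust
construction for noisy gaze traces. The per-axis dispersion is the
median-based estimator σ² = median(v²) − median(v)², insensitive to the
heavy velocity tail that saccades produce. Samples with
(v_x/λσ_x)² + (v_y/λσ_y)² > 1 in runs of at least 2 form saccades;
maximal inter-saccade runs are fixation candidates; candidates shorter
than 100 ms are discarded (a run of exactly 100 ms is kept — the rule is
strictly less-than). λ defaults to 6 and is exposed in configuration.
When a trial's dispersion is exactly zero (perfectly still synthetic
data), the threshold falls back to an absolute velocity floor of 10°/s.

Blink samples (aspect ratio < 0.5) are excluded from the dispersion
estimate and cannot mark saccades themselves; because position is held
during a blink, a fixation is split only when the post-blink position
jumps far enough to register as a saccade.

**Drift correction.** corrected(t) = raw(t) − movmedian(raw, 3301)(t) +
median(raw), per axis, with edge-truncated centred windows. Re-adding
the overall median preserves absolute screen coordinates, which AOI
assignment needs; the removed baseline is therefore determined only up
to a constant, and tests compare drift-corrected signals after removing
the mean offset.

**Blink detection.** Maximal runs of pupil-ellipse aspect ratio < 0.6
lasting ≥ 83 ms; duration is run length × sampling interval.

## Quality control

Outlier fences are q₁ − 1.5·IQR and q₃ + 1.5·IQR with quartiles from the
ideal-fourths interpolation (depth n/4 + 5/12 from either end; for n = 2
the depth falls below the first order statistic and the estimator
degenerates to the extremes). Subjects are dropped for upper-outlying
total calibration deviation (sum over the nine targets of the distance
between per-target *median* gaze — robust to blinks — and the target) or
for outlying velocity dispersion on the x- and/or y-axis; the dispersion
summary is the robust SD of sample-to-sample velocity per axis, a pinned
choice since several summaries would be defensible. Trials are dropped
for containing at most one fixation, for aspect ratio < 0.5 in more than
half of the picture-window samples, or for a pupil profile whose
correlation with the grand-average profile is a lower boxplot outlier
after Fisher-z transformation. The grand average is computed from the
valid-signal trials of the current dataset, not from a stored reference.

## Areas of interest

Flat-kernel mean shift (scikit-learn's `MeanShift`) on fixation
centroids pooled over at most 200 subjects per picture (a seeded sample
when more are available). Modes closer than bandwidth/2 are merged,
clusters holding < 5 % of points are discarded, and each surviving mode
becomes a circular AOI with radius max(bandwidth, RMS member distance).
The bandwidth defaults to 2.0° of visual angle — a typical semantic
object size at viewing distance — and is recorded in output metadata.
Points are sorted before clustering so results are order-independent.
Areas of no interest repeat the procedure on the fixations outside every
interest AOI, dropping any mode that falls inside one.

Fixation-to-AOI assignment takes the nearest interest AOI whose radius
covers the centroid; exact ties go to the lower AOI index.

## Features and the association model

Per 2.5 s picture trial: fixation count (onset-based window inclusion —
a fixation straddling the picture onset counts only if it begins inside
the window), fixations in AOIs, unique AOIs fixated, total blink
duration over the whole trial, and mean distance between consecutive
fixation centroids. Features are z-standardized within picture (n−1
denominator) over valid trials of all retained subjects, removing
stimulus-level differences. Subject × valence aggregates require at
least 25 % valid trials (6 of 24 at the full design; the threshold
scales with the simulated design size).

The association model regresses the per-subject-per-valence recall
count on one z-feature, valence, their interaction, and the covariates
sex, age, goggles and recall room, with a random intercept per subject
(statsmodels `MixedLM`; on a singular or non-converging fit the model
downgrades to subject fixed effects and says so). The interaction is
Wald-F-tested first and FDR-adjusted across the four features; where
non-significant the model is refit without it. Main-effect p-values are
FDR-adjusted across the four features; a significant interaction
triggers three per-valence post-hoc tests (one row per subject within a
valence, hence OLS), FDR-adjusted across three. Denominator degrees of
freedom follow the nested-model convention: observations minus subjects
minus within-subject fixed-effect columns. Treatment coding with the
alphabetically first valence as reference is used throughout; the recall
count (0–24 per valence) is modelled linearly, matching the
repeated-measures structure of the design.

R²β\* = (q/ν)F / (1 + (q/ν)F). Its 95 % CI inverts the noncentral-F
distribution of the observed statistic for the noncentrality parameter
at the 2.5th/97.5th percentiles and maps the bounds through the same
formula; the lower bound is floored at zero.

## Guided viewing

Scan paths halt n = AOIs_pic (or 2·AOIs_pic) times; halt duration is the
exact rational 7000/n ms, kept as a `Fraction` so the 7000 ms fixated
exposure is conserved exactly rather than to rounding error; positions
are quantized to the sample grid only when a path is rendered.
Transitions run at 200°/s. The first halt is always the interest AOI
nearest the screen centre; the remaining order is a uniform shuffle, and
in the doubled condition the second pass repeats the first pass's order
element-wise. Trial order is found by rejection sampling under the
constraints of at most four consecutive trials of the same valence or
the same picture set.

Compliance correlates the rendered circle trajectory with gaze on the
concatenated x and y series (a per-axis mean is available via
configuration; how the axes combine is a genuinely open choice).
Arrival lag is measured from the first displayed frame of each halt to
the first gaze sample within the circle radius, searched within
416.67 ms (50 samples at 120 Hz); referencing the first frame rather
than the analytic onset makes perfectly compliant gaze score exactly
zero lag. The condition analysis is a random-intercept mixed model with
a Wald F for the three-level condition factor, two paired post-hoc
contrasts FDR-corrected over two, and percent changes between condition
means.

## Synthetic data

Trials alternate fixation plateaus (Gaussian jitter, default SD 0.3°,
consistent with a tracker accuracy of about 1°) with linear saccadic
ramps at 200°/s; a session-long random walk (step SD 0.01° per sample,
accumulating to a few degrees over a 40-minute session) models slow
drift; blinks occur in 26 % of trials with durations of 100–400 ms,
drop the aspect ratio to 0.3 and hold position at the last valid sample.
Fixation counts per 2.5 s trial are Normal(5.3, 1.0) rounded and
clipped. Recall is Bernoulli with logit α + β·z(N_fix in AOIs) +
condition effect; the default β is 0.5 and the condition effects
(−0.32, 0, +0.23 on the log-odds scale, intercept −1.19) are sized so
expected recall counts out of 18 pictures per condition are ≈ 3.25,
4.19 and 4.97.

Two generator parameters exist to keep injected events detectable in
principle, which the recovery invariants require: the minimum injected
fixation duration is 180 ms (the 100 ms discard threshold plus the
4-sample support of the velocity kernel, 66.7 ms at 60 Hz), and
consecutive fixation targets keep at least 2° separation so every
injected saccade clears the velocity floor. Randomness is one top-level
seed with per-subject substreams, so enlarging a cohort never changes
existing subjects' data.

What the generator does **not** emulate: saccade kinematics (ramps are
linear, real saccades have bell-shaped velocity profiles), pupillary
light responses and cognitive pupil dilation (the aspect-ratio trace is
flat noise plus blink dips), smooth pursuit, microsaccades, binocular
vergence, and measurement artifacts other than blinks and drift.
Passing recovery tests therefore show that the detectors implement
their definitions correctly under the assumed signal structure, not
that they are optimal for any particular hardware's noise.

## Problem sizes and numerical choices

Statistical calibration uses cohorts of 200 subjects × 72 pictures:
200 null simulations for the type-I error of the association model
(observed rejection rate ≤ 7 % at nominal 5 %) and 100 simulations at
β = 0.5 for power (≥ 80 %). Fixation-count recovery is checked on 200
subjects × 96 trials under study-condition noise (≥ 95 % of trials
within ±1) and exactly on noise-free cohorts. The end-to-end pipeline
demo runs 24 subjects × 48 pictures. Scan-path invariants are checked
on 1000 random paths. Degenerate inputs are handled explicitly:
zero-variance picture features z-score to 0 with a warning, pictures
with fewer than two valid trials get missing z-values, trials shorter
than five samples yield no events with a warning, and an empty picture
window invalidates the trial as signal loss.

## Known limitations

* Denominator degrees of freedom are a convention, not a Satterthwaite
  or Kenward-Roger approximation; with hundreds of subjects the
  difference is negligible, at small n the reported df are approximate.
* The linear model on bounded recall counts ignores the binomial
  mean-variance relation; calibration simulations show the Wald test is
  nevertheless conservative at the sizes used.
* Mean-shift bandwidth is fixed per run, not adapted per picture.
* The guided-viewing presentation-time range depends on the AOI
  geometry of the actual stimuli, so only the invariant
  total_presentation ≥ 7000 ms is asserted, not a numeric range.
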