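# Methods

## Problem and scope

`fallstack` implements a clip-level fall detector for smartphone inertial
data and the evaluation protocol needed to answer two questions: does a
detector trained on able-bodied ("control") volunteers transfer to people
walking with a transfemoral prosthesis ("amputee"), and how many false
alarms per day does it raise during unsupervised free living? Since raw
recordings of this kind are rarely shareable, the package ships a seeded
synthetic IMU generator that reproduces the statistical structure the
analysis depends on, and the whole chain — windowing, filtering,
features, stacking, subject-wise evaluation — is exercised end-to-end on
that generator.

## Synthetic data model

Signals are synthesized as a scalar resultant-magnitude profile times a
unit direction vector, then rotated by a per-(subject, location) carry
orientation. This construction controls the resultant acceleration
exactly and makes it provably invariant to phone orientation, which is
the core geometric property the resultant-based features rely on.

**Falls.** A fall is a parametric kernel: ~1 g quiet lead-in, a sub-1 g
free-fall dip (duration 0.3–0.5 s), a single impact peak (raised-cosine
pulse, width 0.10–0.16 s, with a flat top wide enough that one raw sample
always attains the exact peak value), a ring-down, and a ~3 s rest phase
at 1 g. Impact peaks are lognormal with location-specific medians (waist
5 g, pocket 6 g, hand 4 g; σ_log = 0.25), truncated below at 2 g by
rejection; with these parameters the first percentile of peaks sits near
2.2–2.8 g, which is what justifies the 2 g pre-filter. The phone
simultaneously pitches/rolls about a fall-type-specific axis (trip
forward, slip backward, lateral left/right); the gyroscope records the
rotation rate plus an impact jolt. Dip depth and rotation magnitude scale
with impact energy, so low-peak falls are genuinely harder, not just
smaller.

**Activities.** Sitting/standing/lying are quiet 1 g baselines with
occasional sub-2 g postural shifts; walking and stairs add a
step-frequency bounce (1.8 / 1.4 Hz, amplitude 0.25 / 0.35 g). Supra-2 g
transients — the confounders a threshold detector cannot reject — are
Poisson-timed and come in two morphologies with equal probability:
*handling* (a spike with ongoing motion; phone pulled from a pocket) and
*set-down* (a spike followed by ~1 s of stillness; phone dropped on a
table — the classic fall look-alike). Transient peaks are lognormal
(median 2.8 g, σ_log = 0.3, floor 2.05 g), deliberately overlapping the
lower tail of fall peaks.

**Populations.** Control and amputee cohorts differ *only* in gait
parameters: a step-asymmetry scalar (default 0 vs 0.4) that modulates
alternate-step amplitude and reduces cadence by 15% of its value. Fall
morphology and transient statistics are shared. This is a structural
assumption, not an empirical claim: it encodes the hypothesis under which
cross-population transfer should work, and the transfer experiment tests
exactly that.

**Free-living ("home") streams** are gap-free `home_days` × 24 h
recordings with an hourly ~10 min walking bout, transients at
`adl_supra2g_rate` per hour (default 9/h, i.e. ~216 supra-2 g clips per
day, in line with free-living phone use), and zero falls.

**Timing.** Nominal sampling is 50 Hz with ±10% uniform per-sample
timestamp jitter (monotonicity is guaranteed since the jitter never
exceeds half the interval), so the resampler always has real work to do.
All randomness flows from `numpy` generators keyed by (seed, subject), so
subjects are independent yet every stream is bit-reproducible.

What the generator does **not** model: biomechanically validated fall
dynamics, prosthesis-specific gait beyond the asymmetry scalar,
barometer/GPS channels, real-world activity diversity, and sensor
saturation. Passing tests on this generator therefore demonstrate that
the *pipeline* behaves as specified under the stated statistical
structure — not that the detector would reach the same numbers on human
recordings.

## Preprocessing

* Fall windowing: the impact is the maximum resultant-acceleration sample
  inside the annotated event (ties broken earliest); a 10 s clip centered
  on the impact is required to exist, and ten 5 s windows are drawn so the
  annotated fall onset sits Uniform(0 s, 3 s) after the window start.
  Windows are half-open `[start, start + 5 s)`.
* Activity windowing: non-overlapping 5 s tiles per labeled interval;
  trailing remainders are dropped.
* The 2 g filter keeps clips whose *peak Euclidean resultant*
  √(x²+y²+z²) strictly exceeds 2 g. It applies to activity and home clips
  only; fall clips are retained by construction since the threshold is
  calibrated as the falls' first percentile. The filter is idempotent.
* Resampling: each channel is interpolated to a uniform 250-sample,
  1/50 s grid with a cubic spline using not-a-knot boundary conditions.
  That choice reproduces cubic polynomials exactly, which gives the test
  suite a closed-form oracle; it also passes through every input sample.
  Free-living streams are pre-screened on the raw resultant (candidates
  within 5% of the threshold) before resampling, which makes 2-day
  streams cheap without changing the retained set.

## Features

40 features per clip, 20 per sensor, frozen in a named manifest
(`sensor.signal.statistic`) whose hash is stamped into fitted models. Per
sensor: on the resultant — mean, median, population std, skewness, excess
kurtosis, IQR, min, max, plus IQR/min/max of the first-difference
derivative (×50 Hz, units per second); per axis — max, min, IQR.
Quantiles use linear interpolation; zero-variance signals map skewness
and kurtosis to 0 and snap an O(ulp) accumulated variance to exactly 0.
The "derivative of X" features are statistic-X-of-the-derivative (one
extra feature per statistic); an alternative reading — time-derivative of
a running statistic — was considered and rejected because it does not
yield a fixed-length descriptor per clip.

## Detector

Four base classifiers with fixed published-style hyperparameters: random
forest (100 trees), linear-kernel max-margin classifier (C = 1,
probabilities via a sigmoid link on decision values fitted on internal
folds), gradient boosting (100 trees, depth 2), extreme gradient boosting
(150 trees, depth 2, learning rate 0.5, feature subsample 0.6). The meta
input is x_meta = [P₁, P₂, P₃, P₄, σ(Pᵢ)] with σ the *population*
standard deviation (the four probabilities are the complete population of
base outputs); a logistic regression maps it to the final probability.
σ can be dropped via `include_sigma=False` to measure its contribution.

Meta-training uses out-of-fold probabilities from a subject-grouped
internal cross-validation (5 folds, capped at the number of training
subjects) so no clip contributes to both a base fit and its own
meta-feature; the bases are then refitted on the full training set.
Hyperparameter grids around the defaults exist (`grid_search_spaces`) but
are off by default. The threshold baseline scores a clip by its peak
resultant acceleration (squashed monotonically to [0, 1)); its ROC is
identical to sweeping a threshold on the raw feature.

## Evaluation

* AUC is the pairwise-ranking probability (ties ½); bootstrap CIs
  resample clips within subject strata (clips of one subject are
  correlated), 1000 reps by default, seeded.
* The operating point maximizes sensitivity + specificity; ties go to the
  lower threshold (higher sensitivity).
* LOSOCV: one fold per subject; single-class test folds are flagged,
  logged, and excluded from summaries. Cohort summaries are
  across-subject means with 1.96 × SEM half-widths.
* False alarms/day: the largest threshold reaching the target sensitivity
  (default 90%) on labeled fall clips, applied to the 2 g-pre-filtered
  free-living clips, divided by monitored days. For cross-population use
  the sensitivity sweep is located on the test population's lab falls.
* Model comparison: two-sided Wilcoxon rank-sum on per-subject AUCs, with
  midranks and tie-corrected normal approximation, or full enumeration
  when the combined sample is smaller than 12. A fully tied pooled sample
  returns p = 1. No multiple-comparison correction is applied; raw
  p-values are reported.

## Problem sizes and runtime

The default study scale is 10 control + 6 amputee subjects, three carry
locations (→ 36 fall trials and 360 fall clips per subject), 40–60 s
activity intervals, and three 2-day home streams; a full `reproduce` run
takes ~3 min on one CPU. The test suite exercises the same properties at
reduced scale — e.g. the multi-seed qualitative checks use 5 control + 4
amputee subjects with a single carry location, which keeps ten seeded
replicates of the full train/evaluate cycle inside a few minutes while
leaving every per-seed quantity (per-subject AUCs, pooled AUCs, alarm
rates) statistically meaningful.

## Known limitations

* The simulator's separability is configurable but idealized; with the
  default peak distributions the stacked detector is essentially perfect
  (AUC ≈ 1.0), which is the regime the protocol targets but says little
  about borderline falls.
* The threshold baseline's probability squashing fixes its ROC but makes
  its absolute "probabilities" meaningless; only rankings and thresholds
  in g are interpretable.
* Streams are processed in memory; multi-week recordings would need
  chunked readers.
* Model archives are joblib pickles (versioned and validated on load);
  they are reproducible across runs on the same library versions but not
  a long-term interchange format.
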