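# Methods

This note documents the models, estimators, numerical choices and known
limitations of `gaitokr`. Empirical claims below are limited to what the
test suite and `scripts/acceptance.py` themselves compute.

## Gait analysis

### Model of the gait cycle

A stride is one full cycle of a limb, from stance onset (paw touches down)
to the next stance onset. On a linear track the paw, viewed in the body
frame (relative to the nose–tail midpoint), moves backward during stance —
the paw is planted while the body advances — and forward during swing. The
stance onset is therefore the maximum of the body-frame anteroposterior (AP)
trajectory (paw closest to the nose) and the swing onset the minimum between
consecutive maxima.

All limb positions are projected onto the unit vector from tail base to
nose and referenced to the axis midpoint before segmentation. This makes the
analysis invariant to image-coordinate conventions (origin top-left,
y down) and to heading.

### Segmentation estimator

The stated extremum criterion needs anti-noise safeguards on tracker data:

- Candidate maxima are found on a zero-phase (filtfilt) 4th-order
  Butterworth low-pass at 10 Hz, with minimum peak separation 0.1 s and
  minimum prominence 10% of the trajectory's run-range. All three values are
  exposed in `SegmentationConfig`.
- Each extremum is then *refined on the unfiltered trajectory*, because at
  cadences approaching 5 strides/s the filter attenuates the waveform's
  harmonics and would otherwise bias events toward a sinusoid (stance
  fraction toward 0.5).
- The paw dwells near both extremes (swing decelerates into touchdown; the
  planted paw leaves its rearmost position slowly), so raw argmax/argmin
  drift into the flat side of each extremum and bias stance fraction upward
  by several frames per stride. Events are therefore anchored to the steep
  side of the corner: the stance onset is the last frame within
  `plateau_tol_frac` (default 3% of run-range) of the local maximum, and the
  swing onset the first frame within tolerance of the local minimum.

Frames with tracking likelihood < 0.9 are linearly interpolated over gaps of
at most 5 frames; longer gaps split the run. Straight runs can be isolated
automatically (heading circular SD < 15° and body speed > 50 mm/s over a
0.5 s window) or supplied as a manual annotation table, which takes
precedence — the automated criterion exists so the pipeline is runnable
end-to-end, the annotation path so it can reproduce manually curated
workflows.

### Metrics and conventions

Per stride: cadence = 1/duration; stance fraction = stance frames over
stride frames (swing fraction its complement, exactly); walking speed =
body-midpoint displacement over duration. **Stride length is the paw's
arena-frame displacement between consecutive stance onsets** — the
alternative (body displacement per cycle) is numerically equal for steady
walking but the paw convention is the one implemented and flagged here.

Interlimb phase: for each left-forelimb (LF) stride, the phase of limb L is
2π(t_stance(L) − t_stance(LF))/T_LF wrapped to [0, 2π), using the first
stance onset of L at or after the LF onset; strides where a limb has no
onset are skipped and logged. Stepping variability is the circular standard
deviation **in radians**, √(−2 ln R̄) with R̄ the mean resultant length
(the angular deviation √(2(1−R̄)) is available behind a config switch);
the per-limb SDs of RF, LH, RH are averaged into one animal-level value.
Per-animal summaries are stride-weighted means; group comparisons are then
made on animal-level values.

Known estimator bias: when the reference limb's stance onsets happen to fall
exactly on the frame grid while other limbs' do not (possible only for
cadences commensurate with the frame rate), frame rounding of event times is
one-sided and shifts all phases by up to ~0.15 rad. For generic cadences the
rounding is common-mode and cancels in the phase differences.

## Oculomotor analysis

### Calibration

The corneal reflection (CR) serves as a head-fixed reference. Rotating the
camera by ±10° displaces the CR-referenced pupil center by Rp·sin 10°;
Rp is fit as the mean measured displacement divided by sin 10°, and eye
angle is arcsin(Δ/Rp). Displacements beyond Rp are clipped to ±90° and
flagged.

### Velocity and event detection

Velocity is a central difference after a 10 ms moving-average smooth — short
enough to resolve 20 ms events at both 130 and 200 Hz. Candidate events are
maximal intervals where |velocity| exceeds 30°/s (a deliberately low
boundary threshold); candidates separated by < 20 ms are merged, since
differentiation noise can split one event. A candidate becomes an event iff
its amplitude magnitude and peak |velocity| meet the per-axis minima:
3°/100°/s horizontal, 1°/100°/s vertical (vertical saccades are smaller).

Amplitude is measured between the positions 10 ms *outside* the boundary
crossings (capped at neighboring candidates). At these sample rates a
~30 ms event spans only 4–6 samples and the sub-threshold velocity tails
carry ~15% of the true displacement; measuring strictly between the
crossings would systematically reject genuinely ≥ 3° events. Onset/offset
times remain at the crossings. Peak velocity is still mildly attenuated
(~10–15% for the briefest events) by the smoothing window; amplitudes are
essentially unbiased. Main-sequence slopes fitted from *detected* events
therefore run slightly below the generative slope; the CI-coverage
validation injects events directly to test the regression itself.

Blink/track-loss handling mirrors the gait stage: linear interpolation up to
50 ms, longer gaps split the record.

### OKR gain

Drum assay (default estimator): per sinusoidal cycle,
gain = (eye max − eye min)/(drum peak-to-peak). Trials (not cycles)
containing any detected saccade are excluded entirely before cycle division.
An alternative velocity-ratio estimator (eye velocity peak-to-peak over drum
velocity peak-to-peak) is available behind `estimator="velocity"`; the
position-amplitude ratio is the default because it is the more robust of the
two definitions in common use and the two agree for pure tracking.

Dome assay: within each 30 s moving epoch, detected quick-phase intervals
(±25 ms pad) are excised and the slow-phase velocity is the **median** of
the remaining smoothed velocity — robust to residual undetected events —
divided by the signed stimulus velocity (10°/s). Sign conventions: azimuth
positive nasal, elevation positive dorsal, left eye recorded. Resetting
quick phases oppose the slow phase (temporal stimulus → nasal quick phases),
and directional quick-phase frequency counts only events in the resetting
direction within that stimulus direction's moving epochs, over the summed
moving time.

Caveat: measured slow-phase gain is weakly coupled to the quick-phase rate,
because events below the detection thresholds cannot be excised and shift
the velocity median slightly. In cohort simulations with matched injected
gain but different quick-phase rates this produces small but statistically
real group differences in measured gain; gain is therefore not treated as a
null measure in the false-positive accounting.

### Main sequence

OLS of peak velocity on |amplitude| per axis/direction; slope, intercept,
r², and a t-based 95% CI on the slope; ≥ 3 events with non-identical
amplitudes required. Validated by CI coverage: the injected slope lies in
the fitted CI in ≥ 90/100 simulations at n = 100 events with 10°/s velocity
noise.

## Pathology and statistics

Densities are pooled per animal and region: total AT8+ count over total
section area (both hemispheres), per 10⁴ µm² — a ratio of totals, invariant
to how the area is split into the 5–7 sections and robust to unequal section
areas, rather than a mean of per-section densities. Pearson correlations
between region densities and behavioral summaries drop incomplete animals
pairwise (n ≥ 3 required) and are reported unadjusted by default, matching
common practice for small-cohort exploratory histology; a Benjamini–Hochberg
option exists and its caveat is documented in the code. For n ≤ 7 the
two-sided p is computed by exhaustive permutation enumeration (≤ 5040
permutations) because the t approximation deviates from the permutation null
by more than Monte-Carlo error at those sample sizes; larger n use the
t-based p.

Mann–Whitney U uses midrank tie handling; the exact two-sided p (doubled
one-sided tail, capped at 1) is computed when the data are tie-free and
n₁·n₂ ≤ 64, otherwise the normal approximation with tie and continuity
corrections. The method used is recorded on every result. Repeated-measures
designs (multiple ages or stimulus frequencies) are handled as per-timepoint
two-sample tests; no omnibus model is fit.

## Synthetic-data generator

The generator is first-class, tested code; its defaults define the study
conditions under which the pipeline is validated.

**Gait**: limb body-frame AP position follows a piecewise cycle — linear
retreat during stance (the planted paw under an advancing body), minimum-jerk
advance during swing — with amplitude stride_length × stance_fraction, which
yields unambiguous extrema for segmentation while resembling real paw
trajectories. Interlimb offsets (default trot: RF = LH = π, RH = 0 relative
to LF) are jittered per stride by von Mises noise of concentration κ
(∞ = noiseless); the reference limb is kept clean so injected phases are
well-defined. Nose and tail base advance at cadence × stride_length.
Coordinates receive i.i.d. Gaussian noise (mm) and are scaled to pixels by
`px_per_mm`; the pose writer emits the DeepLabCut three-header-row dialect
with likelihood 1.0.

**Eye traces**: the drum assay is gain × sinusoidal drum position (±5°
default; 10 s stimulus flanked by 4 s static per trial) plus optional
spontaneous saccades; the dome assay integrates gain × stimulus velocity
over 6 epochs (5 s static / 30 s moving / 5 s static, 10°/s) interrupted by
resetting quick phases arriving as a Poisson process thinned to ≥ 100 ms
separation (real quick phases are refractory, and overlapping events would
make ground truth ill-defined). Every rapid event is a minimum-jerk step
whose peak velocity is the commanded main-sequence law
slope × amplitude + intercept; the step duration follows as
1.875·A/V_peak, which for the default slope of 60 s⁻¹ gives 30–95 ms
events. Tying duration to the commanded velocity keeps the injected
kinematics exactly linear, at the cost of letting slow-commanded events
exceed the typical 20–50 ms saccade duration band.

**Pathology**: one region's density is base + slope × standardized behavioral
covariate + Gaussian noise (the baseline scales with |slope| so densities
stay non-negative without clipping, which would break exact linearity);
remaining regions are independent. Counts/areas are synthesized consistently
with the densities (idealized real-valued counts).

Measurement-noise magnitudes are free parameters, not claims about any real
rig: defaults used in validation are 0.5 mm coordinate noise for gait
(typical pose-tracker error at ~5 px/mm) and 0.05–0.1° eye-position noise.

**What the generator does not emulate**: curved or hesitant locomotion,
missing/occluded markers beyond uniform likelihood, pupil-size changes and
blinks, drift or slow nystagmus outside stimulation, torsional eye
movements, and integer count noise in histology. Passing validation
therefore demonstrates correctness of the estimators under these idealized
conditions, not robustness to every artifact of real recordings.

## Cohort-level validation

The end-to-end check simulates cohorts of 8 control ("WT") and 6 affected
("Tau") animals. Injected effects: stance fraction 0.60 vs 0.70, interlimb
phase concentration κ = 20 vs 4 (stepping variability ≈ 0.23 vs 0.54 rad),
upward quick-phase rate 0.30 vs 0.02 s⁻¹, downward rate 0.40 vs 0.15 s⁻¹,
and DCN density negatively coupled to the true downward quick-phase rate.
Cadence, stride length (hence walking speed) and slow-phase gain parameters
are matched between groups. Per-animal parameters vary around the group
condition (e.g. stance fraction SD 0.015, cadence SD 0.25). Effect sizes
were chosen as a strong, phenotypically penetrant contrast — the regime the
pipeline is meant to flag reliably at these cohort sizes with exact
nonparametric tests (minimum attainable two-sided p at 8 vs 6 is ≈ 0.0007).

Across 50 seeded reruns the pipeline must flag each injected effect at
α = 0.05 in ≥ 90% of reruns and keep the pooled false-positive rate on null
measures (the matched gait measures plus the eight uncoupled
region-correlations) at ≤ 10%. Pooling is used because per-measure rates
estimated from 50 replicates of a nominal-5% test have substantial binomial
mass above 10% even when the test is exact.

## Problem sizes and determinism

Validation problem sizes — 100 parameter-recovery runs of ~15 strides,
200-stride variability checks, 100 CI simulations of 100 events, 500
enumeration comparisons, 50 cohort reruns — were chosen so the full
validation completes in a few minutes on one core while keeping Monte-Carlo
error well below the asserted margins. All generators take explicit integer
seeds; identical seed and parameters produce byte-identical outputs, and the
file pipeline records the config hash, seed and package version in a
provenance record so any output table can be regenerated exactly.
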