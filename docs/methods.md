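# Methods

`gaitpipe` implements the computation chain of a dual-instrument overground
gait assessment: one instrument is a markerless motion-capture (MLMC) volume
that reconstructs per-frame 4x4 segment poses at 60 Hz along a 10 m walkway,
the other a pressure-sensitive walkway (PSW) that reports footprint position
and contact timing at 100 Hz over a 3.6 m instrumented span. The package
covers event detection, the twelve spatiotemporal gait parameters, lower-limb
joint kinematics with reference-band comparison, a paired-instrument
agreement battery, feasibility-checklist tallying, and a synthetic generator
that emulates both instruments with full ground truth.

## Measurement model

**Coordinate frames.** The walkway frame has +Y along the walking path, +Z
up, and its origin at the calibration-object centre. Passes alternate
between +Y and -Y walking directions; all detection is direction-aware, so
results are invariant to the direction of travel. Within 1.5 m of each
walkway end (the capture margin) the biomechanical model is not yet fully
identified; poses there are flagged invalid and never used.

**Gait events.** Initial contact (IC) and toe off (TO) are found with the
coordinate-based rule: IC at local maxima of the heel's displacement from
the pelvis along the walking direction, TO at local minima of the toe's.
A minimum peak separation of half the stride period — estimated per pass
from the autocorrelation maximum of the displacement series in the 0.4-2.5 s
lag range — prevents double detection and adapts to walking speed. No
pre-filtering is applied by default; a zero-lag 4th-order 6 Hz Butterworth
low-pass is available for noisy data. Plateau extrema resolve to the
earliest frame. Event sequences are validated against the canonical
alternation IC(s), TO(opp), IC(opp), TO(s), IC(s); for the MLMC chain only
runs of at least 3 consecutive cycles are kept, the minimum for a usable
kinematic record. PSW events are the contact onsets/offsets of footprints
that occurred entirely within the instrumented span; because that span
physically admits only one or two complete strides per side per pass, the
PSW stride builder keeps validated runs of any length rather than requiring
3 consecutive cycles. Runs are also split at gaps longer than 1.5 s so
strides never span the rest between passes.

Events are reported on the instrument's frame grid. A frame-quantized
coordinate-based detector locates IC at the last frame before the true
contact and TO at the first frame after the true lift, so MLMC stance times
carry a small positive offset (up to one frame at each edge, ~10 ms at
60 Hz) relative to continuous truth; stride times, which difference two ICs,
are unbiased. This is inherent to frame-based event detection and is left
visible in the agreement tables rather than corrected.

**Spatiotemporal parameters.** Each stride (ipsilateral IC to next
ipsilateral IC) carries its five canonical event times and yields, in closed
form: stride time, step time, stance and swing time, 1st double support,
single support, and 2nd double support, with the exact identities
stride = stance + swing and stance = DS1 + single + DS2. Spatial parameters
are measured parallel to the walking direction between foot reference
positions: the ankle-joint-centre ground projection for MLMC (the foot
segment's proximal origin) and the heel coordinate for PSW footprints; the
systematic stride-width offset this pair of definitions can induce on real
data is surfaced in the agreement table, not hidden. Each stride carries its
ipsilateral step, the contralateral-IC to ipsilateral-IC half that ends the
stride; cadence is 120 / stride time so every row is self-contained, and
speed is stride length / stride time. Per-subject summaries use the
arithmetic mean and sample SD (n-1) across strides.

**Participant selection.** When several persons are reconstructed (spotter,
bystanders), eligible tracks must traverse at least 60 % of the usable
walkway along Y; among those the track with the smallest mean absolute
lateral offset from the centreline wins, with ties (< 5 cm) broken by
earliest entry into the usable volume. The rule is a heuristic
operationalization of "position relative to the global origin" and is fully
parameterized; a trailing on-centreline spotter is separated by lateral
offset first, then entry time.

**Joint kinematics.** Joint angles decompose the proximal-to-distal relative
rotation R_prox^T R_dist with the Cardan sequence equivalent to the joint
coordinate system: flexion about the proximal mediolateral axis first, then
ab/adduction, then axial rotation (X-Y'-Z''). Signs follow the right-sided
clinical convention (flexion/dorsiflexion +, adduction +, internal
rotation +), with the left side mirrored so left and right curves
superimpose; the raw Cardan X angle of the knee measures extension positive
and is negated. Gimbal proximity (|cos| of the middle angle < 1e-6) is
flagged. Curves are time-normalized to 101 points over the gait cycle by
linear interpolation, with a toe-off percent marker; reference bands are the
pointwise ensemble mean +/- SD over reference cycles (k_sd = 1 by default,
matching mean(SD) shading), and deviations are reported as maximal
cycle-percent intervals outside the band.

**Agreement battery.** For each parameter, matched per-subject means (the
default pairing unit; pooled mode exists for sensitivity analysis) feed:
the signed mean difference d = PSW - MLMC (negative means the walkway reads
lower) with percent error 100·mean(|d_i|)/mean(PSW); Bland-Altman 95 %
limits of agreement d_bar +/- 1.96·SD(d) with the classic fixed 1.96
multiplier (no small-sample t-correction) plus a t-based 95 % CI of the mean
difference; and single-measure ICCs from the two-way ANOVA decomposition,

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE)/n)
    ICC(3,1) = (MSR - MSE) / (MSR + (k-1) MSE)

with F-distribution 95 % confidence intervals (Satterthwaite degrees of
freedom for the agreement form). Ratings use half-open categories
[0, 0.5) poor, [0.5, 0.75) moderate, [0.75, 0.9) good, [0.9, 1] excellent;
the prose convention leaves boundary membership ambiguous, so boundaries
were assigned to the higher category. Zero between-subject variance yields a
flagged degenerate estimate. Note ICC(3,1) >= ICC(2,1) is guaranteed only
when both MSC >= MSE and MSR >= MSE (a non-negative estimate); for negative
estimates the inequality can reverse.

## Synthetic generator

The generator is the package's test bed: it emulates the paired experiment
with known ground truth, not a biomechanical simulation.

* **Timing.** A periodic step schedule derives from cadence (stride time
  T = 120/cadence), stance fraction f (default 0.65 of the stride), and
  optional left/right multiplicative asymmetry factors on step time and step
  length, normalized so stride totals are preserved. For symmetric periodic
  gait each double-support fraction is f - 0.5 and is derived, not set
  independently. Toe off follows each IC by fT.
* **Geometry.** Foot placements advance so that stride length equals
  speed x T exactly and the step-length split matches the configured
  asymmetry; stride width is the lateral separation of the two feet. The
  pelvis translates at constant speed with 1.5 cm vertical and 2 cm lateral
  sinusoidal oscillation at stride frequency.
* **Trajectories.** During stance the foot is exactly stationary; during
  swing the ankle follows a cubic-Hermite interpolant whose endpoint
  velocity equals the pelvis velocity, with 5 cm sinusoidal vertical
  clearance. The velocity-matched Hermite is the key design choice: it is a
  C1 smooth monotone interpolant whose pelvis-relative displacement has its
  maxima/minima exactly at the events, so the coordinate-based detector can
  be scored against truth at single-frame resolution, and the extremum
  remains identifiable under millimetre-scale noise.
* **Segments.** Thigh and shank poses come from a two-link inverse-kinematics
  chain (thigh and shank 0.44 m, hip centres +/- 9 cm lateral in the pelvis
  frame) between hip and ankle, with the knee displaced toward the walking
  direction and the chain clamped at full extension; heel and toe are fixed
  offsets in the foot frame (6 cm behind / 18 cm ahead of the ankle, at
  ground level). This yields periodic, plausible joint-angle curves while
  keeping foot placements exact; it does not reproduce physiological
  joint-angle magnitudes, foot pitch during rollover, or soft-tissue
  artefact, so kinematic tests demonstrate pipeline correctness, not
  clinical validity of the curves.
* **Instruments.** MLMC recordings sample poses at 60 Hz and flag frames
  within the capture margin invalid. PSW footprints are emitted at onset =
  true IC + contact latency and offset = true TO - latency (emulating a
  pressure threshold), with optional Gaussian timing jitter, quantized to
  the 100 Hz grid, and flagged incomplete unless heel and toe both lie
  within the instrumented span. Position noise is additive i.i.d. Gaussian
  on pose translations (MLMC only); the walkway's spatial output is taken
  as vendor-exact.
* **Extra tracks.** A spotter track trails the participant by 0.8 m along
  the path with a 0.3 m lateral offset; bystanders wander slowly outside the
  centreline corridor. A single integer seed drives every stochastic draw;
  identical configs are bit-identical.
* **Cohorts.** `generate_cohort` draws per-subject cadence and speed from a
  correlated bivariate normal (SDs 9.77 steps/min and 0.23 m/s, r = 0.8,
  the dispersion of a mixed-age self-selected walking cohort), with small
  between-subject variation in stance fraction (SD 0.01) and stride width
  (SD 3 cm), clipped to physiological ranges, and spawns deterministic child
  seeds.

What the generator does *not* emulate: pose-estimation dropout mid-walkway,
turning strides, assistive devices, soft-tissue artefact, camera occlusion,
or pressure-image content. Passing tests therefore show the computation
chain is correct on idealized signals of the right structure, not that the
upstream pose estimator is accurate on real video.

## Numerical choices

* Rotation validity: orthonormality to 1e-5 and det > 0 on load; Cardan
  decomposition uses the principal branch with the middle angle in
  (-90, 90) deg.
* Pass segmentation smooths pelvis Y-velocity with a 0.25 s moving average
  (well below stride frequency) before sign detection; passes need >= 2 m
  net displacement.
* Resampling is linear with endpoints preserved; a resampled point is valid
  only if both bracketing inputs are valid.
* Interval conventions: 0-based frames, half-open [start, stop) intervals,
  metres and seconds throughout.
* Tallying rounds success rates half-up to one decimal.
* Problem sizes in the validation studies: event recovery uses 100
  two-pass sessions per noise condition (~4,000 scored events); parameter
  recovery 10 four-pass subjects; the latency experiment 10 six-pass
  subjects; the noisy-cohort ICC study 40 subjects; the ICC oracle 1,000
  random matrices. These sizes give stable rates while keeping the whole
  battery to a few seconds.

## Known limitations

* C3D import/export requires the optional `ezc3d` dependency; the
  documented CSV dialect is the always-available interchange format.
* The ICC(2,1) confidence interval uses the standard F/Satterthwaite
  approximation; it can be conservative at very small n.
* MLMC stance/swing estimates inherit the half-frame event quantization
  offset described above; at 60 Hz this bounds sub-phase accuracy at about
  10 ms regardless of noise level.
* The per-question feasibility checklist is transcribed as a versioned CSV
  fixture; its tallying generalizes, but the packaged answers are fixed.
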