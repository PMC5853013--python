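# Methods

This note documents the models, procedures and numerical choices behind
`pdmotor`: what each stage computes, why its defaults are what they are,
what the synthetic-movement generator does and does not emulate, and the
known limitations.

## Signal model and preprocessing

A recording is a uniformly sampled 6-axis inertial time series: 3-axis
angular velocity (deg/s) and 3-axis acceleration (m/s², carried but unused
by the indexes), with metadata naming the sensor location (index finger,
thumb, metacarpus, wrist or arm), subject, medication state (OFF / ON /
healthy) and task. The default sampling rate is 128 Hz, the native rate of
common research-grade wearable IMUs.

Three zero-phase filters are provided, all 4th-order Butterworth applied
forward-backward (`sosfiltfilt`, reflect padding of three filter lengths,
so cycle boundaries keep their timing):

* 1 Hz high-pass — removes slow orientation drift of the body segment;
* 1–4 Hz band-pass — the bradykinesia analysis band;
* 4–8 Hz band-pass — the tremor band (provided for completeness; no tremor
  index is extracted).

The scalar speed profile v(t) ≥ 0 is either the absolute angular velocity
on the task's dominant gyroscope axis (*y* for finger tapping, *x* for
prono-supination — `task_axis_abs`) or the Euclidean norm of the three gyro
channels (`gyro_norm`). Segmentation and fatigability default to
`task_axis_abs`; smoothness defaults to `gyro_norm`. Both are config
switches, since the construction of v(t) from 3-axis data is a genuinely
open choice.

**Which band feeds which stage.** Total power is always computed in the
1–4 Hz bradykinesia band. Segmentation, fatigability and smoothness default
to the *unfiltered* speed profile, for two reasons established during
development:

1. Slow Parkinsonian repetition rates sit at or below the 1 Hz drift
   cutoff. A fragmented OFF-state tap cycle occupies ≈ 1–1.5 s, so the
   cycle fundamental (≈ 0.7 Hz) is inside the high-pass stopband; the
   filtered trace then acquires large compensating sweeps through the rest
   windows (the filter output must have no sub-1 Hz content) which defeat
   any threshold rule. The passive rigidity movement at ≈ 0.5 Hz is
   affected even more strongly.
2. The 1–4 Hz band is narrower than the harmonic content of a movement
   burst. At a 3 Hz repetition rate the band-passed signal degenerates to a
   near-pure 3 Hz tone whose envelope never drops between cycles, and
   band-passing biases peak-to-peak amplitudes (a −4 deg/s per cycle
   peak-to-peak ramp reads as ≈ −1.5 after band-passing).

For recordings with real sensor drift or strong tremor the config switches
`seg_band: highpass | bradykinesia` restore the filtered paths; the
trade-offs above then apply.

## Segmentation

A movement cycle is delimited where the speed profile crosses 10 % of that
cycle's own peak speed. Because a cycle may contain several speed humps
(open and close phases, hesitations) separated by near-zero dips, detection
is two-pass:

1. **Provisional bursts**: runs of v ≥ 10 % of the *global* peak; runs
   separated by less than `min_gap` (default 0.15 s) are merged — this is
   what groups an open-close pair, or a hesitating movement, into one
   cycle — and merged runs shorter than `min_duration` (default 0.10 s) are
   discarded as glitches. Neither constant is prescribed by the analysis
   definition; both were chosen as round values separating intra-cycle dips
   (≲ 0.1 s) from inter-cycle rests (≳ 0.2 s) at realistic movement rates.
2. **Per-cycle refinement**: each burst's boundaries are walked outward to
   the outermost samples at or above 10 % of that burst's own peak,
   stopping at the neighbouring burst. Crossings are taken at the first
   sample at/above threshold; no sub-sample interpolation.

Total time is `t_b − t_a` (end of last cycle minus begin of first). The
expected repetition count (15 taps / 15 prono-supinations / 10 passive
movements) is metadata only: a mismatch is logged, never enforced, since
patients' actual performance varies.

Per-cycle peak-to-peak angular velocity is max − min within the cycle
window, per gyroscope axis; fatigability is the ordinary-least-squares
slope of the task-axis values against cycle number 1…n (n ≥ 2 required).

## Total power

Welch PSD per axis: Hann window, segments of `min(512, N)` samples, 50 %
overlap, integrated over [0, Nyquist] by the trapezoid rule; the index is
the task-axis power by default (`power_axes: task | sum3`). The 512-sample
segment (4 s at 128 Hz, 0.25 Hz resolution) was chosen over shorter
segments because with 0.5 Hz bins the Hann main lobes of components 1 Hz
apart overlap in a shared bin and their coherent cross-term breaks the
additivity of the estimate (a 2 Hz + 3 Hz two-tone test signal reads 13 %
high at 256 samples, and exact at 512). A record shorter than one segment
degenerates to a single windowed periodogram, which is logged.

## Smoothness (spectral arc length)

The speed profile is zero-padded so the FFT grid spacing is ≤ 0.05 Hz
(configurable), the magnitude spectrum is normalized by its zero-frequency
value, and the cutoff ωc is the smaller of the cap (4 Hz bradykinesia /
20 Hz rigidity) and the highest grid frequency where the normalized
magnitude still reaches the 10 % threshold — scanning from the top of the
grid for the last index at/above threshold. The arc length is accumulated
segment-wise on the grid over (0, ωc], with the frequency axis normalized
by ωc. Degenerate profiles (all-zero: V(0) = 0) are an error; a spectrum
that collapses below threshold before the first non-zero grid point falls
back to the first grid interval and is logged. Normalization makes the
value exactly invariant to amplitude scaling, and invariant to time
dilation with proportionally scaled cutoff up to grid discretization
(≈ 5·10⁻⁷ at 0.005 Hz resolution).

Per-cycle SAL is computed on the unfiltered speed profile — the metric's
own spectral cutoff performs the low-pass action — and averaged across
cycles; cycles with undefined SAL are excluded from the mean and logged.

## The synthetic-movement generator

The generator produces 6-axis recordings with the statistical structure the
analysis assumes, so pipeline properties can be verified against known
ground truth.

**Waveform.** One movement (e.g. a finger opening) is a Gaussian angular
velocity pulse of width σ = 1/(24·rate) on the task axis; a cycle is an
opening pulse followed by a closing pulse of opposite sign with centres
4.8 σ apart, so a symmetric cycle has peak-to-peak exactly twice its peak
and the speed dips briefly to zero mid-cycle (merged by segmentation's
`min_gap`). Cycle k peaks at `base_amplitude + k·decay_per_cycle`, floored
at 5 % of base (floored cycles leave a warning in the metadata, not an
error). Pulse centres are snapped to the sample grid and cycle intervals
rounded to whole samples, so noiseless cycles are sampled identically —
peaks are exact and per-cycle SAL values agree to 10⁻⁹.

**Fragmentation.** A hesitant movement is built from
`n_submovements_per_cycle` same-sign sub-pulses staggered 0.2 s apart
(sub-pulse width floored at 25 ms). This stretches the movement and injects
spectral content at a few hertz — the submovement signature the spectral
arc length responds to. Fragmented cycles also rest 0.12 s longer per extra
submovement: hesitant repetition is slower, and the nominal period
stretches whenever the active burst plus minimum rest (0.18 s) exceeds
1/rate.

**Arrhythmicity, tremor, noise, leakage.** Inter-cycle intervals are
jittered multiplicatively (`rate_jitter_cv`); an optional tremor sinusoid
(4–8 Hz) rides on the task axis (30 % on the others); white noise is added
to all gyro channels; 10 % of the task-axis movement signal leaks into the
other two gyro axes so most-relevant-axis selection is testable; the
accelerometer carries gravity on z plus noise only.

**Rigidity.** The passive elbow task uses slow cycles (rate capped at
0.6 Hz) of brisker pulses (σ = 0.11 s, spectral centre ≈ 1.5 Hz), 10 cycles
by default. Cogwheel rigidity is emulated as raised-cosine velocity notches
repeating at 8 Hz (within the 6–9 Hz cogwheel range), `severity` notches
per movement, with depth growing with severity and each notch's depth
weighted by the movement-pulse height at its centre — interruptions bite
where the passive movement is fast, not in the near-zero tails (unweighted
tail notches split cycles under the 10 % rule). Severity defaults to
`n_submovements_per_cycle − 1`, so the smooth default has none.

**Cohorts.** A cohort draws per-subject parameters from per-group normal
distributions: 12 patients recorded in both OFF and ON states and 13
healthy controls by default, each at five sensor locations with distal →
proximal amplitude scaling (index 1.0 → arm 0.18; decay and tremor scale
with amplitude). A patient's OFF and ON draws share a latent severity
(correlation 0.7), giving the paired structure the repeated-measures
comparisons need. The group contrasts — OFF: rate 1.0 Hz, amplitude
150 deg/s, decay −3 deg/s per cycle, 3 submovements, jitter CV 0.15, tremor
5 deg/s; ON intermediate; healthy: 2.2 Hz, 350 deg/s, decay −0.3, smooth,
no tremor — are free design choices (no quantitative waveform description
of the states exists to estimate them from), set to plausible magnitudes
for mild-to-moderate disease. Task-time tremor is kept small relative to
movement amplitude because rest tremor is largely suppressed during
voluntary movement; recordings dominated by tremor would need the
band-passed segmentation path. Everything is reproducible from a single
seed, with per-recording seeds below 2³¹.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: biomechanical limb dynamics and realistic pulse
shapes (real velocity profiles are asymmetric), gravity and motion
artefacts in the accelerometer, sensor drift (the motivation for the 1 Hz
high-pass), magnetometer data, freezing episodes, amplitude *increase*
under hastening, or within-movement variability beyond the staggered
Gaussian model.

## Statistical layer

The ANOVA decompositions are delegated to `pingouin` (`rm_anova` with two
within factors; `mixed_anova`), wrapped behind the package's API; the test
suite verifies both against independent hand-written sums-of-squares
decompositions to 10⁻⁸. Uncorrected degrees of freedom are reported by
default, matching common practice of reporting integer df when sphericity
is not discussed; Greenhouse-Geisser correction is an option on the
repeated-measures path. Subjects with missing cells are excluded listwise
per analysis. Post hoc tests are per-location t-tests — paired for ON/OFF,
independent (pooled variance; Welch optional) against healthy — compared to
the Bonferroni threshold α/n; n defaults to the number of locations tested
(5 → 0.01; a 2-wrist rigidity montage → 0.025) and is exposed as a
parameter. Degenerate t-tests (zero-variance differences) are flagged
rather than raised. Correlations with the bundled per-subject UPDRS item
ratings (items 22, 23, 25, OFF and ON) are reported as squared Pearson
coefficients; zero-variance inputs return NaN with a warning.

Shapiro–Wilk screening is reported per (state, location) cell with no
automatic branching; cells with n < 3 or zero variance are marked
untestable.

**Calibration.** Under 500 seeded null replicates (standard-normal cohort
tables, 12 paired patients + 13 controls, 5 locations), the type-I error of
the repeated-measures state test, the mixed-design group test and both
t-tests lies within [0.03, 0.07] at α = 0.05. The end-to-end power study
simulates 200 replicate cohorts at two sensor locations (index finger and
wrist — 74 recordings per replicate) and computes only the total-power
index for speed; both the paired OFF/ON and the independent OFF/healthy
contrast at the index finger reject at the 0.01 Bonferroni threshold in
every replicate under the default group contrasts. The cohort-level
fatigability recovery experiment (12 patients + 3 controls, index finger)
correlates recovered slopes with the true decay parameters at R² ≈ 0.99.

## Known limitations

* With tremor amplitudes comparable to 10 % of movement amplitude, raw-band
  segmentation degrades; the band-passed path is then needed, with the
  caveats above.
* Mild cogwheel severities whose notch energy stays below the spectral
  10 % threshold leave the adaptive cutoff — and hence the SAL — nearly
  unchanged; the severity → SAL mapping is locally flat at the low end.
  This is a property of the metric's adaptive cutoff, not of the generator.
* The "single movement" (open vs close sub-phase) granularity of smoothness
  is exposed only at cycle level; sub-phase SAL would require splitting
  cycles at the mid-cycle speed minimum.
* The mixed-design ANOVA assumes homogeneous covariance across groups; no
  sphericity correction is applied by default.
* Index values from the simulator are on realistic scales but are not
  calibrated to any patient population; cohort-level effect sizes are
  design choices, so detection rates reported by the replicate studies
  validate the pipeline's machinery, not clinical effect sizes.
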