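# pdmotor

Quantitative kinematic analysis of Parkinsonian **bradykinesia** and
**rigidity** from wearable inertial sensor recordings.

Clinical rating of Parkinson's disease motor symptoms (UPDRS part III) is
semi-quantitative and examiner-dependent. Wearable magneto-inertial sensors
worn on the upper limb record the angular velocity of repetitive exam
movements — finger tapping (item 23), hand prono-supination (item 25) and
passive elbow flexion-extension for rigidity (item 22) — and allow the
symptoms to be described by objective kinematic indexes. `pdmotor`
implements that analysis as a reusable, tested pipeline for researchers
working with 6-axis IMU recordings of such tasks, together with a synthetic
movement generator so the whole pipeline can be exercised and validated
without patient data.

## The four kinematic indexes

For a recording with detected movement cycles (one cycle = the submovements
of one task repetition, delimited where the speed profile crosses 10 % of
the cycle's peak speed):

* **Total time** — `t_TOT = t_b − t_a`: end of the last cycle minus begin of
  the first; captures slowness.
* **Fatigability** — the slope *m* of the first-order fit `y = m·x + q` of
  per-cycle peak-to-peak angular velocity (task-dominant gyroscope axis: *y*
  for tapping, *x* for prono-supination) against cycle number *x* = 1…n;
  captures the progressive amplitude decrement.
* **Total power** — the integral of the power spectral density of the
  angular velocity (Welch estimate, integrated to Nyquist). By Parseval's
  theorem this equals the mean-square signal content and captures overall
  movement intensity and rhythmicity.
* **Smoothness** — the spectral arc length (SPARC):

  `SAL = −∫₀^ωc √[(1/ωc)² + (dV̂(ω)/dω)²] dω`, with `V̂(ω) = V(ω)/V(0)`

  the Fourier magnitude spectrum of the speed profile normalized at zero
  frequency, and the cutoff `ωc` the smaller of a cap (4 Hz for the active
  bradykinesia tasks, 20 Hz for passive rigidity) and the highest frequency
  at which `V̂` still reaches 10 %. Values are ≤ 0; less negative means
  smoother. Computed per cycle and averaged.

The cohort layer provides Shapiro–Wilk screening, two-way repeated-measures
ANOVA (state × sensor location, both within subjects), mixed-design ANOVA
(location within, patient-vs-healthy group between), Bonferroni-corrected
per-location post hoc t-tests (α/5 = 0.01 for the five-sensor montage),
paired/independent t-tests for total time, and R² correlations against the
bundled per-subject UPDRS item ratings.

## Worked example

Simulate one OFF-state-like recording (slow, low amplitude, strong decay,
hesitant, mildly tremulous) and one ON-state-like recording, then extract
the indexes:

```python
from pdmotor import SimulationParams, simulate_recording, extract_all

off = simulate_recording(
    SimulationParams(base_rate=1.0, base_amplitude=150, decay_per_cycle=-3.0,
                     rate_jitter_cv=0.15, n_submovements_per_cycle=3,
                     tremor_amplitude=5.0, noise_sd=0.5, seed=42),
    subject_id="P01", condition="OFF")
on = simulate_recording(
    SimulationParams(base_rate=1.6, base_amplitude=250, decay_per_cycle=-1.0,
                     rate_jitter_cv=0.08, n_submovements_per_cycle=2,
                     tremor_amplitude=2.0, noise_sd=0.5, seed=42),
    subject_id="P01", condition="ON")

for rec in (off, on):
    ks = extract_all(rec)
    print(f"{rec.condition}: cycles={ks.n_cycles}  "
          f"t_tot={ks.total_time:.2f} s  "
          f"slope={ks.fatigability.slope:.2f} deg/s per cycle  "
          f"power={ks.total_power:.0f} (deg/s)^2  "
          f"SAL={ks.smoothness.mean:.2f}")
```

prints

```
OFF: cycles=15  t_tot=24.64 s  slope=-6.00 deg/s per cycle  power=676 (deg/s)^2  SAL=-2.51
ON: cycles=15  t_tot=14.32 s  slope=-1.82 deg/s per cycle  power=2513 (deg/s)^2  SAL=-2.10
```

All 15 generated taps are found in both recordings. The OFF-like recording
takes 24.6 s against 14.3 s ON (slowness); its peak-to-peak velocity decays
at −6 deg/s per cycle — exactly twice the generated −3 deg/s amplitude decay,
since each symmetric open-close cycle swings from +peak to −peak — against
−1.8 ON; its total power is ~4× lower (smaller, slower movement); and its
mean spectral arc length is more negative (hesitant, fragmented movement).

The same workflow is available from the shell:

```
pdmotor simulate --config cohort.yaml --seed 7 --out recs/
pdmotor extract  --recordings recs/ --out indexes.csv
pdmotor stats    --index-csv indexes.csv --out results/
pdmotor report   --stats-dir results/
```

`stats` writes ANOVA, post hoc and t-test tables plus a star-matrix report
(one row per effect, one column per index, `*` p < 0.05, `**` p < 0.01).

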