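"""The four kinematic indexes quantifying bradykinesia and rigidity.

* **Total time** t_TOT = t_b - t_a: end of the last movement cycle minus
  begin of the first (computed in :mod:`pdmotor.segmentation`).
* **Fatigability**: the slope m of the first-order regression y = m x + q of
  per-cycle peak-to-peak angular velocity (on the task's dominant gyroscope
  axis) against cycle number — the progressive amplitude reduction of
  repetitive movement.
* **Total power**: the integral of the power spectral density of angular
  velocity; by Parseval's theorem this equals the signal's mean-square
  content and proxies overall movement intensity.
* **Smoothness**: the spectral arc length (SPARC) of the movement speed
  profile — the negative arc length of the normalized Fourier magnitude
  spectrum up to an adaptive cutoff omega_c, computed per cycle and averaged.
  The cutoff cap is 4 Hz for the active bradykinesia tasks and 20 Hz for the
  passive rigidity task; values are dimensionless and <= 0, with less
  negative meaning smoother.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .recording import SensorRecording, SpeedProfile, task_axis_index
from . import preprocessing, segmentation

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Fatigability
# ---------------------------------------------------------------------------

@dataclass
class FatigabilityFit:
    """Slope/intercept of peak-to-peak angular velocity vs cycle number."""

    slope: float  # deg/s per cycle
    intercept: float  # deg/s
    axis: str  # gyro axis used (x, y or z)
    n_cycles: int
    r_squared: float


def fatigability(cs: segmentation.CycleSet, task: str) -> FatigabilityFit:
    """Ordinary least squares of task-axis peak-to-peak speed on cycle number.

    Cycle numbers run 1..n.  Requires at least two cycles with populated
    ``ptp_by_axis`` (see :func:`pdmotor.segmentation.cycle_ptp`).
    """
    axis = task_axis_index(task)
    ptps = [c.ptp_by_axis for c in cs.cycles]
    if any(p is None for p in ptps):
        raise ValueError("cycle peak-to-peak values not populated; run cycle_ptp first")
    y = np.array([p[axis] for p in ptps], dtype=float)
    if y.size < 2:
        raise ValueError("fatigability slope needs at least 2 cycles")
    x = np.arange(1, y.size + 1, dtype=float)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    return FatigabilityFit(slope=float(slope), intercept=float(intercept),
                           axis="xyz"[axis], n_cycles=y.size, r_squared=r2)


# ---------------------------------------------------------------------------
# Total power
# ---------------------------------------------------------------------------

@dataclass
class PowerSpectrum:
    """Welch power spectral density per gyro axis with its integral."""

    freqs: np.ndarray  # Hz
    psd: np.ndarray  # (3, n_freqs), (deg/s)^2 / Hz
    power_by_axis: np.ndarray  # (3,), trapezoidal integral over [0, Nyquist]
    total_power: float  # (deg/s)^2, per the configured axis policy
    axis_policy: str
    window: str
    nperseg: int


def total_power(rec: SensorRecording, axis_policy: str = "task") -> PowerSpectrum:
    """Integral of the angular-velocity PSD over [0, Nyquist].

    The PSD is a Welch estimate (Hann window, segments of
    ``min(512, N)`` samples, 50 % overlap; a record shorter than one segment
    degenerates to a single periodogram, which Welch handles by shrinking the
    segment).  ``axis_policy="task"`` reports the task-axis power,
    ``"sum3"`` the sum over the three gyro axes.
    """
    n = rec.n_samples
    nperseg = min(512, n)
    if n < 512:
        logger.info("record of %d samples shorter than one PSD segment; "
                    "falling back to a single-segment periodogram", n)
    freqs, psd = sps.welch(rec.gyro, fs=rec.sample_rate, window="hann",
                           nperseg=nperseg, noverlap=nperseg // 2, axis=1)
    power_by_axis = np.trapezoid(psd, freqs, axis=1)
    if axis_policy == "task":
        total = float(power_by_axis[task_axis_index(rec.task)])
    elif axis_policy == "sum3":
        total = float(power_by_axis.sum())
    else:
        raise ValueError(f"unknown axis policy {axis_policy!r}")
    return PowerSpectrum(freqs=freqs, psd=psd, power_by_axis=power_by_axis,
                         total_power=total, axis_policy=axis_policy,
                         window="hann", nperseg=nperseg)


# ---------------------------------------------------------------------------
# Smoothness (SPARC)
# ---------------------------------------------------------------------------

@dataclass
class SparcConfig:
    """Settings of the spectral-arc-length computation.

    ``omega_c_max``: cap on the adaptive spectral cutoff (Hz) — 4 for the
    bradykinesia tasks, 20 for the passive rigidity task.
    ``magnitude_threshold``: the normalized-magnitude level (10 %) above
    which spectrum content keeps extending the cutoff.
    ``freq_resolution``: the FFT grid is zero-padded until its spacing is at
    most this (Hz).
    """

    omega_c_max: float = 4.0
    magnitude_threshold: float = 0.10
    freq_resolution: float = 0.05

    def __post_init__(self) -> None:
        if self.omega_c_max <= 0:
            raise ValueError("omega_c_max must be > 0")
        if not (0.0 < self.magnitude_threshold < 1.0):
            raise ValueError("magnitude_threshold must lie in (0, 1)")


BRADYKINESIA_SPARC = SparcConfig(omega_c_max=4.0)
RIGIDITY_SPARC = SparcConfig(omega_c_max=20.0)


def sparc(v: SpeedProfile | np.ndarray, cfg: SparcConfig = BRADYKINESIA_SPARC,
          sample_rate: float | None = None) -> float:
    """Spectral arc length of a speed profile; dimensionless, <= 0.

    The magnitude spectrum V(omega) of v(t) is normalized by its value at
    zero frequency; the cutoff omega_c is the smaller of ``omega_c_max`` and
    the highest frequency at which the normalized magnitude still reaches
    the 10 % threshold.  The returned value is the negative arc length of
    the normalized spectrum over (0, omega_c], with the frequency axis
    normalized by omega_c — so the result is invariant to amplitude scaling
    of v and, asymptotically, to time dilation with proportionally scaled
    cutoff.
    """
    if isinstance(v, SpeedProfile):
        speed, fs = v.v, v.sample_rate
    else:
        speed = np.asarray(v, dtype=float)
        if sample_rate is None:
            raise ValueError("sample_rate required for a bare array")
        fs = sample_rate
    if speed.size < 2:
        raise ValueError("speed profile needs more than one sample")

    n_fft = int(2 ** np.ceil(np.log2(max(fs / cfg.freq_resolution, speed.size))))
    mag = np.abs(np.fft.rfft(speed, n_fft))
    if mag[0] == 0.0:
        raise ValueError("speed profile has zero mean magnitude (V(0) = 0)")
    mag_norm = mag / mag[0]
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)

    above = np.flatnonzero(mag_norm >= cfg.magnitude_threshold)
    # above always contains index 0 (mag_norm[0] == 1).
    omega_c = min(cfg.omega_c_max, float(freqs[above[-1]]))
    sel = freqs <= omega_c
    if sel.sum() < 2:
        # Spectrum collapses below threshold before the first non-zero grid
        # point; fall back to the first grid interval.
        logger.info("degenerate SPARC cutoff; using the first grid interval")
        sel = np.zeros_like(sel)
        sel[:2] = True
        omega_c = float(freqs[1])
    f_sel = freqs[sel]
    m_sel = mag_norm[sel]
    du = np.diff(f_sel) / omega_c
    dm = np.diff(m_sel)
    return -float(np.sum(np.sqrt(du ** 2 + dm ** 2)))


@dataclass
class SmoothnessResult:
    """Per-cycle spectral arc lengths and their mean."""

    per_cycle: list[float]
    mean: float
    omega_c_max: float
    n_excluded: int = 0


def _smoothness(v: SpeedProfile, cs: segmentation.CycleSet,
                cfg: SparcConfig) -> SmoothnessResult:
    if not cs.cycles:
        raise ValueError("smoothness needs at least one detected cycle")
    values: list[float] = []
    n_excluded = 0
    for c in cs.cycles:
        try:
            values.append(sparc(v.slice(c.start_idx, c.end_idx), cfg))
        except ValueError as exc:
            n_excluded += 1
            logger.warning("cycle [%g, %g] excluded from smoothness: %s",
                           c.start_t, c.end_t, exc)
    if not values:
        raise ValueError("no cycle yielded a defined spectral arc length")
    return SmoothnessResult(per_cycle=values, mean=float(np.mean(values)),
                            omega_c_max=cfg.omega_c_max, n_excluded=n_excluded)


def smoothness_bradykinesia(v: SpeedProfile, cs: segmentation.CycleSet,
                            cfg: SparcConfig = BRADYKINESIA_SPARC) -> SmoothnessResult:
    """Per-cycle SPARC (cutoff cap 4 Hz) of the active-task speed profile.

    ``v`` should be the drift-removed (1 Hz high-passed) but otherwise
    unfiltered speed profile: the spectral cutoff supplies the low-pass
    action, so no analysis band-pass is applied.
    """
    return _smoothness(v, cs, cfg)


def smoothness_rigidity(v: SpeedProfile, cs: segmentation.CycleSet,
                        cfg: SparcConfig = RIGIDITY_SPARC) -> SmoothnessResult:
    """Mean SPARC (cutoff cap 20 Hz) of passive flexion-extension cycles."""
    return _smoothness(v, cs, cfg)


# ---------------------------------------------------------------------------
# Per-recording orchestration
# ---------------------------------------------------------------------------

@dataclass
class KinematicIndexSet:
    """The four indexes of one recording, plus identifying metadata.

    The passive rigidity task is described by smoothness only; its other
    fields stay ``None``.
    """

    subject_id: str
    condition: str
    task: str
    location: str
    total_time: float | None = None
    fatigability: FatigabilityFit | None = None
    total_power: float | None = None
    smoothness: SmoothnessResult | None = None
    n_cycles: int = 0
    warnings: list = field(default_factory=list)

    def to_rows(self) -> list[dict]:
        """Tidy rows (one per index) for CSV export."""
        base = dict(subject_id=self.subject_id, state=self.condition,
                    task=self.task, location=self.location)
        rows = []
        if self.total_time is not None:
            rows.append({**base, "index": "total_time", "value": self.total_time})
        if self.fatigability is not None:
            rows.append({**base, "index": "fatigability",
                         "value": self.fatigability.slope})
        if self.total_power is not None:
            rows.append({**base, "index": "total_power", "value": self.total_power})
        if self.smoothness is not None:
            rows.append({**base, "index": "smoothness", "value": self.smoothness.mean})
        return rows


class StageError(RuntimeError):
    """Failure of a named pipeline stage while extracting indexes."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def _banded(rec: SensorRecording, band: str) -> SensorRecording:
    if band == "raw":
        return rec
    if band == "highpass":
        return preprocessing.highpass_1hz(rec)
    return preprocessing.bandpass(rec, band)


def extract_all(rec: SensorRecording, threshold_frac: float = 0.10,
                seg_band: str = "raw",
                segmentation_mode: str = "task_axis_abs",
                smoothness_mode: str = "gyro_norm",
                smoothness_band: str = "raw",
                power_axis_policy: str = "task") -> KinematicIndexSet:
    """Run preprocessing, segmentation and all applicable indexes.

    Bradykinesia tasks (finger tapping, prono-supination) yield all four
    indexes; the passive rigidity task yields smoothness only.

    By default segmentation, fatigability and smoothness work on the
    unfiltered task-axis speed: slow Parkinsonian repetition rates
    (0.5-1 Hz) sit below the 1 Hz drift cutoff, so any drift-filtered trace
    acquires large compensating sweeps between cycles that defeat the 10 %
    threshold rule, and the smoothness metric's spectral cutoff performs its
    own low-pass action.  ``seg_band``/``smoothness_band`` accept
    ``"highpass"`` or ``"bradykinesia"`` for drifty or tremor-heavy real
    recordings.  Total power is always computed in the 1-4 Hz bradykinesia
    band.
    """
    out = KinematicIndexSet(subject_id=rec.subject_id, condition=rec.condition,
                            task=rec.task, location=rec.location)
    is_rigidity = rec.task == "rigidity"

    def run(stage, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
            raise StageError(stage, exc) from exc

    seg_rec = run("band_filter", _banded, rec, seg_band)
    v_seg = run("speed_profile", preprocessing.speed_profile, seg_rec, segmentation_mode)
    cs = run("segmentation", segmentation.detect_cycles, v_seg, threshold_frac,
             expected_count=segmentation.EXPECTED_COUNT.get(rec.task))
    out.n_cycles = len(cs)
    if cs.expected_count is not None and len(cs) != cs.expected_count:
        out.warnings.append(
            f"detected {len(cs)} cycles, expected {cs.expected_count}")

    smooth_rec = seg_rec if smoothness_band == seg_band else run(
        "band_filter", _banded, rec, smoothness_band)
    v_smooth = run("speed_profile", preprocessing.speed_profile, smooth_rec,
                   smoothness_mode)
    if is_rigidity:
        out.smoothness = run("smoothness", smoothness_rigidity, v_smooth, cs)
        return out

    out.total_time = run("total_time", segmentation.total_time, cs)
    run("cycle_ptp", segmentation.cycle_ptp, seg_rec, cs)
    out.fatigability = run("fatigability", fatigability, cs, rec.task)
    bp = run("bandpass", preprocessing.bandpass, rec, "bradykinesia")
    out.total_power = run("total_power", total_power, bp,
                          power_axis_policy).total_power
    out.smoothness = run("smoothness", smoothness_bradykinesia, v_smooth, cs)
    return out
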