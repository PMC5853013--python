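"""Synthetic 6-axis inertial recordings of UPDRS-III motor tasks.

The generator emulates the statistical structure the kinematic analysis
assumes, so the full pipeline can be exercised without patient data:

* quasi-periodic repetitive movement bursts — 15 taps, 15 prono-supinations
  or 10 passive elbow flexion-extensions;
* progressive amplitude decay across cycles (fatigability);
* inter-cycle arrhythmicity (jittered cycle intervals);
* submovement fragmentation within a movement (hesitations), and for the
  passive rigidity task a cogwheel-like notch modulation of the velocity;
* an optional 4-8 Hz tremor sinusoid and additive white sensor noise.

One movement (a finger opening, say) is a Gaussian angular-velocity pulse of
width sigma on the task's dominant gyroscope axis; a cycle is an opening
pulse followed by a closing pulse of opposite sign, so a symmetric cycle has
peak-to-peak angular velocity exactly twice its peak amplitude.  Cycle k
peaks at ``base_amplitude + k * decay_per_cycle`` (floored at 5 % of base to
avoid sign-flipped cycles).  Fragmented movements are built from
``n_submovements_per_cycle`` sub-pulses staggered 0.2 s apart, which stretches
the movement and injects spectral content at a few hertz — the signature the
spectral-arc-length smoothness index is sensitive to.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .recording import SensorRecording, LOCATIONS, TASKS, task_axis_index

#: Interval between staggered submovement pulses within one movement (s).
SUBMOVEMENT_INTERVAL = 0.20

#: Minimum rest between consecutive cycles (s); the nominal period
#: 1/base_rate is stretched when the active burst plus this rest exceeds it.
#: Fragmented (hesitant) movements rest longer: their larger net angular
#: excursion leaves a bigger drift-filter undershoot to die out, and slow
#: hesitant repetitions are the bradykinetic phenotype being emulated.
MIN_REST = 0.18
REST_PER_SUBMOVEMENT = 0.12

#: Fraction of the task-axis movement signal leaked into the two other
#: gyroscope axes, so that most-relevant-axis selection is testable.
OFF_AXIS_LEAKAGE = 0.10

#: Amplitude floor, as a fraction of base_amplitude, protecting strongly
#: decaying sequences from negative cycle amplitudes.
AMPLITUDE_FLOOR_FRAC = 0.05

#: Cogwheel notch geometry for the rigidity task: notches repeat at 8 Hz
#: (within the 6-9 Hz cogwheel range) with a raised-cosine profile.
NOTCH_INTERVAL = 1.0 / 8.0
NOTCH_HALF_WIDTH = 0.04

#: Gaussian pulse width for the passive rigidity movement (s).  The pulse
#: is brisk enough (~1.5 Hz spectral centre) to pass the 1 Hz drift filter
#: while the cycle repetition stays slow (~0.5 Hz).
RIGIDITY_SIGMA = 0.11


@dataclass
class SimulationParams:
    """Knobs of one simulated recording; defaults give a smooth performance.

    Units: rates in Hz, amplitudes in deg/s, decay in deg/s per cycle,
    times in seconds.
    """

    task: str = "finger_tapping"
    n_cycles: int | None = None  # 15 for bradykinesia tasks, 10 for rigidity
    base_rate: float = 2.0
    base_amplitude: float = 100.0
    decay_per_cycle: float = 0.0
    rate_jitter_cv: float = 0.0
    n_submovements_per_cycle: int = 1
    tremor_amplitude: float = 0.0
    tremor_freq: float = 5.0
    noise_sd: float = 0.0
    sample_rate: float = 128.0
    lead_in: float = 1.0
    lead_out: float = 1.0
    seed: int = 0

    def resolved(self) -> "SimulationParams":
        """Return a copy with task-dependent defaults filled in."""
        p = replace(self)
        if p.n_cycles is None:
            p.n_cycles = 10 if p.task == "rigidity" else 15
        if p.task == "rigidity":
            p.base_rate = min(p.base_rate, 0.6)
        return p

    def validate(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")
        n_cycles = self.n_cycles if self.n_cycles is not None else 1
        if n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.base_amplitude <= 0:
            raise ValueError("base_amplitude must be > 0")
        if self.rate_jitter_cv < 0:
            raise ValueError("rate_jitter_cv must be >= 0")
        if self.n_submovements_per_cycle < 1:
            raise ValueError("n_submovements_per_cycle must be >= 1")
        if self.base_rate <= 0:
            raise ValueError("base_rate must be > 0")
        if not (4.0 <= self.tremor_freq <= 8.0):
            raise ValueError("tremor_freq must lie in [4, 8] Hz")
        if self.sample_rate <= 2 * max(self.tremor_freq, 20.0):
            raise ValueError("sample_rate must exceed twice max(tremor_freq, 20 Hz)")


def _pulse_sigma(base_rate: float, n_submovements: int = 1) -> float:
    # One movement pulse (+/-3 sigma) spans a quarter of the nominal period.
    # Hesitant submovements have a floor on their width: a fragmented
    # movement is never briskier than a smooth one.
    sigma = 1.0 / (24.0 * base_rate)
    if n_submovements > 1:
        sigma = max(sigma, 0.025)
    return sigma


def _cycle_geometry(params: SimulationParams, sigma: float) -> tuple[float, float, float]:
    """Return (movement_span, movement_separation, active_span) in seconds."""
    n = params.n_submovements_per_cycle
    span = (n - 1) * SUBMOVEMENT_INTERVAL + 6.0 * sigma
    sep = (n - 1) * SUBMOVEMENT_INTERVAL + 4.8 * sigma
    return span, sep, sep + span


def _cycle_layout(params: SimulationParams, rng: np.random.Generator,
                  sigma: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Draw cycle start times and amplitudes.

    Returns (starts, amplitudes, active_span); a warning string is attached
    by the caller when the amplitude floor bites before the last cycle.
    """
    _, _, active = _cycle_geometry(params, sigma)
    rest = MIN_REST + REST_PER_SUBMOVEMENT * (params.n_submovements_per_cycle - 1)
    period = max(1.0 / params.base_rate, active + rest)
    jitter = rng.normal(0.0, params.rate_jitter_cv, size=max(params.n_cycles - 1, 0))
    intervals = np.maximum(period * (1.0 + jitter), active + 0.12)
    # snap intervals to the sample grid so noiseless cycles are sampled
    # identically regardless of the nominal period
    fs = params.sample_rate
    intervals = np.round(intervals * fs) / fs
    starts = params.lead_in + np.concatenate([[0.0], np.cumsum(intervals)])
    k = np.arange(params.n_cycles)
    amps = params.base_amplitude + k * params.decay_per_cycle
    floor = AMPLITUDE_FLOOR_FRAC * params.base_amplitude
    amps = np.maximum(amps, floor)
    return starts, amps, active


def _snap(c: float, fs: float) -> float:
    """Round a pulse centre onto the sample grid so peaks are sampled exactly."""
    return round(c * fs) / fs


def _notch_envelope(t: np.ndarray, notches: Iterable[tuple[float, float]]) -> np.ndarray:
    """Multiplicative cogwheel envelope: raised-cosine dips at given centres.

    ``notches`` yields (centre, depth) pairs; depths are pre-weighted by the
    movement-pulse height at each notch so interruptions bite where the
    passive movement is fast, not in the near-zero tails.
    """
    m = np.ones_like(t)
    for c, depth in notches:
        u = (t - c) / NOTCH_HALF_WIDTH
        mask = np.abs(u) < 1.0
        m[mask] *= 1.0 - depth * np.cos(0.5 * np.pi * u[mask]) ** 2
    return m


def _build_task_axis_signal(params: SimulationParams, rng: np.random.Generator,
                            sigma: float, severity: int | None = None,
                            ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Synthesize the clean task-axis angular velocity.

    Returns (t, signal, info) where info records true cycle windows and any
    amplitude-floor warning.
    """
    fs = params.sample_rate
    starts, amps, active = _cycle_layout(params, rng, sigma)
    span, sep, _ = _cycle_geometry(params, sigma)
    n_sub = params.n_submovements_per_cycle
    duration = starts[-1] + active + params.lead_out
    n_samples = int(round(duration * fs)) + 1
    t = np.arange(n_samples) / fs
    x = np.zeros(n_samples)

    offsets = (np.arange(n_sub) - (n_sub - 1) / 2.0) * SUBMOVEMENT_INTERVAL
    for s_k, a_k in zip(starts, amps):
        open_center = s_k + span / 2.0
        close_center = open_center + sep
        cycle = np.zeros(n_samples)
        for sign, center in ((1.0, open_center), (-1.0, close_center)):
            for off in offsets:
                c = _snap(center + off, fs)
                cycle += sign * a_k * np.exp(-0.5 * ((t - c) / sigma) ** 2)
        if severity is not None and severity > 0:
            depth = min(0.90, 0.52 + 0.08 * severity)
            notches = []
            for center in (open_center, close_center):
                rel = (np.arange(severity) - (severity - 1) / 2.0) * NOTCH_INTERVAL
                weights = np.exp(-0.5 * (rel / sigma) ** 2)
                notches.extend(zip(center + rel, depth * weights))
            cycle *= _notch_envelope(t, notches)
        x += cycle

    floor = AMPLITUDE_FLOOR_FRAC * params.base_amplitude
    raw = params.base_amplitude + np.arange(params.n_cycles) * params.decay_per_cycle
    warnings = []
    floored = np.flatnonzero(raw < floor)
    if floored.size and floored[0] < params.n_cycles - 1:
        warnings.append(
            f"amplitude floor ({floor:.3g} deg/s) reached at cycle {int(floored[0])}"
        )
    info = {
        "cycle_starts": starts.tolist(),
        "cycle_ends": (starts + active).tolist(),
        "cycle_amplitudes": amps.tolist(),
        "active_span": active,
        "warnings": warnings,
    }
    return t, x, info


def _assemble_recording(params: SimulationParams, t: np.ndarray, x: np.ndarray,
                        info: dict, rng: np.random.Generator,
                        location: str, subject_id: str, condition: str,
                        ) -> SensorRecording:
    fs = params.sample_rate
    axis = task_axis_index(params.task)
    gyro = np.zeros((3, t.size))
    gyro[axis] = x
    for other in range(3):
        if other != axis:
            gyro[other] += OFF_AXIS_LEAKAGE * x

    tremor_phase = rng.uniform(0.0, 2.0 * np.pi)
    if params.tremor_amplitude > 0:
        tremor = params.tremor_amplitude * np.sin(
            2.0 * np.pi * params.tremor_freq * t + tremor_phase
        )
        gyro[axis] += tremor
        for other in range(3):
            if other != axis:
                gyro[other] += 0.3 * tremor

    accel = np.zeros((3, t.size))
    accel[2] = 9.81
    if params.noise_sd > 0:
        gyro += rng.normal(0.0, params.noise_sd, size=gyro.shape)
        accel += rng.normal(0.0, 0.05, size=accel.shape)

    meta = {"simulation": asdict(params), **info}
    return SensorRecording(
        sample_rate=fs, t=t, gyro=gyro, accel=accel,
        location=location, subject_id=subject_id,
        condition=condition, task=params.task, meta=meta,
    )


def simulate_recording(params: SimulationParams, *, location: str = "index",
                       subject_id: str = "S0", condition: str = "HS",
                       ) -> SensorRecording:
    """Generate one 6-axis recording of a repetitive bradykinesia task.

    Deterministic given ``params.seed``.  Rigidity-task parameters are
    routed to :func:`simulate_rigidity`.
    """
    params = params.resolved()
    params.validate()
    if params.task == "rigidity":
        return simulate_rigidity(params, location=location,
                                 subject_id=subject_id, condition=condition)
    rng = np.random.default_rng(params.seed)
    sigma = _pulse_sigma(params.base_rate, params.n_submovements_per_cycle)
    t, x, info = _build_task_axis_signal(params, rng, sigma)
    return _assemble_recording(params, t, x, info, rng,
                               location, subject_id, condition)


def simulate_rigidity(params: SimulationParams, *, severity: int | None = None,
                      location: str = "wrist", subject_id: str = "S0",
                      condition: str = "HS") -> SensorRecording:
    """Generate a passive elbow flexion-extension recording.

    The movement is a slow (~0.5 Hz) open/close velocity pulse pair; cogwheel
    rigidity is emulated as ``severity`` raised-cosine velocity notches per
    movement, repeating at 7.5 Hz, whose depth grows with severity.  By
    default severity is ``n_submovements_per_cycle - 1`` so the smooth
    single-pulse default has no notches.
    """
    params = replace(params, task="rigidity").resolved()
    params.validate()
    if severity is None:
        severity = params.n_submovements_per_cycle - 1
    if severity < 0:
        raise ValueError("severity must be >= 0")
    rng = np.random.default_rng(params.seed)
    # Movements are single slow pulses; fragmentation is carried by the
    # notch envelope rather than by staggered sub-pulses.
    base = replace(params, n_submovements_per_cycle=1)
    t, x, info = _build_task_axis_signal(base, rng, RIGIDITY_SIGMA,
                                         severity=severity)
    info["severity"] = severity
    return _assemble_recording(params, t, x, info, rng,
                               location, subject_id, condition)


# ---------------------------------------------------------------------------
# Cohort-level simulation
# ---------------------------------------------------------------------------

#: Per-location amplitude scaling, distal to proximal: distal sensors see the
#: largest angular velocities during hand tasks.
DEFAULT_LOCATION_SCALE = {
    "index": 1.0, "thumb": 0.85, "metacarpus": 0.55, "wrist": 0.40, "arm": 0.18,
}

#: Group-level means and standard deviations of the simulation parameters for
#: the bradykinesia tasks.  OFF: slow, low-amplitude, strongly decaying,
#: fragmented, arrhythmic, tremulous; ON: intermediate; healthy: fast and
#: smooth.  Amplitudes are for the index-finger sensor before location
#: scaling; all values deg/s, Hz or dimensionless as in SimulationParams.
DEFAULT_GROUP_PARAMS = {
    "OFF": {
        "base_rate": (1.0, 0.15), "base_amplitude": (150.0, 30.0),
        "decay_per_cycle": (-3.0, 0.5), "rate_jitter_cv": (0.15, 0.03),
        "n_submovements_per_cycle": (3, 0), "tremor_amplitude": (5.0, 2.0),
        "tremor_freq": (5.0, 0.5), "noise_sd": (0.5, 0.0),
    },
    "ON": {
        "base_rate": (1.6, 0.2), "base_amplitude": (250.0, 40.0),
        "decay_per_cycle": (-1.0, 0.4), "rate_jitter_cv": (0.08, 0.02),
        "n_submovements_per_cycle": (2, 0), "tremor_amplitude": (2.0, 1.0),
        "tremor_freq": (5.0, 0.5), "noise_sd": (0.5, 0.0),
    },
    "HS": {
        "base_rate": (2.2, 0.25), "base_amplitude": (350.0, 50.0),
        "decay_per_cycle": (-0.3, 0.3), "rate_jitter_cv": (0.04, 0.01),
        "n_submovements_per_cycle": (1, 0), "tremor_amplitude": (0.0, 0.0),
        "tremor_freq": (5.0, 0.5), "noise_sd": (0.5, 0.0),
    },
}

#: Rigidity-task severities (cogwheel notch counts) per group.
DEFAULT_RIGIDITY_SEVERITY = {"OFF": 5, "ON": 2, "HS": 0}

#: Correlation between a PD subject's OFF and ON parameter draws: the same
#: latent severity underlies both medication states.
WITHIN_SUBJECT_RHO = 0.7


@dataclass
class CohortSpec:
    """Design of a simulated cohort.

    ``n_pd`` Parkinson's subjects are each recorded in both OFF and ON
    states (the paired structure the repeated-measures comparisons need);
    ``n_hs`` healthy subjects are recorded once.
    """

    n_pd: int = 12
    n_hs: int = 13
    tasks: tuple[str, ...] = ("finger_tapping",)
    locations: tuple[str, ...] = LOCATIONS
    location_scale: dict = field(default_factory=lambda: dict(DEFAULT_LOCATION_SCALE))
    group_params: dict = field(default_factory=lambda: {
        g: dict(v) for g, v in DEFAULT_GROUP_PARAMS.items()
    })
    rigidity_severity: dict = field(
        default_factory=lambda: dict(DEFAULT_RIGIDITY_SEVERITY))
    sample_rate: float = 128.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_pd < 1 or self.n_hs < 1:
            raise ValueError("each group needs at least one subject")
        for task in self.tasks:
            if task not in TASKS:
                raise ValueError(f"unknown task {task!r}")
        for loc in self.locations:
            if loc not in LOCATIONS:
                raise ValueError(f"unknown location {loc!r}")
            if self.location_scale.get(loc, 0.0) <= 0:
                raise ValueError(f"location_scale[{loc!r}] must be > 0")


_PARAM_BOUNDS = {
    "base_rate": (0.5, 4.0),
    "base_amplitude": (20.0, None),
    "decay_per_cycle": (None, 0.0),
    "rate_jitter_cv": (0.0, 0.5),
    "tremor_amplitude": (0.0, None),
    "tremor_freq": (4.0, 8.0),
    "noise_sd": (0.0, None),
}


def _clip(name: str, value: float) -> float:
    lo, hi = _PARAM_BOUNDS.get(name, (None, None))
    if lo is not None:
        value = max(value, lo)
    if hi is not None:
        value = min(value, hi)
    return value


def _draw_subject_params(group: dict, u: float, rng: np.random.Generator) -> dict:
    """Draw one subject-state parameter set.

    ``u`` is the subject's latent severity; draws mix the shared latent with
    independent noise so OFF and ON values of one subject are correlated.
    """
    out = {}
    for name, (mean, sd) in group.items():
        if name == "n_submovements_per_cycle":
            out[name] = int(round(mean))
            continue
        z = WITHIN_SUBJECT_RHO * u + math.sqrt(1 - WITHIN_SUBJECT_RHO ** 2) * rng.normal()
        out[name] = _clip(name, mean + sd * z)
    return out


def simulate_cohort(spec: CohortSpec) -> tuple[list[SensorRecording], pd.DataFrame]:
    """Simulate a full cohort: recordings plus a ground-truth parameter table.

    One recording per subject-state x location x task; PD subjects appear in
    both OFF and ON.  The returned table has one row per recording with the
    true generating parameters, for recovery experiments.  Fully reproducible
    from ``spec.seed``.
    """
    spec.validate()
    seeds = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(seeds.spawn(1)[0])

    subjects: list[tuple[str, str, tuple[str, ...]]] = []
    for i in range(spec.n_pd):
        subjects.append((f"P{i + 1:02d}", "PD", ("OFF", "ON")))
    for i in range(spec.n_hs):
        subjects.append((f"H{i + 1:02d}", "HS", ("HS",)))

    recordings: list[SensorRecording] = []
    truth_rows: list[dict] = []
    rec_seed = 1  # deterministic per-recording seed counter below 2**31
    base_seed = int(np.random.default_rng(seeds.spawn(1)[0]).integers(0, 2 ** 20))

    for subject_id, group, states in subjects:
        u = rng.normal()
        for state in states:
            drawn = _draw_subject_params(spec.group_params[state], u, rng)
            for task in spec.tasks:
                for loc in spec.locations:
                    scale = spec.location_scale[loc]
                    params = SimulationParams(
                        task=task,
                        base_rate=drawn["base_rate"],
                        base_amplitude=drawn["base_amplitude"] * scale,
                        decay_per_cycle=drawn["decay_per_cycle"] * scale,
                        rate_jitter_cv=drawn["rate_jitter_cv"],
                        n_submovements_per_cycle=drawn["n_submovements_per_cycle"],
                        tremor_amplitude=drawn["tremor_amplitude"] * scale,
                        tremor_freq=drawn["tremor_freq"],
                        noise_sd=drawn["noise_sd"],
                        sample_rate=spec.sample_rate,
                        seed=(base_seed + rec_seed) % (2 ** 31),
                    )
                    rec_seed += 1
                    if task == "rigidity":
                        sev = spec.rigidity_severity[state]
                        rec = simulate_rigidity(
                            params, severity=sev, location=loc,
                            subject_id=subject_id, condition=state,
                        )
                    else:
                        rec = simulate_recording(
                            params, location=loc,
                            subject_id=subject_id, condition=state,
                        )
                    recordings.append(rec)
                    row = {
                        "subject_id": subject_id, "group": group,
                        "state": state, "task": task, "location": loc,
                        "seed": params.seed,
                    }
                    row.update({k: v for k, v in asdict(params.resolved()).items()
                                if k not in ("task", "seed")})
                    if task == "rigidity":
                        row["severity"] = spec.rigidity_severity[state]
                    truth_rows.append(row)

    truth = pd.DataFrame(truth_rows)
    return recordings, truth
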