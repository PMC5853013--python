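"""Band-specific filtering of inertial signals and speed-profile derivation.

Raw gyroscope data are high-pass filtered at 1 Hz to remove slow orientation
drift of the body segment; the bradykinesia analysis band is 1-4 Hz and the
tremor band 4-8 Hz.  All filters are 4th-order Butterworth applied
forward-backward (zero phase), so cycle boundaries found on filtered traces
keep their timing.  The smoothness (spectral arc length) analysis uses only
the 1 Hz high-passed signal: the metric's own spectral cutoff performs the
low-pass action, so no analysis band-pass is applied upstream of it.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .recording import SensorRecording, SpeedProfile, task_axis_index

FILTER_ORDER = 4

#: Analysis bands in Hz: symptom-specific pass bands on the gyroscope data.
BANDS = {
    "bradykinesia": (1.0, 4.0),
    "tremor": (4.0, 8.0),
}

_BAND_TAG = {"bradykinesia": "bradykinesia_1_4", "tremor": "tremor_4_8"}


def _design_highpass(fs: float):
    return sps.butter(FILTER_ORDER, 1.0, btype="highpass", fs=fs, output="sos")


def _design_bandpass(band: str, fs: float):
    try:
        lo, hi = BANDS[band]
    except KeyError:
        raise ValueError(f"unknown band {band!r}; expected one of {sorted(BANDS)}") from None
    return sps.butter(FILTER_ORDER, (lo, hi), btype="bandpass", fs=fs, output="sos")


def _padlen(sos: np.ndarray) -> int:
    # Reflect-pad three filter lengths per pass (sosfiltfilt's default pad
    # is shorter; a longer pad suppresses edge transients on short records).
    return 3 * (2 * sos.shape[0] + 1)


def _apply_sos(rec: SensorRecording, sos: np.ndarray) -> np.ndarray:
    padlen = _padlen(sos)
    if rec.n_samples <= padlen:
        raise ValueError(
            f"recording too short to filter: {rec.n_samples} samples <= "
            f"pad length {padlen}"
        )
    return sps.sosfiltfilt(sos, rec.gyro, axis=1, padtype="even", padlen=padlen)


def highpass_1hz(rec: SensorRecording) -> SensorRecording:
    """1 Hz high-pass (drift removal) of all gyroscope channels, zero phase."""
    if rec.sample_rate <= 2.0:
        raise ValueError("sample rate must exceed 2 Hz for a 1 Hz high-pass")
    sos = _design_highpass(rec.sample_rate)
    out = rec.copy_with(gyro=_apply_sos(rec, sos))
    out.meta["band"] = "highpass_1hz"
    return out


def bandpass(rec: SensorRecording, band: str = "bradykinesia") -> SensorRecording:
    """Symptom-band filtering: 1-4 Hz (bradykinesia) or 4-8 Hz (tremor)."""
    sos = _design_bandpass(band, rec.sample_rate)
    out = rec.copy_with(gyro=_apply_sos(rec, sos))
    out.meta["band"] = _BAND_TAG[band]
    return out


def band_frequency_response(kind: str, fs: float, freqs: np.ndarray) -> np.ndarray:
    """|H(f)|^2 of the designed zero-phase filter at the given frequencies.

    ``kind`` is ``"highpass"`` or a band name.  The squared magnitude
    accounts for the forward-backward application.
    """
    sos = _design_highpass(fs) if kind == "highpass" else _design_bandpass(kind, fs)
    _, h = sps.sosfreqz(sos, worN=2 * np.pi * np.asarray(freqs, float) / fs)
    return np.abs(h) ** 2


def speed_profile(rec: SensorRecording, mode: str = "gyro_norm") -> SpeedProfile:
    """Scalar speed v(t) from the 3-axis angular velocity.

    ``task_axis_abs``: absolute angular velocity on the task's dominant axis
    (y for finger tapping, x for prono-supination).  ``gyro_norm``: Euclidean
    norm of the three gyroscope channels.
    """
    if mode == "task_axis_abs":
        axis = task_axis_index(rec.task)
        v = np.abs(rec.gyro[axis])
    elif mode == "gyro_norm":
        v = np.linalg.norm(rec.gyro, axis=0)
    else:
        raise ValueError(f"unknown speed mode {mode!r}")
    return SpeedProfile(
        t=rec.t, v=v, sample_rate=rec.sample_rate,
        provenance=mode, band=rec.meta.get("band", "raw"),
    )
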