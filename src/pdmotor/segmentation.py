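"""Movement-cycle detection from speed profiles.

A movement cycle is the set of submovements completing one task repetition
(e.g. one open-close of the fingers).  Cycles are delimited where the speed
profile crosses 10 % of the cycle's own peak speed, realized as a two-pass
procedure: provisional bursts above 10 % of the *global* peak are merged
across short gaps (an open-close pair or a hesitation is one cycle, not
two) and pruned of glitches, then each burst's boundaries are refined to the
nearest crossings of 10 % of that burst's *own* peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recording import SensorRecording, SpeedProfile

logger = logging.getLogger(__name__)

#: Bursts separated by less than this are merged into one cycle (s).
DEFAULT_MIN_GAP = 0.15

#: Bursts shorter than this after merging are discarded as glitches (s).
DEFAULT_MIN_DURATION = 0.10

#: Expected repetition counts per task, recorded as metadata only; a
#: mismatch is logged, never enforced — patients' performance varies.
EXPECTED_COUNT = {"finger_tapping": 15, "pronosupination": 15, "rigidity": 10}


@dataclass
class MovementCycle:
    """One detected task repetition; indices are half-open [start, end)."""

    start_idx: int
    end_idx: int
    start_t: float
    end_t: float
    peak_speed: float
    ptp_by_axis: np.ndarray | None = None  # deg/s per gyro axis, filled later

    @property
    def duration(self) -> float:
        return self.end_t - self.start_t


@dataclass
class CycleSet:
    """Ordered, non-overlapping movement cycles of one recording."""

    cycles: list[MovementCycle] = field(default_factory=list)
    expected_count: int | None = None
    sample_rate: float | None = None

    def __len__(self) -> int:
        return len(self.cycles)

    def __iter__(self):
        return iter(self.cycles)

    @property
    def t_a(self) -> float:
        """Begin of the first cycle."""
        if not self.cycles:
            raise ValueError("empty cycle set has no t_a")
        return self.cycles[0].start_t

    @property
    def t_b(self) -> float:
        """End of the last cycle."""
        if not self.cycles:
            raise ValueError("empty cycle set has no t_b")
        return self.cycles[-1].end_t

    def to_frame(self) -> pd.DataFrame:
        """One row per cycle, suitable for CSV export."""
        rows = []
        for i, c in enumerate(self.cycles):
            row = {
                "cycle": i + 1, "start_t": c.start_t, "end_t": c.end_t,
                "start_idx": c.start_idx, "end_idx": c.end_idx,
                "peak_speed": c.peak_speed,
            }
            if c.ptp_by_axis is not None:
                row.update(ptp_x=c.ptp_by_axis[0], ptp_y=c.ptp_by_axis[1],
                           ptp_z=c.ptp_by_axis[2])
            rows.append(row)
        return pd.DataFrame(rows)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True in a boolean mask."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    return list(zip(idx[0::2], idx[1::2]))


def detect_cycles(v: SpeedProfile, threshold_frac: float = 0.10,
                  min_gap: float = DEFAULT_MIN_GAP,
                  min_duration: float = DEFAULT_MIN_DURATION,
                  expected_count: int | None = None) -> CycleSet:
    """Detect movement cycles where speed exceeds 10 % of the cycle peak.

    Pass 1 finds bursts above ``threshold_frac`` of the global peak, merges
    bursts separated by less than ``min_gap`` seconds and discards merged
    bursts shorter than ``min_duration``.  Pass 2 moves each burst's
    boundaries to the nearest crossings of ``threshold_frac`` times that
    burst's own peak (the per-cycle threshold), taking the first sample at or
    above threshold, and never crossing into a neighbouring burst.

    An all-zero profile yields an empty :class:`CycleSet`.
    """
    if not (0.0 < threshold_frac < 1.0):
        raise ValueError("threshold_frac must lie in (0, 1)")
    speed = v.v
    fs = v.sample_rate
    out = CycleSet(expected_count=expected_count, sample_rate=fs)
    global_peak = speed.max(initial=0.0)
    if global_peak <= 0.0:
        return out

    # Pass 1: provisional bursts against the global threshold.
    runs = _runs_above(speed >= threshold_frac * global_peak)
    gap_samples = int(round(min_gap * fs))
    merged: list[list[int]] = []
    for start, end in runs:
        if merged and start - merged[-1][1] < gap_samples:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    min_len = int(round(min_duration * fs))
    bursts = [(s, e) for s, e in merged if e - s >= min_len]

    # Pass 2: refine boundaries against each burst's own 10 % threshold.
    cycles: list[MovementCycle] = []
    for i, (start, end) in enumerate(bursts):
        local_peak = float(speed[start:end].max())
        local_thr = threshold_frac * local_peak
        left_lim = bursts[i - 1][1] if i > 0 else 0
        right_lim = bursts[i + 1][0] if i + 1 < len(bursts) else speed.size
        while start > left_lim and speed[start - 1] >= local_thr:
            start -= 1
        while end < right_lim and speed[end] >= local_thr:
            end += 1
        cycles.append(MovementCycle(
            start_idx=start, end_idx=end,
            start_t=float(v.t[start]), end_t=float(v.t[end - 1]),
            peak_speed=local_peak,
        ))
    out.cycles = cycles
    if expected_count is not None and len(cycles) != expected_count:
        logger.warning("detected %d cycles, expected %d", len(cycles), expected_count)
    return out


def total_time(cs: CycleSet) -> float:
    """Total task time: end of the last cycle minus begin of the first."""
    if not cs.cycles:
        raise ValueError("total time undefined for an empty cycle set")
    return cs.t_b - cs.t_a


def cycle_ptp(rec: SensorRecording, cs: CycleSet) -> CycleSet:
    """Fill per-cycle, per-axis peak-to-peak angular velocities in place.

    The recording must be the (band-passed) signal the cycles were detected
    on, sample-aligned with the cycle indices.
    """
    for c in cs.cycles:
        if c.end_idx > rec.n_samples or c.start_idx < 0:
            raise ValueError(
                f"cycle [{c.start_idx}, {c.end_idx}) out of range for a "
                f"recording of {rec.n_samples} samples"
            )
        seg = rec.gyro[:, c.start_idx:c.end_idx]
        c.ptp_by_axis = seg.max(axis=1) - seg.min(axis=1)
    return cs
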