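"""Replicate studies validating the statistical layer and the pipeline.

Three canned experiments, all fully seeded:

* :func:`null_type1_rates` — type-I error calibration of the
  repeated-measures state test, the mixed-design group test and both
  t-tests under data with no true effects;
* :func:`discrimination_rates` — end-to-end detection power: fraction of
  simulated cohorts in which the total-power index separates OFF from ON
  (paired) and OFF from healthy (independent) at a distal sensor at the
  Bonferroni-corrected threshold;
* :func:`fatigability_recovery` — agreement between each recording's true
  amplitude-decay parameter and the fatigability slope recovered by the
  pipeline, as an R^2 across one simulated cohort.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import preprocessing, indices, stats
from .recording import LOCATIONS
from .synthetic import CohortSpec, simulate_cohort

_NULL_LOCATIONS = LOCATIONS


def _null_table(rng: np.random.Generator, n_pd: int, n_hs: int) -> pd.DataFrame:
    """Cohort table with standard-normal values: no state or group effect."""
    rows = []
    for s in range(n_pd):
        for state in ("OFF", "ON"):
            for loc in _NULL_LOCATIONS:
                rows.append((f"P{s}", "PD", state, "finger_tapping", loc,
                             "total_power", rng.normal()))
    for s in range(n_hs):
        for loc in _NULL_LOCATIONS:
            rows.append((f"H{s}", "HS", "HS", "finger_tapping", loc,
                         "total_power", rng.normal()))
    return pd.DataFrame(rows, columns=stats.COHORT_COLUMNS)


def null_type1_rates(n_reps: int = 500, seed: int = 0, n_pd: int = 12,
                     n_hs: int = 13, alpha: float = 0.05) -> dict[str, float]:
    """Empirical type-I error of each test op under null simulations.

    Returns rejection rates at ``alpha`` for: the repeated-measures state
    main effect, the mixed-design group main effect, the paired t-test and
    the independent t-test (the latter two on the index-finger cell).
    """
    rng = np.random.default_rng(seed)
    hits = {"rm_state": 0, "mixed_group": 0, "paired_t": 0, "independent_t": 0}
    for _ in range(n_reps):
        df = _null_table(rng, n_pd, n_hs)
        rm = stats.rm_anova_state_by_location(df, "total_power", "finger_tapping")
        if rm.p_of("state") < alpha:
            hits["rm_state"] += 1
        mx = stats.mixed_anova_group_by_location(df, "total_power",
                                                 "finger_tapping", ("OFF", "HS"))
        if mx.p_of("group") < alpha:
            hits["mixed_group"] += 1
        cell = df[df["location"] == "index"]
        off = cell[cell["state"] == "OFF"].set_index("subject_id")["value"]
        on = cell[cell["state"] == "ON"].set_index("subject_id")["value"]
        hs = cell[cell["state"] == "HS"]["value"].to_numpy()
        if stats.paired_t(off.to_numpy(), on.loc[off.index].to_numpy()).p < alpha:
            hits["paired_t"] += 1
        if stats.independent_t(off.to_numpy(), hs).p < alpha:
            hits["independent_t"] += 1
    return {k: v / n_reps for k, v in hits.items()}


def _total_power_table(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a cohort and extract only the total-power index (fast path)."""
    recordings, _ = simulate_cohort(spec)
    rows = []
    for rec in recordings:
        bp = preprocessing.bandpass(rec, "bradykinesia")
        power = indices.total_power(bp).total_power
        rows.append((rec.subject_id, "HS" if rec.condition == "HS" else "PD",
                     rec.condition, rec.task, rec.location, "total_power", power))
    return pd.DataFrame(rows, columns=stats.COHORT_COLUMNS)


def discrimination_rates(n_reps: int = 200, seed: int = 0,
                         location: str = "index",
                         alpha: float = 0.05,
                         n_comparisons: int = 5) -> dict[str, float]:
    """End-to-end detection rates for the total-power index.

    For each replicate cohort (default OFF / ON / healthy contrast of the
    simulator), the pipeline extracts total power at a distal sensor and
    tests OFF vs ON (paired) and OFF vs healthy (independent) against the
    Bonferroni threshold ``alpha / n_comparisons`` (0.01 for the five-sensor
    montage).  Returns the fraction of replicates flagging each contrast.
    """
    threshold = stats.bonferroni_threshold(alpha, n_comparisons)
    seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2 ** 31)
    hits = {"state_off_on": 0, "group_off_hs": 0}
    for rep_seed in seeds:
        spec = CohortSpec(tasks=("finger_tapping",),
                          locations=(location, "wrist"),
                          seed=int(rep_seed))
        df = _total_power_table(spec)
        cell = df[df["location"] == location]
        off = cell[cell["state"] == "OFF"].set_index("subject_id")["value"]
        on = cell[cell["state"] == "ON"].set_index("subject_id")["value"]
        hs = cell[cell["state"] == "HS"]["value"].to_numpy()
        if stats.paired_t(off.to_numpy(), on.loc[off.index].to_numpy()).p < threshold:
            hits["state_off_on"] += 1
        if stats.independent_t(off.to_numpy(), hs).p < threshold:
            hits["group_off_hs"] += 1
    return {k: v / n_reps for k, v in hits.items()}


def fatigability_recovery(seed: int = 0, n_pd: int = 12,
                          location: str = "index") -> float:
    """R^2 between true per-recording amplitude decay and recovered slope.

    Simulates one cohort (index-finger tapping only), runs the full
    extraction on each recording, and correlates the fatigability slope
    with the generating ``decay_per_cycle``.  For the generator's symmetric
    open-close cycles the expected slope is twice the decay, so perfect
    recovery gives R^2 = 1.
    """
    spec = CohortSpec(n_pd=n_pd, n_hs=3, tasks=("finger_tapping",),
                      locations=(location,), seed=seed)
    recordings, truth = simulate_cohort(spec)
    slopes, decays = [], []
    for rec in recordings:
        ks = indices.extract_all(rec)
        if ks.fatigability is None:
            continue
        row = truth[(truth["subject_id"] == rec.subject_id)
                    & (truth["state"] == rec.condition)
                    & (truth["location"] == rec.location)].iloc[0]
        slopes.append(ks.fatigability.slope)
        decays.append(row["decay_per_cycle"])
    return stats.r_squared(np.asarray(slopes), np.asarray(decays))
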