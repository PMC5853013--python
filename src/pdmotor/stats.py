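"""Cohort-level statistics for the kinematic indexes.

The analysis design mirrors standard practice for ON/OFF medication studies:

* Shapiro-Wilk normality screening per (state, location) cell — reported,
  with no automatic branching;
* two-way repeated-measures ANOVA with medication state (ON vs OFF) and
  sensor location (5 levels) as within-subject factors;
* mixed-design ANOVA with sensor location within subjects and group
  (patients-OFF vs healthy, or patients-ON vs healthy) between subjects;
* post hoc per-location t-tests (paired for ON/OFF, independent vs healthy)
  compared against a Bonferroni-corrected threshold alpha / n_comparisons;
* paired / independent t-tests for the total-time index;
* squared Pearson correlations (R^2) between index values and the clinical
  UPDRS part-III item scores, whose printed per-subject ratings are bundled
  as fixture tables.

The ANOVA decompositions are delegated to ``pingouin``; uncorrected degrees
of freedom are reported by default (a Greenhouse-Geisser flag is available
on the repeated-measures path).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sst

logger = logging.getLogger(__name__)

COHORT_COLUMNS = ["subject_id", "group", "state", "task", "location", "index", "value"]


# ---------------------------------------------------------------------------
# Cohort table plumbing
# ---------------------------------------------------------------------------

def build_cohort_table(index_sets) -> pd.DataFrame:
    """Long-format cohort table from per-recording index sets."""
    rows = []
    for ks in index_sets:
        for row in ks.to_rows():
            row["group"] = "HS" if row["state"] == "HS" else "PD"
            rows.append(row)
    df = pd.DataFrame(rows)
    return validate_cohort_table(df[COHORT_COLUMNS])


def validate_cohort_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format invariants: required columns, no duplicate keys."""
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns {missing}")
    key = ["subject_id", "state", "task", "location", "index"]
    dup = df.duplicated(subset=key)
    if dup.any():
        raise ValueError(f"{int(dup.sum())} duplicate (subject, state, task, "
                         "location, index) keys in cohort table")
    return df


def _cell(df: pd.DataFrame, index: str, task: str) -> pd.DataFrame:
    sub = df[(df["index"] == index) & (df["task"] == task)]
    if sub.empty:
        raise ValueError(f"no rows for index {index!r}, task {task!r}")
    return sub


# ---------------------------------------------------------------------------
# Normality screening
# ---------------------------------------------------------------------------

def shapiro_screen(df: pd.DataFrame, index: str, task: str) -> pd.DataFrame:
    """Shapiro-Wilk W and p per (state, location) cell.

    Cells with fewer than 3 values or zero variance are marked untestable.
    Report only — downstream tests are not switched on the outcome.
    """
    sub = _cell(df, index, task)
    rows = []
    for (state, location), grp in sub.groupby(["state", "location"], sort=False):
        vals = grp["value"].to_numpy(dtype=float)
        row = {"state": state, "location": location, "n": vals.size,
               "W": np.nan, "p": np.nan, "testable": False}
        if vals.size >= 3 and np.ptp(vals) > 0:
            w, p = sst.shapiro(vals)
            row.update(W=float(w), p=float(p), testable=True)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ANOVA layer
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """One ANOVA analysis: per-effect F table plus design metadata."""

    design: str  # "rm2way" | "mixed"
    effects: pd.DataFrame  # columns: effect, F, df1, df2, p
    n_subjects: int
    correction: str = "none"
    posthoc: pd.DataFrame | None = None

    def effect(self, name: str) -> pd.Series:
        match = self.effects[self.effects["effect"] == name]
        if match.empty:
            raise KeyError(f"no effect {name!r}; have {list(self.effects['effect'])}")
        return match.iloc[0]

    def p_of(self, name: str) -> float:
        return float(self.effect(name)["p"])


def _complete_pd_subjects(sub: pd.DataFrame, states, locations) -> pd.DataFrame:
    """Keep only subjects observed in every state x location cell (listwise)."""
    need = len(states) * len(locations)
    counts = sub.groupby("subject_id").size()
    complete = counts[counts == need].index
    dropped = sorted(set(sub["subject_id"]) - set(complete))
    if dropped:
        logger.warning("dropping %d subjects with incomplete cells: %s",
                       len(dropped), dropped)
    return sub[sub["subject_id"].isin(complete)]


def rm_anova_state_by_location(df: pd.DataFrame, index: str, task: str,
                               states: tuple[str, str] = ("OFF", "ON"),
                               locations: tuple[str, ...] | None = None,
                               correction: bool = False) -> AnovaResult:
    """Two-way repeated-measures ANOVA: state x sensor location, both within.

    Patients with any missing state x location cell are dropped listwise.
    ``correction=True`` applies Greenhouse-Geisser corrected p-values.
    """
    import pingouin as pg

    sub = _cell(df, index, task)
    sub = sub[sub["state"].isin(states)]
    if locations is not None:
        sub = sub[sub["location"].isin(locations)]
    locs = tuple(sub["location"].unique())
    sub = _complete_pd_subjects(sub, states, locs)
    n_subj = sub["subject_id"].nunique()
    if n_subj < 3:
        raise ValueError(f"repeated-measures ANOVA needs >= 3 complete "
                         f"subjects, have {n_subj}")
    aov = pg.rm_anova(data=sub, dv="value", within=["state", "location"],
                      subject="subject_id", detailed=True, correction=correction)
    aov = aov.rename(columns={"p-unc": "p_unc", "p-GG-corr": "p_GG_corr"})
    p_col = "p_GG_corr" if correction and "p_GG_corr" in aov else "p_unc"
    effects = pd.DataFrame({
        "effect": aov["Source"].str.replace(" * ", " x ", regex=False),
        "F": aov["F"], "df1": aov["ddof1"], "df2": aov["ddof2"],
        "p": aov[p_col],
    })
    return AnovaResult(design="rm2way", effects=effects, n_subjects=n_subj,
                       correction="greenhouse-geisser" if correction else "none")


def mixed_anova_group_by_location(df: pd.DataFrame, index: str, task: str,
                                  group_pair: tuple[str, str] = ("OFF", "HS"),
                                  ) -> AnovaResult:
    """Mixed-design ANOVA: location within subjects, group between.

    ``group_pair`` selects the two between-subject arms by state label,
    e.g. ``("OFF", "HS")`` compares patients off medication with healthy
    subjects.  Every subject must have all locations.
    """
    import pingouin as pg

    sub = _cell(df, index, task)
    sub = sub[sub["state"].isin(group_pair)]
    locs = tuple(sub["location"].unique())
    sub = _complete_pd_subjects(sub, ("one",), locs)
    sizes = sub.groupby("state")["subject_id"].nunique()
    for g in group_pair:
        if sizes.get(g, 0) < 3:
            raise ValueError(f"group {g!r} has {sizes.get(g, 0)} subjects; "
                             "need >= 3")
    aov = pg.mixed_anova(data=sub, dv="value", within="location",
                         subject="subject_id", between="state")
    aov = aov.rename(columns={"p-unc": "p_unc"})
    effects = pd.DataFrame({
        "effect": aov["Source"].replace({"state": "group",
                                         "Interaction": "group x location"}),
        "F": aov["F"], "df1": aov["DF1"], "df2": aov["DF2"],
        "p": aov["p_unc"],
    })
    return AnovaResult(design="mixed", effects=effects,
                       n_subjects=int(sizes.sum()))


# ---------------------------------------------------------------------------
# t-tests and Bonferroni-corrected post hoc comparisons
# ---------------------------------------------------------------------------

def bonferroni_threshold(alpha: float, n_comparisons: int) -> float:
    """Corrected significance threshold alpha / n_comparisons."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    return alpha / n_comparisons


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    kind: str  # "paired" | "independent"
    degenerate: bool = False


def paired_t(x, y) -> TTestResult:
    """Two-sided paired-samples t-test.

    A constant non-zero difference vector has zero variance and an undefined
    statistic; it is flagged degenerate (p = 0 by convention).  Identical
    samples give t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired t-test needs two equal-length samples, n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    n = d.size
    if sd == 0.0:
        if d.mean() == 0.0:
            return TTestResult(t=0.0, df=n - 1, p=1.0, kind="paired")
        return TTestResult(t=math.copysign(math.inf, d.mean()), df=n - 1,
                           p=0.0, kind="paired", degenerate=True)
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * sst.t.sf(abs(t), n - 1)
    return TTestResult(t=float(t), df=n - 1, p=float(p), kind="paired")


def independent_t(x, y, equal_var: bool = True) -> TTestResult:
    """Two-sided independent-samples t-test (pooled variance by default;
    ``equal_var=False`` switches to Welch)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("independent t-test needs n >= 2 per group")
    if x.std(ddof=1) == 0.0 and y.std(ddof=1) == 0.0:
        same = x.mean() == y.mean()
        return TTestResult(t=0.0 if same else math.inf,
                           df=x.size + y.size - 2, p=1.0 if same else 0.0,
                           kind="independent", degenerate=True)
    t, p = sst.ttest_ind(x, y, equal_var=equal_var)
    if equal_var:
        dof = x.size + y.size - 2
    else:
        vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        dof = (vx + vy) ** 2 / (vx ** 2 / (x.size - 1) + vy ** 2 / (y.size - 1))
    return TTestResult(t=float(t), df=float(dof), p=float(p), kind="independent")


def posthoc_by_location(df: pd.DataFrame, index: str, task: str,
                        comparison: tuple[str, str],
                        alpha: float = 0.05,
                        n_comparisons: int | None = None) -> pd.DataFrame:
    """Per-location t-tests for a state or group contrast.

    ON/OFF contrasts use paired tests on subjects measured in both states;
    contrasts against healthy subjects use independent (pooled-variance)
    tests.  Each raw p is compared against the Bonferroni threshold
    ``alpha / n_comparisons`` (default: the number of locations tested).
    """
    sub = _cell(df, index, task)
    a, b = comparison
    locations = [loc for loc in sub["location"].unique()]
    n_comp = n_comparisons if n_comparisons is not None else len(locations)
    threshold = bonferroni_threshold(alpha, n_comp)
    paired = "HS" not in comparison
    rows = []
    for loc in locations:
        cell = sub[sub["location"] == loc]
        xa = cell[cell["state"] == a].set_index("subject_id")["value"]
        xb = cell[cell["state"] == b].set_index("subject_id")["value"]
        if paired:
            common = xa.index.intersection(xb.index)
            res = paired_t(xa.loc[common].to_numpy(), xb.loc[common].to_numpy())
        else:
            res = independent_t(xa.to_numpy(), xb.to_numpy())
        rows.append({"location": loc, "t": res.t, "df": res.df,
                     "p_raw": res.p, "threshold": threshold,
                     "significant": bool(res.p < threshold),
                     "degenerate": res.degenerate})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# UPDRS correlation
# ---------------------------------------------------------------------------

def r_squared(x, y) -> float:
    """Squared Pearson correlation; NaN (with a warning) when either vector
    has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("correlation needs >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("zero-variance vector: correlation undefined")
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


_UPDRS_FILES = {
    "patients": "updrs_patients.csv",
    "bradykinesia": "updrs_bradykinesia.csv",
    "rigidity": "updrs_rigidity.csv",
}

#: UPDRS part-III item per motor task.
TASK_ITEM = {"finger_tapping": 23, "pronosupination": 25, "rigidity": 22}


def load_updrs_table(which: str) -> pd.DataFrame:
    """Bundled per-subject UPDRS part-III clinical ratings.

    ``which`` is ``"patients"`` (cohort characteristics and total motor
    score in OFF), ``"bradykinesia"`` (items 23 and 25, OFF and ON) or
    ``"rigidity"`` (item 22 per arm, OFF and ON).
    """
    try:
        fname = _UPDRS_FILES[which]
    except KeyError:
        raise ValueError(f"unknown table {which!r}; expected one of "
                         f"{sorted(_UPDRS_FILES)}") from None
    ref = resources.files("pdmotor").joinpath("data", fname)
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def updrs_item_scores(task: str, state: str, side: str = "right") -> pd.Series:
    """Per-subject item score for a task and medication state.

    Returns a Series indexed by subject id; for the rigidity task ``side``
    selects the rated arm.
    """
    state = state.lower()
    if state not in ("off", "on"):
        raise ValueError("state must be OFF or ON")
    if task == "rigidity":
        df = load_updrs_table("rigidity")
        col = f"item22_{side.lower()}_{state}"
    else:
        df = load_updrs_table("bradykinesia")
        col = f"item{TASK_ITEM[task]}_{task}_{state}"
    return df.set_index("subject_id")[col]


def r_squared_vs_updrs(df: pd.DataFrame, index: str, task: str, state: str,
                       location: str, scores: pd.Series | None = None) -> float:
    """R^2 between an index at one sensor location and the UPDRS item score.

    ``scores`` defaults to the bundled clinical ratings; pass a Series
    indexed by subject id to correlate against other ratings.  Subjects
    missing from either side are dropped.
    """
    if scores is None:
        scores = updrs_item_scores(task, state)
    sub = _cell(df, index, task)
    sub = sub[(sub["state"] == state) & (sub["location"] == location)]
    vals = sub.set_index("subject_id")["value"]
    common = vals.index.intersection(scores.index)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} subjects shared between index "
                         "values and UPDRS scores")
    return r_squared(vals.loc[common].to_numpy(), scores.loc[common].to_numpy())
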