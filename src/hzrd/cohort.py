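"""Rollout eligibility rules, study cohorts, outcome ascertainment, centering.

The vaccination program made the vaccine available from September 1, 2013 in
yearly catch-up waves keyed to date of birth: persons born on or before
September 1, 1933 (80+ at program start) never became eligible; those born
September 2, 1933 - September 1, 1942 became eligible in a staggered schedule;
from April 1, 2017 eligibility switched to the 78th-birthday rule.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from hzrd.dates import (
    as_datetime64,
    center_weeks,
    is_monday,
    straddle_week_monday,
)
from hzrd.exceptions import DataIntegrityError, DomainError, SchemaError

PROGRAM_START = dt.date(2013, 9, 1)
THRESHOLD_DATE = dt.date(1933, 9, 2)
SPAN_START = dt.date(1925, 9, 1)
SPAN_END = dt.date(1942, 9, 1)

DAYS_PER_MONTH = 30.44  # month arithmetic for the MCI-not-followed-by-dementia rule

DEFAULT_DEMENTIA_CODES = frozenset({"F00", "F01", "F02", "F03", "G30"})

COHORT_RULES = ("no_cognitive_impairment", "living_with_dementia")


@dataclass(frozen=True)
class EligibilitySchedule:
    """Program cohort label and first eligibility window for one date of birth."""

    cohort_label: str  # never_eligible, catchup_year_1..4, post_2017_rule, routine
    eligibility_start: dt.date | None
    eligibility_end: dt.date | None


def assign_eligibility(date_of_birth: dt.date) -> EligibilitySchedule:
    """Eligibility cohort and window per the printed rollout schedule.

    Raises :class:`DomainError` for dates of birth outside the supported span
    (September 1, 1925 - September 1, 1942).
    """
    d = date_of_birth
    if not (SPAN_START <= d <= SPAN_END):
        raise DomainError(f"date of birth {d} outside supported span {SPAN_START}..{SPAN_END}")
    if d <= dt.date(1933, 9, 1):
        return EligibilitySchedule("never_eligible", None, None)
    if d <= dt.date(1934, 9, 1):
        return EligibilitySchedule("catchup_year_1", dt.date(2013, 9, 1), dt.date(2014, 8, 31))
    if d <= dt.date(1936, 9, 1):
        return EligibilitySchedule("catchup_year_2", dt.date(2014, 9, 1), dt.date(2015, 8, 31))
    if d <= dt.date(1937, 9, 1):
        return EligibilitySchedule("catchup_year_3", dt.date(2015, 9, 1), dt.date(2016, 8, 31))
    if d <= dt.date(1938, 9, 1):
        return EligibilitySchedule("catchup_year_4", dt.date(2016, 9, 1), dt.date(2017, 8, 31))
    # post-2017 rule: eligible on the 78th birthday (not before April 1, 2017),
    # remaining eligible until the 80th birthday
    try:
        b78 = d.replace(year=d.year + 78)
        b80 = d.replace(year=d.year + 80)
    except ValueError:  # Feb 29
        b78 = d.replace(year=d.year + 78, day=28)
        b80 = d.replace(year=d.year + 80, day=28)
    start = max(b78, dt.date(2017, 4, 1))
    return EligibilitySchedule("post_2017_rule", start, b80)


def eligibility_start_vector(dob: np.ndarray) -> np.ndarray:
    """Vectorized first-eligibility dates (NaT for the never-eligible)."""
    d = as_datetime64(dob)
    conds = [
        d <= np.datetime64("1933-09-01"),
        d <= np.datetime64("1934-09-01"),
        d <= np.datetime64("1936-09-01"),
        d <= np.datetime64("1937-09-01"),
        d <= np.datetime64("1938-09-01"),
    ]
    choices = [
        np.datetime64("NaT", "D"),
        np.datetime64("2013-09-01"),
        np.datetime64("2014-09-01"),
        np.datetime64("2015-09-01"),
        np.datetime64("2016-09-01"),
    ]
    out = np.select(conds, choices, default=np.datetime64("NaT", "D")).astype("datetime64[D]")
    post = d > np.datetime64("1938-09-01")
    if post.any():
        starts = [np.datetime64(max(assign_eligibility(x.astype(dt.date)).eligibility_start,
                                    dt.date(2017, 4, 1)), "D")
                  for x in d[post]]
        out[post] = np.array(starts, dtype="datetime64[D]")
    return out


def build_cohort(persons: pd.DataFrame, which: str) -> pd.DataFrame:
    """Select one of the two study cohorts by baseline cognitive status.

    ``no_cognitive_impairment``: no record of any cognitive impairment prior to
    program start. ``living_with_dementia``: a dementia diagnosis prior to
    program start. Persons with non-dementia cognitive impairment belong to
    neither cohort. Returns a new table; input unmodified.
    """
    if which not in COHORT_RULES:
        raise DomainError(f"unknown cohort {which!r}; expected one of {COHORT_RULES}")
    if which == "no_cognitive_impairment":
        mask = persons["baseline_cognitive_impairment"].to_numpy() == 0
    else:
        mask = persons["baseline_dementia"].to_numpy() == 1
    return persons.loc[mask].reset_index(drop=True)


@dataclass(frozen=True)
class OutcomeSpec:
    """Outcome definition over a configurable follow-up window.

    ``window_shift_years`` shifts both ends of the follow-up window (0 for the
    primary analysis, -9 for the pre-period confounding test, +/-k when the
    threshold itself is moved in placebo analyses). The grace period delays
    the start of outcome ascertainment without extending the window end.
    """

    name: str = "mci"
    follow_up_years: int = 9
    grace_period_weeks: int = 0
    index_date_policy: str = "program_start"  # or "own_eligibility_date"
    window_shift_years: int = 0
    dementia_codes: frozenset = field(default_factory=lambda: DEFAULT_DEMENTIA_CODES)

    def __post_init__(self):
        if not (1 <= self.follow_up_years <= 9):
            raise DomainError(f"follow_up_years must be in 1..9, got {self.follow_up_years}")
        if self.grace_period_weeks < 0:
            raise DomainError("grace_period_weeks must be nonnegative")
        if self.index_date_policy not in ("program_start", "own_eligibility_date"):
            raise DomainError(f"unknown index_date_policy {self.index_date_policy!r}")


def load_code_sets(path) -> dict:
    """Outcome code sets from a YAML mapping (outcome name -> list of codes)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return {k: frozenset(v) for k, v in raw.items()}



def _datecol(persons: pd.DataFrame, col: str) -> np.ndarray:
    """Column as datetime64[D], robust to object-dtype single-row frames."""
    return pd.to_datetime(persons[col]).to_numpy().astype("datetime64[D]")

def _window(persons: pd.DataFrame, spec: OutcomeSpec, threshold_date=THRESHOLD_DATE):
    """Per-person (index, ascertainment start, window end) as datetime64 arrays."""
    n = len(persons)
    shift = spec.window_shift_years
    if spec.index_date_policy == "program_start":
        index = np.full(n, np.datetime64(PROGRAM_START.replace(year=PROGRAM_START.year + shift), "D"))
    else:
        dob = _datecol(persons, "date_of_birth")
        start = eligibility_start_vector(dob)
        # staggered index for the never-eligible by mirroring: a person born k
        # weeks before the threshold adopts the index date of the person born k
        # weeks after it, preserving age at index across the threshold
        thr = as_datetime64(threshold_date)
        nat = np.isnat(start)
        if nat.any():
            mirrored = thr + (thr - dob[nat])
            start[nat] = eligibility_start_vector(mirrored)
        if shift:
            start = start + np.timedelta64(int(round(shift * 365.25)), "D")
        index = start
    grace = np.timedelta64(int(spec.grace_period_weeks * 7), "D")
    end = np.array([np.datetime64(
        (d.astype(object).replace(year=d.astype(object).year + spec.follow_up_years)
         - dt.timedelta(days=1)), "D") if not np.isnat(d) else np.datetime64("NaT", "D")
        for d in np.unique(index)])
    lut = dict(zip(np.unique(index), end))
    window_end = np.array([lut[d] for d in index], dtype="datetime64[D]")
    return index.astype("datetime64[D]"), (index + grace).astype("datetime64[D]"), window_end


def _in_window(dates: np.ndarray, start: np.ndarray, end: np.ndarray) -> np.ndarray:
    d = dates.astype("datetime64[D]")
    return (~np.isnat(d)) & (d >= start) & (d <= end)


def _event_dates(persons: pd.DataFrame, base: str) -> list[np.ndarray]:
    """All date columns that can carry an event for outcome ``base``."""
    cols = []
    for cand in (f"{base}_date", f"event_{base}_date", f"preperiod_{base}_date"):
        if cand in persons.columns:
            cols.append(_datecol(persons, cand))
    return cols


def ascertain_outcomes(persons: pd.DataFrame, spec: OutcomeSpec,
                       threshold_date=THRESHOLD_DATE) -> np.ndarray:
    """Vectorized binary outcome over the spec's follow-up window.

    Supported names: ``mci``, ``mci_no_dementia_3m``/``6m``, ``dementia``,
    ``dementia_type:<type>``, ``death_due_to_dementia``, ``death_nondementia``,
    ``death_all_cause``, ``vaccine_uptake``, ``column:<col>`` (a baseline
    column used directly, for balance tests), or any name with a matching
    ``event_<name>_date``/``preperiod_<name>_date`` column.
    """
    name = spec.name
    if name.startswith("column:"):
        col = name.split(":", 1)[1]
        if col not in persons.columns:
            raise SchemaError(f"balance column {col!r} not in person table")
        return persons[col].to_numpy().astype(float)

    _, start, end = _window(persons, spec, threshold_date)
    n = len(persons)

    # integrity: dementia diagnosis after death is inconsistent
    if "dementia_date" in persons.columns and "death_date" in persons.columns:
        dd = _datecol(persons, "dementia_date")
        de = _datecol(persons, "death_date")
        bad = (~np.isnat(dd)) & (~np.isnat(de)) & (dd > de)
        if bad.any():
            raise DataIntegrityError(
                f"{int(bad.sum())} records have dementia_date after death_date")

    if name == "vaccine_uptake":
        v = _datecol(persons, "vaccination_date")
        return ((~np.isnat(v)) & (v <= end)).astype("int8")

    if name in ("mci", "mci_no_dementia_3m", "mci_no_dementia_6m"):
        hit = np.zeros(n, dtype=bool)
        for dates in _event_dates(persons, "mci"):
            hit |= _in_window(dates, start, end)
        if name != "mci":
            months = 3 if name.endswith("3m") else 6
            lag = np.timedelta64(int(round(months * DAYS_PER_MONTH)), "D")
            mci = _datecol(persons, "mci_date")
            dem = _datecol(persons, "dementia_date")
            followed = (~np.isnat(mci)) & (~np.isnat(dem)) & (dem <= mci + lag)
            hit &= ~followed
        return hit.astype("int8")

    if name == "dementia" or name.startswith("dementia_type:"):
        hit = np.zeros(n, dtype=bool)
        for dates in _event_dates(persons, "dementia"):
            hit |= _in_window(dates, start, end)
        if name.startswith("dementia_type:"):
            want = name.split(":", 1)[1]
            hit &= persons["dementia_type"].to_numpy() == want
        return hit.astype("int8")

    if name in ("death_due_to_dementia", "death_nondementia", "death_all_cause"):
        death = persons["death_date"].to_numpy() if "death_date" in persons.columns \
            else np.full(n, np.datetime64("NaT"))
        hit = _in_window(death, start, end)
        for dates in _event_dates(persons, name):  # pre-period death indicators
            hit |= _in_window(dates, start, end)
        if name == "death_all_cause":
            return hit.astype("int8")
        codes = spec.dementia_codes
        underlying = persons["underlying_cause"].astype(str).to_numpy()
        und_dem = np.isin(underlying, list(codes))
        if name == "death_due_to_dementia":
            return (hit & und_dem).astype("int8")
        contrib = persons["contributing_causes"].astype(str).to_numpy()
        contrib_dem = np.array([any(c in codes for c in s.split(";")) if s else False
                                for s in contrib])
        return (hit & ~und_dem & ~contrib_dem).astype("int8")

    # generic event-dated outcome (negative controls, preventive uptake indicators)
    cols = _event_dates(persons, name)
    if not cols:
        raise SchemaError(f"no event date column found for outcome {name!r}")
    hit = np.zeros(n, dtype=bool)
    for dates in cols:
        hit |= _in_window(dates, start, end)
    return hit.astype("int8")


def ascertain_outcome(person: pd.Series, spec: OutcomeSpec) -> int:
    """Single-person convenience wrapper around :func:`ascertain_outcomes`."""
    return int(ascertain_outcomes(person.to_frame().T, spec)[0])


def center_running_variable(week_of_birth, threshold_date=THRESHOLD_DATE,
                            straddle_rule: str = "majority"):
    """Signed weeks of a Monday birth week from the eligibility threshold.

    0 is the first week on the eligible side; weeks on the ineligible side are
    negative. Raises :class:`DomainError` for non-Monday input.
    """
    return center_weeks(week_of_birth, threshold_date, straddle_rule)


def build_analysis_cohort(persons: pd.DataFrame,
                          cohort: str = "no_cognitive_impairment",
                          outcome: OutcomeSpec | str = "mci",
                          threshold_date=THRESHOLD_DATE,
                          straddle_rule: str = "majority",
                          covariates: tuple = (),
                          frequent_attenders_only: bool = False) -> pd.DataFrame:
    """Assemble the row-per-person analysis table for the RD estimators.

    Columns: person_id, centered_wob, eligible (== centered_wob >= 0),
    vaccinated (receipt by end of the follow-up window), outcome, gender,
    male, rollout_cohort, plus any requested covariate columns carried over.
    """
    if isinstance(outcome, str):
        outcome = OutcomeSpec(name=outcome)
    sub = build_cohort(persons, cohort) if cohort is not None else persons.reset_index(drop=True)
    if frequent_attenders_only:
        cols = [f"pc_visits_prior_y{j}" for j in range(1, 6)]
        mask = np.ones(len(sub), dtype=bool)
        for c in cols:
            mask &= sub[c].to_numpy() >= 1
        sub = sub.loc[mask].reset_index(drop=True)

    wob = _datecol(sub, "week_of_birth")
    if not np.all(is_monday(wob)):
        raise DomainError("week_of_birth column contains non-Monday dates")
    x = center_weeks(wob, threshold_date, straddle_rule)
    keep = np.ones(len(sub), dtype=bool)
    if straddle_rule == "drop":
        smon = straddle_week_monday(threshold_date)
        if smon is not None:
            keep = wob != smon
    sub = sub.loc[keep].reset_index(drop=True)
    x = np.asarray(x)[keep]

    _, start, end = _window(sub, outcome, threshold_date)
    v = _datecol(sub, "vaccination_date")
    vaccinated = (~np.isnat(v)) & (v <= end)

    y = ascertain_outcomes(sub, outcome, threshold_date)
    dob = _datecol(sub, "date_of_birth")

    def _labels_for(dobs):
        labs = np.full(len(dobs), "never_eligible", dtype=object)
        bounds = [("1934-09-01", "catchup_year_1"), ("1936-09-01", "catchup_year_2"),
                  ("1937-09-01", "catchup_year_3"), ("1938-09-01", "catchup_year_4"),
                  ("9999-01-01", "post_2017_rule")]
        prev = np.datetime64("1933-09-01")
        for upper, lab in bounds:
            m = (dobs > prev) & (dobs <= np.datetime64(upper))
            labs[m] = lab
            prev = np.datetime64(upper)
        return labs

    labels = _labels_for(dob)
    if outcome.index_date_policy == "own_eligibility_date":
        # staggered follow-up: never-eligibles mirror the cohort label of the
        # person born equally far on the other side, so cohort fixed effects
        # absorb window differences symmetrically
        thr = as_datetime64(threshold_date)
        never = labels == "never_eligible"
        if never.any():
            mirrored = thr + (thr - dob[never])
            labels[never] = np.char.add("mirror_", _labels_for(mirrored).astype(str)).astype(object)

    out = pd.DataFrame({
        "person_id": sub["person_id"].to_numpy(),
        "centered_wob": x,
        "eligible": (x >= 0).astype("int8"),
        "vaccinated": vaccinated.astype("int8"),
        "outcome": y,
        "gender": sub["gender"].to_numpy(),
        "male": (sub["gender"].to_numpy() == "male").astype("int8"),
        "rollout_cohort": labels,
    })
    for c in covariates:
        if c not in sub.columns:
            raise SchemaError(f"requested covariate {c!r} not in person table")
        out[c] = sub[c].to_numpy()
    return out
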