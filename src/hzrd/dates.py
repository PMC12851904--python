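"""Calendar helpers: week-of-birth flooring and running-variable centering.

Dates of birth in the emulated data are only observed at week resolution,
with weeks starting on a Monday. All helpers work on numpy ``datetime64[D]``
arrays (scalars are accepted and returned as scalars).
"""

from __future__ import annotations

import datetime as _dt

import numpy as np

from hzrd.exceptions import DomainError

# numpy's datetime64 epoch (1970-01-01) was a Thursday; Monday == weekday 0.
_EPOCH_WEEKDAY = 3

STRADDLE_RULES = ("majority", "eligible", "ineligible", "drop")


def as_datetime64(d) -> np.datetime64 | np.ndarray:
    """Coerce ``date``/``str``/array-like to ``datetime64[D]``."""
    if isinstance(d, (np.datetime64, _dt.date, str)):
        return np.datetime64(d, "D")
    return np.asarray(d, dtype="datetime64[D]")


def weekday(d) -> np.ndarray:
    """Day of week with Monday == 0."""
    days = as_datetime64(d).astype("int64")
    return (days + _EPOCH_WEEKDAY) % 7


def monday_on_or_before(d):
    """The Monday starting the week that contains ``d``."""
    d64 = as_datetime64(d)
    return d64 - weekday(d64).astype("timedelta64[D]")


def is_monday(d) -> np.ndarray:
    return weekday(d) == 0


def week_anchor(threshold_date, straddle_rule: str = "majority") -> np.datetime64:
    """Monday of the first week counted as eligible (centered week 0).

    When the threshold date is not itself a Monday, the week containing it
    straddles the cutoff and must be assigned to one side:

    - ``"majority"``: the side holding at least 4 of the week's 7 days
      (for a Saturday threshold such as 1933-09-02 this is the ineligible
      side, since only the Saturday and Sunday fall on or after the cutoff);
    - ``"eligible"`` / ``"ineligible"``: force the straddling week to that side;
    - ``"drop"``: the straddling week is excluded from analysis; the anchor
      is the first fully eligible week.
    """
    if straddle_rule not in STRADDLE_RULES:
        raise DomainError(f"unknown straddle_rule {straddle_rule!r}; expected one of {STRADDLE_RULES}")
    thr = as_datetime64(threshold_date)
    wk_monday = monday_on_or_before(thr)
    if wk_monday == thr:  # threshold on a Monday: no straddling week
        return thr
    if straddle_rule == "eligible":
        return wk_monday
    if straddle_rule in ("ineligible", "drop"):
        return wk_monday + np.timedelta64(7, "D")
    # majority-of-days: days of the week on/after the threshold
    days_on_eligible_side = int((wk_monday + np.timedelta64(7, "D") - thr) / np.timedelta64(1, "D"))
    if days_on_eligible_side >= 4:
        return wk_monday
    return wk_monday + np.timedelta64(7, "D")


def center_weeks(week_of_birth, threshold_date, straddle_rule: str = "majority"):
    """Signed whole weeks of a (Monday) birth week from the eligibility anchor.

    Week 0 is the first week on the eligible side; negative values lie on the
    ineligible side, one unit per week.
    """
    wob = as_datetime64(week_of_birth)
    if not np.all(is_monday(wob)):
        raise DomainError("week_of_birth values must be Mondays (weeks start on a Monday)")
    anchor = week_anchor(threshold_date, straddle_rule)
    delta = (wob - anchor) / np.timedelta64(7, "D")
    out = delta.astype("int64") if np.ndim(delta) else int(delta)
    return out


def straddle_week_monday(threshold_date) -> np.datetime64 | None:
    """Monday of the week containing the threshold, or None if the threshold is a Monday."""
    thr = as_datetime64(threshold_date)
    mon = monday_on_or_before(thr)
    return None if mon == thr else mon


def add_years(d, years: int):
    """Shift a date by whole calendar years (Feb 29 maps to Feb 28)."""
    d64 = as_datetime64(d)

    def _shift_one(x: np.datetime64) -> np.datetime64:
        py = x.astype(_dt.date)
        try:
            return np.datetime64(py.replace(year=py.year + years), "D")
        except ValueError:  # Feb 29 in a non-leap target year
            return np.datetime64(py.replace(year=py.year + years, day=28), "D")

    if np.ndim(d64) == 0:
        return _shift_one(d64)
    return np.array([_shift_one(x) for x in d64.ravel()], dtype="datetime64[D]").reshape(d64.shape)
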