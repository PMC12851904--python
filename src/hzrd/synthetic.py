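"""Person-level synthetic cohort generator with potential-outcome bookkeeping.

The generator emulates the statistical structure of a linked electronic-health-
record extract around a date-of-birth vaccination threshold: uniform weekly
dates of birth, a sharp (at week resolution) jump in vaccine uptake at the
threshold, outcome risks that are smooth in age on the log-odds scale, a
treatment effect that enters only through simulated receipt, baseline
comorbidity flags, pre-period event histories for placebo tests, and
utilization counts.

For every configured outcome the table carries the two potential outcomes
``y0_<name>`` / ``y1_<name>`` (coupled through a shared uniform draw, so
``y1 <= y0`` pointwise for protective effects) alongside the realized event
dates; the realized indicator always equals the potential outcome selected by
simulated receipt. This makes every downstream estimator testable against
known ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from hzrd.config import CHARLSON_CONDITIONS, SyntheticConfig
from hzrd.dates import as_datetime64, center_weeks, monday_on_or_before
from hzrd.exceptions import SchemaError

PROGRAM_START = np.datetime64("2013-09-01", "D")
FOLLOWUP_END = np.datetime64("2022-08-31", "D")
PREPERIOD_START = np.datetime64("2004-09-01", "D")

#: default cause-of-death code sets used by the generator
DEMENTIA_DEATH_CODE = "F03"
NONDEMENTIA_DEATH_CODE = "I25"
OTHER_CONTRIBUTING_CODE = "J18"
#: probability that a non-dementia underlying-cause death still carries a
#: dementia contributing-cause code (exercises the neither-underlying-nor-
#: contributing outcome definition)
P_DEMENTIA_CONTRIBUTING = 0.15

DATE_COLUMNS_BASE = ("date_of_birth", "week_of_birth", "vaccination_date",
                     "mci_date", "dementia_date", "death_date")
STRING_COLUMNS = ("person_id", "gender", "dementia_type", "underlying_cause", "contributing_causes")


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _logit(p):
    return np.log(p / (1.0 - p))


def _uniform_dates(rng, n, start, end_inclusive, mask=None):
    """Uniform dates in [start, end]; NaT where mask is False."""
    span = int((end_inclusive - start) / np.timedelta64(1, "D")) + 1
    offsets = rng.integers(0, span, size=n)
    dates = start + offsets.astype("timedelta64[D]")
    out = dates.astype("datetime64[D]")
    if mask is not None:
        out = np.where(mask, out, np.datetime64("NaT"))
    return out


def _eligibility_year_start(dob: np.ndarray) -> np.ndarray:
    """Start of each person's first program eligibility year (catch-up schedule)."""
    d = dob.astype("datetime64[D]")
    conds = [
        d <= np.datetime64("1933-09-01"),
        d <= np.datetime64("1934-09-01"),
        d <= np.datetime64("1936-09-01"),
        d <= np.datetime64("1937-09-01"),
        d <= np.datetime64("1938-09-01"),
    ]
    choices = [
        np.datetime64("2013-09-01"),  # never eligible; placeholder (uptake 0 by default)
        np.datetime64("2013-09-01"),
        np.datetime64("2014-09-01"),
        np.datetime64("2015-09-01"),
        np.datetime64("2016-09-01"),
    ]
    # born after 1938-09-01: eligible on 78th birthday under the 2017 rule,
    # approximated by the program year containing that birthday
    fallback = np.datetime64("2017-04-01")
    return np.select(conds, choices, default=fallback).astype("datetime64[D]")


def generate_cohort(config: SyntheticConfig | None = None) -> pd.DataFrame:
    """Simulate a person table with the configured discontinuity structure.

    Deterministic given ``config.rng_seed``. Dates of birth are uniform over
    ``[dob_start, dob_end]``; receipt is Bernoulli with probability
    ``uptake_left_limit`` on the ineligible side of the (week-resolved)
    threshold and the cohort-specific right limit plus ``uptake_dob_slope *
    weeks`` on the eligible side; each outcome is a Bernoulli draw from a
    smooth-in-age log-odds risk, with the configured effect applied to
    vaccinated persons only (scaled per gender).
    """
    config = (config or SyntheticConfig()).validate()
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_persons

    dob = _uniform_dates(rng, n, as_datetime64(config.dob_start), as_datetime64(config.dob_end))
    wob = monday_on_or_before(dob)
    x = center_weeks(wob, config.threshold_date, config.straddle_rule)
    eligible = x >= 0  # week-level assignment; the generator's notion of eligibility

    # gender
    u_g = rng.uniform(size=n)
    gender = np.where(u_g < config.female_share, "female", "male").astype(object)
    if config.include_unspecified_gender and n >= 1:
        gender[rng.integers(0, n)] = "unspecified"

    wimd = rng.integers(1, 6, size=n)

    # baseline cognitive status
    u_b = rng.uniform(size=n)
    baseline_dementia = u_b < config.p_baseline_dementia
    baseline_ci = u_b < config.p_baseline_dementia + config.p_other_cognitive_impairment

    # Charlson flags (dementia flag mirrors the baseline dementia diagnosis)
    flags = {}
    for cond in CHARLSON_CONDITIONS:
        if cond == "dementia":
            flags[cond] = baseline_dementia.copy()
        else:
            prev = config.comorbidity_prevalences.get(cond, 0.0)
            flags[cond] = rng.uniform(size=n) < prev

    # vaccine receipt
    right = np.where(baseline_dementia, config.uptake_right_limit_dementia, config.uptake_right_limit)
    p_receipt = np.where(
        eligible,
        np.clip(right + config.uptake_dob_slope * x, 0.0, 1.0),
        config.uptake_left_limit,
    )
    vaccinated = rng.uniform(size=n) < p_receipt

    elig_year_start = _eligibility_year_start(dob)
    vacc_offset = rng.integers(0, 365, size=n).astype("timedelta64[D]")
    vaccination_date = np.where(vaccinated, elig_year_start + vacc_offset, np.datetime64("NaT"))

    # mortality log-odds offset from comorbidities (gives the severity score signal)
    mort_offset = np.zeros(n)
    for cond, w in config.mortality_logodds.items():
        if cond in flags:
            mort_offset += w * flags[cond]
    mort_offset -= mort_offset.mean()  # center so baseline risks stay interpretable

    jump = np.where(baseline_dementia,
                    config.uptake_right_limit_dementia - config.uptake_left_limit,
                    config.uptake_right_limit - config.uptake_left_limit)
    gm = config.gender_effect_multipliers()
    gender_mult = np.where(gender == "female", gm["female"], gm["male"])

    data = {
        "person_id": np.array([f"S{config.rng_seed}-{i:07d}" for i in range(n)], dtype=object),
        "date_of_birth": dob,
        "week_of_birth": wob,
        "gender": gender,
        "wimd_quintile": wimd.astype("int64"),
    }
    for cond in CHARLSON_CONDITIONS:
        data[f"charlson_{cond}"] = flags[cond].astype("int8")
    data["baseline_cognitive_impairment"] = baseline_ci.astype("int8")
    data["baseline_dementia"] = baseline_dementia.astype("int8")
    data["vaccination_date"] = vaccination_date

    # ---- outcomes with potential-outcome coupling --------------------------------
    realized = {}
    type_labels = None
    type_mult = np.ones(n)
    if "dementia" in config.baseline_outcome_risk:
        names = list(config.dementia_type_weights)
        w = np.array([config.dementia_type_weights[t] for t in names], dtype=float)
        type_labels = np.array(names, dtype=object)[rng.choice(len(names), size=n, p=w / w.sum())]
        if config.dementia_type_effect_multipliers:
            mult = np.ones(len(names))
            for i, t in enumerate(names):
                mult[i] = config.dementia_type_effect_multipliers.get(t, 1.0)
            lut = dict(zip(names, mult))
            type_mult = np.array([lut[t] for t in type_labels])

    birth_month = pd.DatetimeIndex(dob).month.to_numpy()
    post_season = (birth_month >= 9) | (birth_month <= 2)

    for name, base_risk in config.baseline_outcome_risk.items():
        trend = config.outcome_age_trend.get(name, 0.0)
        quad = config.quadratic_age_trend.get(name, 0.0)
        logit0 = _logit(base_risk) + trend * x + quad * x**2
        if name.startswith("death"):
            logit0 = logit0 + mort_offset
        p0 = _sigmoid(logit0)
        season_shift = config.birth_season_risk_shift.get(name, 0.0)
        if season_shift:
            p0 = np.clip(p0 + season_shift * post_season, 0.0, 1.0)
        effect = np.where(jump != 0, config.true_itt.get(name, 0.0) / np.where(jump == 0, 1.0, jump), 0.0)
        effect = effect * gender_mult
        if name == "dementia":
            effect = effect * type_mult
        p1 = np.clip(p0 + effect, 0.0, 1.0)
        u = rng.uniform(size=n)
        y0 = (u < p0).astype("int8")
        y1 = (u < p1).astype("int8")
        y = np.where(vaccinated, y1, y0).astype("int8")
        realized[name] = y
        data[f"y0_{name}"] = y0
        data[f"y1_{name}"] = y1

    # ---- event-date materialization ----------------------------------------------
    y_mci = realized.get("mci", np.zeros(n, dtype="int8"))
    y_dem = realized.get("dementia", np.zeros(n, dtype="int8"))
    y_dd = realized.get("death_due_to_dementia", np.zeros(n, dtype="int8"))
    y_nd = realized.get("death_nondementia", np.zeros(n, dtype="int8"))

    mci_date = _uniform_dates(rng, n, PROGRAM_START, FOLLOWUP_END, mask=y_mci.astype(bool))

    dem_uniform = _uniform_dates(rng, n, PROGRAM_START, FOLLOWUP_END, mask=y_dem.astype(bool))
    # dementia typically follows MCI when both occur
    lag = np.rint(rng.exponential(730.0, size=n)).astype("timedelta64[D]")
    dem_after_mci = np.minimum(mci_date + lag, FOLLOWUP_END)
    both = y_dem.astype(bool) & y_mci.astype(bool)
    dementia_date = np.where(both, dem_after_mci, dem_uniform)

    died = y_dd.astype(bool) | y_nd.astype(bool)
    death_date = _uniform_dates(rng, n, PROGRAM_START, FOLLOWUP_END, mask=died)
    underlying = np.where(y_dd.astype(bool), DEMENTIA_DEATH_CODE,
                          np.where(y_nd.astype(bool), NONDEMENTIA_DEATH_CODE, "")).astype(object)
    contrib_dem = (~y_dd.astype(bool)) & y_nd.astype(bool) & (rng.uniform(size=n) < P_DEMENTIA_CONTRIBUTING)
    contributing = np.where(died,
                            np.where(contrib_dem, f"{OTHER_CONTRIBUTING_CODE};{DEMENTIA_DEATH_CODE}",
                                     OTHER_CONTRIBUTING_CODE),
                            "").astype(object)

    # event ordering consistency: nothing after death
    has_death = ~np.isnat(death_date)
    mci_date = np.where(has_death & ~np.isnat(mci_date), np.minimum(mci_date, death_date), mci_date)
    dementia_date = np.where(has_death & ~np.isnat(dementia_date),
                             np.minimum(dementia_date, death_date), dementia_date)

    data["mci_date"] = mci_date
    data["dementia_date"] = dementia_date
    data["dementia_type"] = np.where(y_dem.astype(bool), type_labels, "") if type_labels is not None \
        else np.full(n, "", dtype=object)
    data["death_date"] = death_date
    data["underlying_cause"] = underlying
    data["contributing_causes"] = contributing

    # generic event dates for outcomes outside the canonical set (negative controls etc.)
    canonical = {"mci", "dementia", "death_due_to_dementia", "death_nondementia"}
    for name, y in realized.items():
        if name not in canonical:
            data[f"event_{name}_date"] = _uniform_dates(rng, n, PROGRAM_START, FOLLOWUP_END,
                                                        mask=y.astype(bool))

    # pre-period events, independent of eligibility side
    preperiod_end = PROGRAM_START - np.timedelta64(1, "D")
    for name, risk in config.preperiod_risk.items():
        mask = rng.uniform(size=n) < risk
        data[f"preperiod_{name}_date"] = _uniform_dates(rng, n, PREPERIOD_START, preperiod_end, mask=mask)

    # utilization: mixture of frequent and infrequent primary-care attenders
    frequent = rng.uniform(size=n) < 0.48
    lam = np.where(frequent, 8.0, 0.9)
    for j in range(1, 6):
        data[f"pc_visits_prior_y{j}"] = rng.poisson(lam).astype("int64")
    data["pc_visits_followup"] = rng.poisson(np.where(frequent, 55.0, 12.0)).astype("int64")

    admissions = np.where(baseline_dementia, rng.poisson(1.2, size=n), 0)
    data["n_dementia_admissions"] = admissions.astype("int64")
    data["inpatient_days_dementia"] = rng.poisson(6.0 * admissions).astype("int64")
    data["n_dementia_recordings"] = (admissions + rng.poisson(
        np.where(baseline_dementia, 3.0, 0.05))).astype("int64")

    df = pd.DataFrame(data)
    for col in df.columns:
        if col.endswith("_date") or col in ("date_of_birth", "week_of_birth"):
            df[col] = pd.to_datetime(df[col])
    return df


# ---- CSV round-trip ------------------------------------------------------------------

MANDATORY_COLUMNS = (
    "person_id", "date_of_birth", "week_of_birth", "gender",
    "baseline_cognitive_impairment", "baseline_dementia", "vaccination_date",
)


def _date_columns(df: pd.DataFrame):
    return [c for c in df.columns if c.endswith("_date") or c in ("date_of_birth", "week_of_birth")]


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a person table to CSV (ISO-8601 dates, absent dates as empty fields)."""
    missing = [c for c in MANDATORY_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"person table is missing mandatory columns: {missing}")
    out = table.copy()
    for col in _date_columns(out):
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d").fillna("")
    out.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a person table written by :func:`write_cohort` (lossless round-trip)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file is missing mandatory columns: {missing}")
    for col in df.columns:
        if col.endswith("_date") or col in ("date_of_birth", "week_of_birth"):
            vals = df[col].replace("", pd.NaT)
            parsed = pd.to_datetime(vals, format="%Y-%m-%d", errors="coerce")
            bad = parsed.isna() & (df[col] != "")
            if bad.any():
                raise SchemaError(
                    f"unparseable dates in column {col!r}: rows {list(df.index[bad][:5])}"
                )
            df[col] = parsed
        elif col in STRING_COLUMNS:
            df[col] = df[col].astype(object)
        else:
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as err:
                raise SchemaError(f"non-numeric values in numeric column {col!r}") from err
            if col.startswith(("charlson_", "y0_", "y1_")) or col in (
                    "baseline_cognitive_impairment", "baseline_dementia"):
                df[col] = df[col].astype("int8")
    return df
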