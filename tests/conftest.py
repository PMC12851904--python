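"""Shared fixtures: small person tables and trimmed generator settings."""

import datetime as dt

import pandas as pd
import pytest

from hzrd.config import SyntheticConfig
from hzrd.synthetic import generate_cohort

#: single-outcome generator settings used by simulation-heavy tests; the
#: study conditions (uptake jump, true effect, sample size policy) match the
#: full defaults, only unanalyzed outcomes are omitted for speed
MCI_ONLY = dict(
    baseline_outcome_risk={"mci": 0.073},
    outcome_age_trend={"mci": -0.0013},
    true_itt={"mci": -0.015},
    preperiod_risk={"mci": 0.030},
)

DEMENTIA_COHORT = dict(
    p_baseline_dementia=1.0,
    p_other_cognitive_impairment=0.0,
    baseline_outcome_risk={"death_due_to_dementia": 0.42},
    outcome_age_trend={"death_due_to_dementia": -0.002},
    true_itt={"death_due_to_dementia": -0.085},
    preperiod_risk={},
)


@pytest.fixture(scope="session")
def persons_small():
    """30k-person default cohort reused by read-only tests."""
    return generate_cohort(SyntheticConfig(n_persons=30_000, rng_seed=101))


@pytest.fixture
def tiny_persons():
    """Ten handcrafted person records with known baseline flags and events."""
    rows = []
    for i, (ci, dem, death, cause) in enumerate([
        (0, 0, None, None), (0, 0, None, None), (1, 0, None, None),
        (1, 1, "2019-05-01", "F03"), (0, 0, None, None), (1, 1, None, None),
        (0, 0, "2016-03-03", "I25"), (1, 0, None, None), (0, 0, None, None),
        (1, 1, "2020-12-31", "F01"),
    ]):
        dob = dt.date(1933, 1, 2) + dt.timedelta(weeks=4 * i)
        rows.append({
            "person_id": f"T{i}",
            "date_of_birth": pd.Timestamp(dob),
            "week_of_birth": pd.Timestamp(dob - dt.timedelta(days=dob.weekday())),
            "gender": "female" if i % 2 == 0 else "male",
            "baseline_cognitive_impairment": ci,
            "baseline_dementia": dem,
            "vaccination_date": pd.Timestamp("2014-01-15") if i in (1, 4) else pd.NaT,
            "mci_date": pd.Timestamp("2015-06-01") if i in (0, 1) else pd.NaT,
            "dementia_date": pd.Timestamp("2015-07-20") if i == 1 else pd.NaT,
            "death_date": pd.Timestamp(death) if death else pd.NaT,
            "underlying_cause": cause or "",
            "contributing_causes": "J18;F03" if i == 6 else ("J18" if death else ""),
        })
    return pd.DataFrame(rows)
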