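"""Falsification and robustness machinery.

- Placebo date-of-birth thresholds (September 2 of 1930-1932 and 1934-1936)
  with follow-up windows shifted congruently and truncated to six years, so
  every placebo comparison covers the same age range as the primary analysis.
- Pre-period outcome tests: the identical RD but with the follow-up window
  moved nine years before program start.
- Baseline balance and negative-control outcomes, reported without
  multiplicity adjustment but alongside the count expected by chance.
- The bandwidth / grace-period / polynomial-order / adjustment robustness grid.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hzrd.cohort import OutcomeSpec, build_analysis_cohort
from hzrd.exceptions import EstimationError
from hzrd.rd import RDConfig, RDResult, rd_fuzzy, rd_sharp

PLACEBO_YEARS = (1930, 1931, 1932, 1934, 1935, 1936)
PLACEBO_FOLLOW_UP_YEARS = 6

DEFAULT_BALANCE_COVARIATES = (
    "charlson_myocardial_infarction", "charlson_congestive_heart_failure",
    "charlson_peripheral_vascular_disease", "charlson_cerebrovascular_disease",
    "charlson_chronic_pulmonary_disease", "charlson_diabetes",
    "charlson_renal_disease", "charlson_any_malignancy",
    "charlson_rheumatologic_disease", "charlson_peptic_ulcer_disease",
)


@dataclass
class FalsificationReport:
    placebo_estimates: dict = field(default_factory=dict)
    preperiod_estimates: dict = field(default_factory=dict)
    balance_table: dict = field(default_factory=dict)
    negative_controls: dict = field(default_factory=dict)
    skipped: dict = field(default_factory=dict)
    alpha: float = 0.05

    @property
    def n_significant_at_05(self) -> int:
        n = 0
        for group in (self.placebo_estimates, self.preperiod_estimates,
                      self.balance_table, self.negative_controls):
            for res in group.values():
                if isinstance(res, RDResult) and res.p_robust < self.alpha:
                    n += 1
        return n

    @property
    def n_tests(self) -> int:
        return sum(len(g) for g in (self.placebo_estimates, self.preperiod_estimates,
                                    self.balance_table, self.negative_controls))

    @property
    def expected_significant_by_chance(self) -> float:
        return self.alpha * self.n_tests

    def to_dict(self) -> dict:
        def conv(group):
            return {str(k): (v.to_dict() if isinstance(v, RDResult) else v)
                    for k, v in group.items()}
        return {
            "placebo_estimates": conv(self.placebo_estimates),
            "preperiod_estimates": conv(self.preperiod_estimates),
            "balance_table": conv(self.balance_table),
            "negative_controls": conv(self.negative_controls),
            "skipped": dict(self.skipped),
            "n_significant_at_05": self.n_significant_at_05,
            "n_tests": self.n_tests,
            "expected_significant_by_chance": self.expected_significant_by_chance,
        }


def placebo_thresholds(persons: pd.DataFrame, outcome: str = "mci",
                       cohort: str = "no_cognitive_impairment",
                       years: tuple = PLACEBO_YEARS,
                       config: RDConfig | None = None,
                       follow_up_years: int = PLACEBO_FOLLOW_UP_YEARS,
                       straddle_rule: str = "majority") -> dict:
    """Sharp RD at each placebo September 2 threshold with congruent windows.

    The follow-up window is shifted by the same offset as the threshold
    (e.g. the 1930 threshold uses September 1, 2010 - August 31, 2016) so
    that every comparison covers identical ages; the six-year window keeps
    all shifted windows inside the observed data span. Placebo years with
    insufficient data are omitted with a warning.
    """
    import datetime as dt

    config = config or RDConfig()
    out = {}
    for year in years:
        thr = dt.date(year, 9, 2)
        spec = OutcomeSpec(name=outcome, follow_up_years=follow_up_years,
                           window_shift_years=year - 1933)
        try:
            ac = build_analysis_cohort(persons, cohort=cohort, outcome=spec,
                                       threshold_date=thr, straddle_rule=straddle_rule)
            out[year] = rd_sharp(ac, config=config)
        except EstimationError as err:
            warnings.warn(f"placebo threshold {year} omitted: {err}", UserWarning)
    return out


def preperiod_test(persons: pd.DataFrame, outcome: str = "mci",
                   cohort: str = "no_cognitive_impairment",
                   config: RDConfig | None = None,
                   follow_up_years: int = 9) -> RDResult:
    """The primary RD with the follow-up window moved nine years earlier.

    Under a valid design pre-period outcomes cannot respond to eligibility,
    so the expectation is no jump.
    """
    config = config or RDConfig()
    spec = OutcomeSpec(name=outcome, follow_up_years=follow_up_years,
                       window_shift_years=-9)
    ac = build_analysis_cohort(persons, cohort=cohort, outcome=spec)
    return rd_sharp(ac, config=config)


def balance_and_negative_controls(persons: pd.DataFrame,
                                  covariates: tuple = DEFAULT_BALANCE_COVARIATES,
                                  control_outcomes: tuple = (),
                                  cohort: str = "no_cognitive_impairment",
                                  config: RDConfig | None = None) -> FalsificationReport:
    """One sharp RD per baseline covariate and per negative-control outcome.

    Multiplicity is left unadjusted; the report carries the number of
    significant results alongside the count expected by chance. Constant
    covariates are skipped with a note.
    """
    config = config or RDConfig()
    report = FalsificationReport(alpha=config.alpha)
    for cov in covariates:
        if cov not in persons.columns:
            report.skipped[cov] = "column absent"
            continue
        if persons[cov].nunique() <= 1:
            report.skipped[cov] = "constant covariate"
            continue
        ac = build_analysis_cohort(persons, cohort=cohort, outcome=f"column:{cov}")
        try:
            report.balance_table[cov] = rd_sharp(ac, config=config)
        except EstimationError as err:
            report.skipped[cov] = str(err)
    for out_name in control_outcomes:
        try:
            ac = build_analysis_cohort(persons, cohort=cohort, outcome=out_name)
            report.negative_controls[out_name] = rd_sharp(ac, config=config)
        except (EstimationError, Exception) as err:  # noqa: BLE001 - cell isolation
            report.skipped[out_name] = str(err)
    return report


def falsification_suite(persons: pd.DataFrame, outcome: str = "mci",
                        cohort: str = "no_cognitive_impairment",
                        covariates: tuple = DEFAULT_BALANCE_COVARIATES,
                        control_outcomes: tuple = (),
                        config: RDConfig | None = None) -> FalsificationReport:
    """Placebo thresholds + pre-period test + balance + negative controls."""
    config = config or RDConfig()
    report = balance_and_negative_controls(persons, covariates, control_outcomes,
                                           cohort, config)
    report.placebo_estimates = placebo_thresholds(persons, outcome, cohort, config=config)
    try:
        report.preperiod_estimates[outcome] = preperiod_test(persons, outcome, cohort, config)
    except EstimationError as err:
        report.skipped[f"preperiod:{outcome}"] = str(err)
    return report


def check_congruent_ages(persons: pd.DataFrame, years=PLACEBO_YEARS,
                         follow_up_years: int = PLACEBO_FOLLOW_UP_YEARS) -> dict:
    """Age range at index across placebo thresholds (should be identical).

    Returns per-year (min, max) age in weeks at the shifted index date for
    persons within +/-100 weeks of each threshold.
    """
    import datetime as dt

    out = {}
    dob = persons["week_of_birth"].to_numpy().astype("datetime64[D]")
    for year in list(years) + [1933]:
        thr = np.datetime64(dt.date(year, 9, 2))
        index = np.datetime64(dt.date(2013 + (year - 1933), 9, 1))
        dist = (thr - dob) / np.timedelta64(7, "D")
        m = np.abs(dist) <= 100
        age_weeks = (index - dob[m]) / np.timedelta64(7, "D")
        out[year] = (float(age_weeks.min()), float(age_weeks.max()))
    return out


def robustness_grid(persons: pd.DataFrame, outcome: str = "mci",
                    cohort: str = "no_cognitive_impairment",
                    grid: dict | None = None,
                    config: RDConfig | None = None,
                    fuzzy: bool = True) -> pd.DataFrame:
    """Cartesian product of robustness variations, one full RD run per cell.

    Supported grid keys: ``bandwidth_multiplier`` (0.5..2.0 of the MSE-optimal
    bandwidth), ``grace_weeks``, ``polynomial_order`` (1 or 2), ``staggered``
    (follow-up from each person's own eligibility date with rollout-cohort
    fixed effects), ``utilization_adjust`` (primary-care visit covariate),
    ``frequent_attenders`` (row filter requiring a visit in each of the five
    pre-program years). A failing cell is marked failed, not fatal.
    """
    base_config = config or RDConfig()
    grid = grid or {"bandwidth_multiplier": [0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0]}
    keys = list(grid)
    rows = []
    for values in itertools.product(*(grid[k] for k in keys)):
        cell = dict(zip(keys, values))
        row = dict(cell)
        try:
            spec = OutcomeSpec(
                name=outcome,
                grace_period_weeks=int(cell.get("grace_weeks", 0)),
                index_date_policy="own_eligibility_date" if cell.get("staggered") else "program_start",
            )
            cfg = base_config.replace(
                polynomial_order=int(cell.get("polynomial_order",
                                              base_config.polynomial_order)),
                bias_order=None,
            )
            mult = cell.get("bandwidth_multiplier", 1.0)
            if mult != 1.0:
                cfg = cfg.replace(bandwidth_policy=f"multiplier:{mult}")
            covs = list(cfg.covariates)
            fes = list(cfg.fixed_effects)
            if cell.get("utilization_adjust"):
                covs.append("pc_visits_followup")
            if cell.get("staggered"):
                fes.append("rollout_cohort")
            cfg = cfg.replace(covariates=tuple(covs), fixed_effects=tuple(fes))
            ac = build_analysis_cohort(
                persons, cohort=cohort, outcome=spec,
                covariates=tuple(c for c in covs if c != "centered_wob"),
                frequent_attenders_only=bool(cell.get("frequent_attenders", False)))
            res = rd_fuzzy(ac, config=cfg) if fuzzy else rd_sharp(ac, config=cfg)
            row.update(estimate=res.estimate, se_robust=res.se_robust,
                       ci_lo=res.ci_robust[0], ci_hi=res.ci_robust[1],
                       p_robust=res.p_robust, bandwidth_h=res.bandwidth_h,
                       n_eff=res.n_eff_left + res.n_eff_right, status="ok")
        except Exception as err:  # noqa: BLE001 - grid cells are isolated
            row.update(status="failed", error=str(err))
            warnings.warn(f"robustness cell {cell} failed: {err}", UserWarning)
        rows.append(row)
    return pd.DataFrame(rows)
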