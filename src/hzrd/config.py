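"""Configuration for the synthetic linked-EHR cohort generator.

The defaults encode the study conditions of the Welsh rollout design that this
package emulates: weekly dates of birth spanning September 1925 - September
1942, a vaccination-uptake discontinuity at the September 2, 1933 threshold
(left limit 0, right limit 0.459 among the cognitively unimpaired and 0.287
among those living with dementia at baseline), smooth age trends in outcome
risk, 9-year cumulative binary outcomes, gender-specific treatment effects
and baseline Charlson-type comorbidity flags.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field

import yaml

from hzrd.exceptions import ConfigError

#: Charlson comorbidity catalogue used as baseline flags. AIDS is excluded
#: throughout (it is suppressed in the emulated source database).
CHARLSON_CONDITIONS = (
    "myocardial_infarction",
    "congestive_heart_failure",
    "peripheral_vascular_disease",
    "cerebrovascular_disease",
    "dementia",
    "chronic_pulmonary_disease",
    "rheumatologic_disease",
    "peptic_ulcer_disease",
    "mild_liver_disease",
    "diabetes",
    "diabetes_with_complications",
    "hemiplegia",
    "renal_disease",
    "any_malignancy",
    "moderate_severe_liver_disease",
    "metastatic_solid_tumor",
)

DEFAULT_COMORBIDITY_PREVALENCES = {
    "myocardial_infarction": 0.10,
    "congestive_heart_failure": 0.12,
    "peripheral_vascular_disease": 0.08,
    "cerebrovascular_disease": 0.10,
    # "dementia" is tied to the baseline_dementia flag, not an independent draw
    "chronic_pulmonary_disease": 0.14,
    "rheumatologic_disease": 0.04,
    "peptic_ulcer_disease": 0.03,
    "mild_liver_disease": 0.02,
    "diabetes": 0.15,
    "diabetes_with_complications": 0.05,
    "hemiplegia": 0.02,
    "renal_disease": 0.12,
    "any_malignancy": 0.12,
    "moderate_severe_liver_disease": 0.01,
    "metastatic_solid_tumor": 0.02,
}

#: Additive log-odds contributions of comorbidities to the mortality outcomes,
#: loosely following Charlson-type hazard weights, so the severity score fitted
#: downstream has real signal to recover.
DEFAULT_MORTALITY_LOGODDS = {
    "myocardial_infarction": 0.35,
    "congestive_heart_failure": 0.60,
    "peripheral_vascular_disease": 0.25,
    "cerebrovascular_disease": 0.35,
    "chronic_pulmonary_disease": 0.30,
    "diabetes": 0.20,
    "diabetes_with_complications": 0.40,
    "hemiplegia": 0.45,
    "renal_disease": 0.50,
    "any_malignancy": 0.50,
    "moderate_severe_liver_disease": 1.00,
    "metastatic_solid_tumor": 1.30,
}

DEFAULT_BASELINE_RISK = {
    "mci": 0.073,
    "dementia": 0.12,
    "death_due_to_dementia": 0.42,
    "death_nondementia": 0.25,
}

DEFAULT_AGE_TREND = {
    # per-week log-odds slope in the running variable (positive weeks = younger,
    # hence lower risk); smooth across the threshold by construction
    "mci": -0.0013,
    "dementia": -0.0013,
    "death_due_to_dementia": -0.002,
    "death_nondementia": -0.002,
}

DEFAULT_TRUE_ITT = {
    "mci": -0.015,
    "dementia": -0.020,
    "death_due_to_dementia": -0.085,
    "death_nondementia": 0.0,
}

DEFAULT_PREPERIOD_RISK = {
    "mci": 0.030,
    "dementia": 0.020,
    "death_due_to_dementia": 0.050,
    "death_nondementia": 0.050,
}

DEFAULT_DEMENTIA_TYPE_WEIGHTS = {
    "alzheimer": 0.50,
    "vascular": 0.20,
    "mixed": 0.20,
    "other": 0.10,
}


@dataclass
class SyntheticConfig:
    """Data-generating parameters for :func:`hzrd.synthetic.generate_cohort`.

    The treatment effect is injected only through simulated vaccine receipt,
    so the true complier average causal effect equals
    ``true_itt[outcome] / (uptake_right - uptake_left)`` by construction.
    """

    n_persons: int = 60_000
    dob_start: dt.date = dt.date(1925, 9, 1)
    dob_end: dt.date = dt.date(1942, 9, 1)
    threshold_date: dt.date = dt.date(1933, 9, 2)
    uptake_right_limit: float = 0.459
    uptake_right_limit_dementia: float = 0.287
    uptake_left_limit: float = 0.0
    uptake_dob_slope: float = 0.0  # per-week change in uptake among eligibles
    baseline_outcome_risk: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE_RISK))
    outcome_age_trend: dict = field(default_factory=lambda: dict(DEFAULT_AGE_TREND))
    quadratic_age_trend: dict = field(default_factory=dict)  # optional per-week^2 log-odds curvature
    true_itt: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_ITT))
    effect_gender_ratio: float = 8.4  # female-to-male multiplier on the receipt effect
    female_share: float = 0.546
    p_baseline_dementia: float = 0.047
    p_other_cognitive_impairment: float = 0.026
    comorbidity_prevalences: dict = field(default_factory=lambda: dict(DEFAULT_COMORBIDITY_PREVALENCES))
    mortality_logodds: dict = field(default_factory=lambda: dict(DEFAULT_MORTALITY_LOGODDS))
    preperiod_risk: dict = field(default_factory=lambda: dict(DEFAULT_PREPERIOD_RISK))
    dementia_type_weights: dict = field(default_factory=lambda: dict(DEFAULT_DEMENTIA_TYPE_WEIGHTS))
    dementia_type_effect_multipliers: dict = field(default_factory=dict)
    #: additive risk shift for persons born in the post-September season
    #: (months September-February), per outcome; exercises the DID pretest
    birth_season_risk_shift: dict = field(default_factory=dict)
    include_unspecified_gender: bool = False
    straddle_rule: str = "majority"
    rng_seed: int = 0

    def validate(self) -> "SyntheticConfig":
        if not (isinstance(self.n_persons, int) and self.n_persons > 0):
            raise ConfigError(f"n_persons must be a positive integer, got {self.n_persons!r}")
        for name in ("uptake_right_limit", "uptake_right_limit_dementia", "uptake_left_limit",
                     "female_share", "p_baseline_dementia", "p_other_cognitive_impairment"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and 0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be a probability in [0, 1], got {v!r}")
        if not (self.dob_start < self.threshold_date < self.dob_end):
            raise ConfigError(
                f"dob_start < threshold_date < dob_end required, got "
                f"{self.dob_start} / {self.threshold_date} / {self.dob_end}"
            )
        for mapping_name in ("baseline_outcome_risk", "preperiod_risk"):
            for k, v in getattr(self, mapping_name).items():
                if not (0.0 <= float(v) <= 1.0):
                    raise ConfigError(f"{mapping_name}[{k!r}] must be in [0, 1], got {v!r}")
        for k, v in self.comorbidity_prevalences.items():
            if k not in CHARLSON_CONDITIONS:
                raise ConfigError(f"comorbidity_prevalences has unknown condition {k!r}")
            if not (0.0 <= float(v) <= 1.0):
                raise ConfigError(f"comorbidity_prevalences[{k!r}] must be in [0, 1], got {v!r}")
        import math

        for name in ("uptake_dob_slope", "effect_gender_ratio"):
            v = getattr(self, name)
            if not math.isfinite(float(v)):
                raise ConfigError(f"{name} must be finite, got {v!r}")
        for k, v in self.true_itt.items():
            if not math.isfinite(float(v)) or abs(float(v)) > 1:
                raise ConfigError(f"true_itt[{k!r}] must be a finite risk difference in [-1, 1], got {v!r}")
        total_w = sum(self.dementia_type_weights.values())
        if total_w <= 0:
            raise ConfigError("dementia_type_weights must have positive total weight")
        return self

    # ---- ground-truth bookkeeping -------------------------------------------------

    def uptake_jump(self, baseline_dementia: bool = False) -> float:
        right = self.uptake_right_limit_dementia if baseline_dementia else self.uptake_right_limit
        return right - self.uptake_left_limit

    def gender_effect_multipliers(self) -> dict:
        """Per-gender multipliers normalized so the share-weighted mean is 1."""
        g, fs = self.effect_gender_ratio, self.female_share
        male = 1.0 / (fs * g + (1.0 - fs))
        return {"female": g * male, "male": male, "unspecified": male}

    def true_cace(self, outcome: str, gender: str | None = None, baseline_dementia: bool = False) -> float:
        """Configured receipt effect implied by the Wald identity of the DGP."""
        jump = self.uptake_jump(baseline_dementia)
        if jump == 0:
            raise ConfigError("uptake jump is zero; CACE undefined")
        base = self.true_itt.get(outcome, 0.0) / jump
        if gender is None:
            return base
        return base * self.gender_effect_multipliers()[gender]

    # ---- (de)serialization --------------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SyntheticConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown SyntheticConfig fields: {sorted(unknown)}")
        kwargs = dict(raw)
        for key in ("dob_start", "dob_end", "threshold_date"):
            if key in kwargs and isinstance(kwargs[key], str):
                kwargs[key] = dt.date.fromisoformat(kwargs[key])
        return cls(**kwargs).validate()

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        for key in ("dob_start", "dob_end", "threshold_date"):
            out[key] = out[key].isoformat()
        return out
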