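"""Gender-interaction IV, severity scores, relative effects, dementia types."""

import warnings

import numpy as np
import pandas as pd
import pytest

from hzrd.config import SyntheticConfig
from hzrd.cohort import build_analysis_cohort, build_cohort
from hzrd.exceptions import DegenerateSplitWarning, EstimationError
from hzrd.heterogeneity import (
    SeverityModel,
    dementia_type_relative_effects,
    fit_severity_model,
    rd_gender_interaction,
    relative_effect,
    score_and_split,
    severity_measures,
)
from hzrd.rd import RDConfig, rd_fuzzy, rd_sharp
from hzrd.synthetic import generate_cohort


def interaction_fixture(seed=15, n=4000, effect_f=-0.10, effect_m=-0.02):
    """Deterministic-receipt cohort with gender-specific receipt effects."""
    rng = np.random.default_rng(seed)
    x = rng.integers(-40, 40, n).astype(float)
    male = (rng.uniform(size=n) < 0.5).astype(int)
    v = ((x >= 0) & (rng.uniform(size=n) < 0.5)).astype(float)
    y = (0.3 + 0.002 * x + np.where(male, effect_m, effect_f) * v
         + rng.normal(0, 0.02, n))
    return pd.DataFrame({"centered_wob": x, "eligible": (x >= 0).astype(int),
                         "vaccinated": v, "outcome": y,
                         "male": male,
                         "gender": np.where(male, "male", "female")})


class TestGenderInteraction:
    def test_recovers_gender_specific_effects(self):
        coh = interaction_fixture()
        res = rd_gender_interaction(coh, bandwidth=35.0)
        assert res.beta_female == pytest.approx(-0.10, abs=0.02)
        assert res.beta_male == pytest.approx(-0.02, abs=0.02)
        assert res.beta_interaction == pytest.approx(0.08, abs=0.03)

    def test_equals_separate_single_gender_fits(self):
        """The fully interacted model reproduces per-gender fuzzy fits exactly
        at the same bandwidth and weights (the design is block-saturated)."""
        coh = interaction_fixture(seed=16)
        h = 30.0
        res = rd_gender_interaction(coh, bandwidth=h)
        cfg = RDConfig(bandwidth_policy=f"fixed:{h}", bias_bandwidth_policy="same_as_h")
        fz_f = rd_fuzzy(coh.loc[coh.male == 0], config=cfg)
        fz_m = rd_fuzzy(coh.loc[coh.male == 1], config=cfg)
        assert res.beta_female == pytest.approx(fz_f.estimate, abs=1e-9)
        assert res.beta_male == pytest.approx(fz_m.estimate, abs=1e-9)

    def test_null_heterogeneity(self):
        coh = interaction_fixture(seed=17, effect_f=-0.06, effect_m=-0.06)
        res = rd_gender_interaction(coh, bandwidth=35.0)
        assert abs(res.beta_interaction) < 3 * res.se_interaction

    def test_single_gender_errors(self):
        coh = interaction_fixture()
        with pytest.raises(EstimationError, match="gender"):
            rd_gender_interaction(coh.loc[coh.male == 1], bandwidth=35.0)

    def test_generator_gender_ratio_recovered(self):
        """Strong female-concentrated effect yields a positive interaction."""
        cfg = SyntheticConfig(n_persons=120_000, rng_seed=18, effect_gender_ratio=25.0,
                              baseline_outcome_risk={"mci": 0.073},
                              true_itt={"mci": -0.015}, preperiod_risk={})
        ac = build_analysis_cohort(generate_cohort(cfg), "no_cognitive_impairment", "mci")
        res = rd_gender_interaction(ac)
        truth_gap = cfg.true_cace("mci", "male") - cfg.true_cace("mci", "female")
        assert res.beta_interaction == pytest.approx(truth_gap, abs=3 * res.se_interaction)


@pytest.fixture(scope="module")
def dementia_persons():
    cfg = SyntheticConfig(n_persons=40_000, rng_seed=19, p_baseline_dementia=0.5,
                          p_other_cognitive_impairment=0.0)
    return build_cohort(generate_cohort(cfg), "living_with_dementia")


class TestSeverityModel:
    def test_fixed_age_imputation(self, dementia_persons):
        """Two persons identical except age get identical scores."""
        model = fit_severity_model(dementia_persons, "death_all_cause")
        a = dementia_persons.iloc[[0]].copy()
        b = a.copy()
        b["date_of_birth"] = pd.Timestamp("1926-01-04")  # much older
        assert model.scores(a)[0] == pytest.approx(model.scores(b)[0], abs=1e-12)

    def test_trained_on_ineligible_only(self, dementia_persons):
        model = fit_severity_model(dementia_persons, "death_all_cause")
        assert model.training_side == "ineligible_only"
        assert not any("aids" in p.lower() for p in model.predictor_names)

    def test_coefficient_recovery(self):
        """Logistic fit recovers the generator's comorbidity log-odds weights
        on a single-cause mortality outcome (which is exactly logistic in the
        flags by construction)."""
        cfg = SyntheticConfig(n_persons=40_000, rng_seed=20, p_baseline_dementia=0.5,
                              p_other_cognitive_impairment=0.0,
                              baseline_outcome_risk={"death_due_to_dementia": 0.42},
                              outcome_age_trend={"death_due_to_dementia": -0.002},
                              true_itt={"death_due_to_dementia": -0.085},
                              preperiod_risk={})
        persons = build_cohort(generate_cohort(cfg), "living_with_dementia")
        model = fit_severity_model(persons, "death_due_to_dementia")
        for cond, truth in [("charlson_metastatic_solid_tumor", 1.30),
                            ("charlson_congestive_heart_failure", 0.60)]:
            assert model.coefficients[cond] == pytest.approx(truth, abs=0.35)

    def test_median_split_ties_below(self):
        model = SeverityModel(predictor_names=["charlson_diabetes"],
                              coefficients={"charlson_diabetes": 1.0}, intercept=-1.0)
        persons = pd.DataFrame({"charlson_diabetes": [0, 0, 0, 1, 1]})
        labels = score_and_split(persons, model)
        # median equals the low score (3 of 5): ties go below
        assert list(labels) == ["below", "below", "below", "above", "above"]

    def test_degenerate_split_warns(self):
        model = SeverityModel(predictor_names=["charlson_diabetes"],
                              coefficients={"charlson_diabetes": 1.0}, intercept=-1.0)
        persons = pd.DataFrame({"charlson_diabetes": np.zeros(10)})
        with pytest.warns(DegenerateSplitWarning):
            score_and_split(persons, model)

    def test_split_invariant_to_monotone_transform(self, dementia_persons):
        model = fit_severity_model(dementia_persons, "death_all_cause")
        s = model.scores(dementia_persons)
        med = np.median(s)
        labels = score_and_split(dementia_persons, model)
        t = np.log(s / (1 - s))  # strictly monotone transform of the score
        labels_t = np.where(t > np.median(t), "above", "below")
        assert np.array_equal(labels.to_numpy(), labels_t)

    def test_severity_measures_arithmetic(self, dementia_persons):
        person = dementia_persons.iloc[0].copy()
        person["inpatient_days_dementia"] = 13
        person["n_dementia_admissions"] = 3
        person["n_dementia_recordings"] = 7
        m = severity_measures(person)
        assert (m["inpatient_days"], m["admissions"], m["recordings"]) == (13.0, 3.0, 7.0)
        person_zero = person.copy()
        for k in ("inpatient_days_dementia", "n_dementia_admissions", "n_dementia_recordings"):
            person_zero[k] = 0
        m0 = severity_measures(person_zero)
        assert (m0["inpatient_days"], m0["admissions"], m0["recordings"]) == (0.0, 0.0, 0.0)

    def test_model_measures_match_scores(self, dementia_persons):
        model = fit_severity_model(dementia_persons, "death_all_cause")
        person = dementia_persons.iloc[5]
        m = severity_measures(person, mortality_model=model)
        assert m["predicted_mortality_risk"] == pytest.approx(
            model.scores(person.to_frame().T)[0])


class TestRelativeEffect:
    def test_arithmetic(self):
        """Absolute -0.085 against a left limit of 0.50 is a 17% reduction."""
        rng = np.random.default_rng(23)
        x = rng.integers(-50, 50, 6000).astype(float)
        y = (rng.uniform(size=6000) < 0.5 - 0.085 * (x >= 0)).astype(float)
        coh = pd.DataFrame({"centered_wob": x, "outcome": y, "eligible": (x >= 0).astype(int)})
        res = rd_sharp(coh, config=RDConfig(bandwidth_policy="fixed:45"))
        rel = relative_effect(res, "eligibility")
        assert rel.relative_estimate == pytest.approx(res.estimate / res.left_limit)
        assert rel.relative_estimate == pytest.approx(-0.17, abs=3 * rel.se)

    def test_scale_invariance(self):
        """Doubling the outcome scale leaves the relative effect unchanged."""
        rng = np.random.default_rng(24)
        x = rng.integers(-50, 50, 4000).astype(float)
        y = 0.4 + 0.002 * x - 0.06 * (x >= 0) + rng.normal(0, 0.05, 4000)
        coh = pd.DataFrame({"centered_wob": x, "outcome": y, "eligible": (x >= 0).astype(int)})
        cfg = RDConfig(bandwidth_policy="fixed:40")
        r1 = relative_effect(rd_sharp(coh, config=cfg), "eligibility")
        r2 = relative_effect(rd_sharp(coh.assign(outcome=2 * y), config=cfg), "eligibility")
        assert r2.relative_estimate == pytest.approx(r1.relative_estimate, abs=1e-10)
        assert r2.se == pytest.approx(r1.se, rel=1e-6)

    def test_sharp_compliance_receipt_equals_eligibility_denominator(self):
        """With full one-sided compliance the untreated-complier level equals
        the plain left limit."""
        rng = np.random.default_rng(25)
        x = rng.integers(-50, 50, 6000).astype(float)
        v = (x >= 0).astype(float)
        y = (rng.uniform(size=6000) < 0.4 - 0.08 * v).astype(float)
        coh = pd.DataFrame({"centered_wob": x, "outcome": y, "eligible": (x >= 0).astype(int),
                            "vaccinated": v})
        fz = rd_fuzzy(coh, config=RDConfig(bandwidth_policy="fixed:45"))
        rel_r = relative_effect(fz, "receipt")
        rel_e = relative_effect(fz, "eligibility")
        assert rel_r.denominator_left_limit == pytest.approx(
            rel_e.denominator_left_limit, abs=1e-9)

    def test_denominator_guard(self):
        rng = np.random.default_rng(26)
        x = rng.integers(-50, 50, 2000).astype(float)
        y = 0.0 * x + 0.1 * (x >= 0) + rng.normal(0, 1e-4, 2000)
        coh = pd.DataFrame({"centered_wob": x, "outcome": y, "eligible": (x >= 0).astype(int)})
        res = rd_sharp(coh, config=RDConfig(bandwidth_policy="fixed:40"))
        with pytest.raises(EstimationError, match="denominator"):
            relative_effect(res, "eligibility", denominator_guard=0.05)


class TestDementiaTypes:
    def test_rank_order_and_null(self):
        base = dict(n_persons=120_000,
                    baseline_outcome_risk={"dementia": 0.12},
                    outcome_age_trend={"dementia": -0.0013},
                    true_itt={"dementia": -0.03},
                    effect_gender_ratio=1.0, preperiod_risk={})
        cfg = SyntheticConfig(rng_seed=27, dementia_type_effect_multipliers={
            "alzheimer": 0.4, "vascular": 0.4, "mixed": 2.2}, **base)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rel = dementia_type_relative_effects(generate_cohort(cfg), estimand="eligibility")
        assert set(rel) == {"alzheimer", "vascular", "mixed"}
        # the type carrying the larger injected effect shows the larger
        # relative reduction
        assert rel["mixed"] < min(rel["alzheimer"], rel["vascular"])

    def test_zero_incidence_type_omitted(self, persons_small):
        women = persons_small.loc[persons_small.gender == "female"]
        with pytest.warns(UserWarning, match="zero incidence"):
            out = dementia_type_relative_effects(
                persons_small, types=("alzheimer", "nonexistent_type"),
                estimand="eligibility")
        assert "nonexistent_type" not in out
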