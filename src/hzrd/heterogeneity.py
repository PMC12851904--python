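"""Effect heterogeneity: gender-interaction IV, severity scores, relative effects.

- The gender interaction model fully interacts the fuzzy RD design with a
  male indicator, instruments receipt and receipt-x-male with eligibility and
  eligibility-x-male, and reads the gender difference in the receipt effect
  off the interaction coefficient. Per-gender effects are recoverable as the
  female coefficient and its sum with the interaction.
- Dementia severity subgroups come from count measures (inpatient days,
  admissions, diagnosis recordings) and from logistic mortality risk scores
  fitted on ineligible persons only and evaluated at a fixed imputed age of
  80 years, split at the median.
- Relative effects divide the absolute RD effect by the predicted outcome
  level just left of the threshold (untreated-complier level for receipt
  effects, valid under one-sided noncompliance), with delta-method intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from hzrd.config import CHARLSON_CONDITIONS
from hzrd.cohort import OutcomeSpec, ascertain_outcomes, build_analysis_cohort
from hzrd.exceptions import DegenerateSplitWarning, DomainError, EstimationError
from hzrd.rd import (
    RDConfig,
    _covariance,
    _fit_functionals,
    _resolve_bandwidths,
    _sandwich,
    kernel_weight,
    rd_fuzzy,
    rd_sharp,
)

IMPUTED_AGE = 80.0


# ---------------------------------------------------------------------------
# gender interaction IV
# ---------------------------------------------------------------------------

@dataclass
class GenderInteractionResult:
    beta_female: float
    beta_male: float
    beta_interaction: float  # male minus female receipt effect
    se_interaction: float
    p_interaction: float
    se_female: float
    se_male: float
    bandwidth_h: float
    n: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def rd_gender_interaction(cohort: pd.DataFrame, outcome_col: str = "outcome",
                          receipt_col: str = "vaccinated",
                          config: RDConfig | None = None,
                          bandwidth: float | None = None,
                          x_col: str = "centered_wob") -> GenderInteractionResult:
    """Two-instrument weighted 2SLS with full gender interactions.

    The bandwidth is taken from the corresponding specification without
    interaction terms (pass ``bandwidth`` to override). Interaction p-values
    use the conventional robust (not bias-corrected) standard error.
    """
    config = config or RDConfig()
    genders = set(cohort["gender"].unique()) & {"female", "male"}
    if len(genders) < 2:
        raise EstimationError("gender interaction model needs both genders present")
    if bandwidth is None:
        h, _ = _resolve_bandwidths(cohort, outcome_col, config, x_col)
    else:
        h = float(bandwidth)

    sub = cohort.loc[np.abs(cohort[x_col].to_numpy(dtype=float)) <= h]
    x = sub[x_col].to_numpy(dtype=float)
    d = (x >= 0).astype(float)
    male = sub["male"].to_numpy(dtype=float)
    for side, g in ((0, 0), (0, 1), (1, 0), (1, 1)):
        if not np.any((d == side) & (male == g)):
            raise EstimationError("a gender is absent on one side of the threshold "
                                  "within the bandwidth")
    w = kernel_weight(x / h)
    v = sub[receipt_col].to_numpy(dtype=float)
    y = sub[outcome_col].to_numpy(dtype=float)

    p = config.polynomial_order
    run = [c for k in range(1, p + 1) for c in ((x / h)**k, d * (x / h)**k)]
    exog = np.column_stack([np.ones_like(x), *run, male, *[c * male for c in run]])
    Z = np.hstack([np.column_stack([d, d * male]), exog])
    Xm = np.hstack([np.column_stack([v, v * male]), exog])
    ZW = Z * w[:, None]
    ZtX = ZW.T @ Xm
    if np.linalg.matrix_rank(ZtX) < Z.shape[1]:
        raise EstimationError("rank-deficient gender-interaction design")
    binv = np.linalg.inv(ZtX)
    beta = binv @ (ZW.T @ y)
    e = y - Xm @ beta

    clusters = x.astype(np.int64)
    if config.variance_estimator == "cluster_by_week":
        meat = np.zeros_like(ZtX)
        for g in np.unique(clusters):
            m = clusters == g
            s = (ZW[m].T @ e[m])
            meat += np.outer(s, s)
    else:
        meat = (ZW * (e**2)[:, None]).T @ ZW
    V = binv @ meat @ binv.T

    b1, b4 = float(beta[0]), float(beta[1])
    se1 = float(np.sqrt(V[0, 0]))
    se4 = float(np.sqrt(V[1, 1]))
    se_male = float(np.sqrt(V[0, 0] + V[1, 1] + 2 * V[0, 1]))
    p4 = 2 * stats.norm.sf(abs(b4) / se4) if se4 > 0 else float("nan")
    return GenderInteractionResult(
        beta_female=b1, beta_male=b1 + b4, beta_interaction=b4,
        se_interaction=se4, p_interaction=float(p4),
        se_female=se1, se_male=se_male, bandwidth_h=h, n=len(sub),
    )


# ---------------------------------------------------------------------------
# severity scores
# ---------------------------------------------------------------------------

@dataclass
class SeverityModel:
    """Logistic mortality-risk score trained on ineligible persons only.

    Predictors are age at program start plus the Charlson condition flags
    (AIDS is never among them); the dementia-specific variant adds inpatient
    days and dementia diagnosis recordings. Predictions impute a fixed age of
    80 years so the score never uses a person's true age.
    """

    predictor_names: list
    coefficients: dict
    intercept: float
    imputed_age: float = IMPUTED_AGE
    training_side: str = "ineligible_only"
    dropped_constant: list = field(default_factory=list)

    def scores(self, persons: pd.DataFrame) -> np.ndarray:
        z = np.full(len(persons), self.intercept)
        for name in self.predictor_names:
            coef = self.coefficients[name]
            if name == "age_at_program_start":
                z = z + coef * self.imputed_age
            else:
                z = z + coef * persons[name].to_numpy(dtype=float)
        return 1.0 / (1.0 + np.exp(-z))


def _age_at_program_start(persons: pd.DataFrame) -> np.ndarray:
    dob = persons["date_of_birth"].to_numpy().astype("datetime64[D]")
    days = (np.datetime64("2013-09-01") - dob) / np.timedelta64(1, "D")
    return days / 365.25


def fit_severity_model(cohort_persons: pd.DataFrame,
                       outcome: str = "death_all_cause",
                       include_dementia_burden: bool = False,
                       threshold_date=None,
                       ridge_alpha: float = 1.0) -> SeverityModel:
    """Maximum-likelihood logistic fit of 9-year mortality on ineligible persons.

    ``outcome`` is ``death_all_cause`` for the all-cause risk measure and
    ``death_due_to_dementia`` (with ``include_dementia_burden=True``) for the
    dementia-death risk measure. Falls back to a small-ridge penalized fit on
    separation or non-convergence, with a logged warning.
    """
    from hzrd.cohort import THRESHOLD_DATE
    from hzrd.dates import center_weeks

    thr = threshold_date or THRESHOLD_DATE
    wob = cohort_persons["week_of_birth"].to_numpy().astype("datetime64[D]")
    x = np.asarray(center_weeks(wob, thr))
    train = cohort_persons.loc[x < 0].reset_index(drop=True)
    if len(train) < 20:
        raise EstimationError("too few ineligible persons to train the severity model")

    names = ["age_at_program_start"] + [f"charlson_{c}" for c in CHARLSON_CONDITIONS]
    if include_dementia_burden:
        names += ["inpatient_days_dementia", "n_dementia_recordings"]

    cols = {"age_at_program_start": _age_at_program_start(train)}
    for nm in names[1:]:
        cols[nm] = train[nm].to_numpy(dtype=float)
    X = pd.DataFrame(cols)
    dropped = [c for c in X.columns if X[c].nunique() <= 1]
    if dropped:
        X = X.drop(columns=dropped)
    kept = X.columns.tolist()
    y = ascertain_outcomes(train, OutcomeSpec(name=outcome), thr).astype(float)

    import statsmodels.api as sm

    Xc = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    coefs = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        if np.all(np.isfinite(fit.params)) and fit.mle_retvals.get("converged", True):
            coefs = np.asarray(fit.params)
    except Exception:
        coefs = None
    if coefs is None:
        warnings.warn("logistic severity fit did not converge (possible separation); "
                      "refitting with a small ridge penalty", UserWarning)
        from sklearn.linear_model import LogisticRegression

        lr = LogisticRegression(C=1.0 / ridge_alpha, max_iter=2000)
        lr.fit(X.to_numpy(dtype=float), y)
        coefs = np.r_[lr.intercept_, lr.coef_.ravel()]

    return SeverityModel(
        predictor_names=kept,
        coefficients=dict(zip(kept, map(float, coefs[1:]))),
        intercept=float(coefs[0]),
        dropped_constant=dropped,
    )


def score_and_split(cohort_persons: pd.DataFrame, model: SeverityModel) -> pd.Series:
    """Median split of severity scores; ties at the median go below.

    Returns a Series of labels {"below", "above"} indexed like the input.
    The median is computed on the full scored cohort.
    """
    s = model.scores(cohort_persons)
    med = float(np.median(s))
    above = s > med
    if not above.any() or above.all():
        warnings.warn("degenerate severity split: all scores on one side of the median",
                      DegenerateSplitWarning)
    return pd.Series(np.where(above, "above", "below"), index=cohort_persons.index)


def severity_measures(person: pd.Series,
                      mortality_model: SeverityModel | None = None,
                      dementia_death_model: SeverityModel | None = None) -> dict:
    """The five severity measures for one person.

    (i) inpatient days in dementia-related admissions, (ii) number of such
    admissions, (iii) number of dementia diagnosis recordings, (iv) predicted
    probability of death due to dementia, (v) predicted probability of death
    from any cause — (iv) and (v) require the fitted models.
    """
    for key in ("inpatient_days_dementia", "n_dementia_admissions", "n_dementia_recordings"):
        if person[key] < 0:
            raise DomainError(f"{key} must be nonnegative, got {person[key]}")
    frame = person.to_frame().T
    out = {
        "inpatient_days": float(person["inpatient_days_dementia"]),
        "admissions": float(person["n_dementia_admissions"]),
        "recordings": float(person["n_dementia_recordings"]),
        "predicted_dementia_death_risk": float(dementia_death_model.scores(frame)[0])
        if dementia_death_model is not None else None,
        "predicted_mortality_risk": float(mortality_model.scores(frame)[0])
        if mortality_model is not None else None,
    }
    return out


def severity_subgroup_effects(persons: pd.DataFrame, measure: str,
                              outcome: str = "death_due_to_dementia",
                              cohort: str = "living_with_dementia",
                              config: RDConfig | None = None) -> dict:
    """Fuzzy RD absolute and relative effects in below/above-median subgroups.

    ``measure`` is one of ``inpatient_days``, ``admissions``, ``recordings``,
    ``predicted_dementia_death_risk``, ``predicted_mortality_risk``.
    """
    from hzrd.cohort import build_cohort

    config = config or RDConfig()
    sub = build_cohort(persons, cohort)
    if measure in ("inpatient_days", "admissions", "recordings"):
        colmap = {"inpatient_days": "inpatient_days_dementia",
                  "admissions": "n_dementia_admissions",
                  "recordings": "n_dementia_recordings"}
        score = sub[colmap[measure]].to_numpy(dtype=float)
        med = float(np.median(score))
        labels = np.where(score > med, "above", "below")
        if (labels == "above").all() or (labels == "below").all():
            warnings.warn("degenerate severity split for measure " + measure,
                          DegenerateSplitWarning)
    else:
        model = fit_severity_model(
            sub,
            outcome="death_due_to_dementia" if measure == "predicted_dementia_death_risk"
            else "death_all_cause",
            include_dementia_burden=(measure == "predicted_dementia_death_risk"))
        labels = score_and_split(sub, model).to_numpy()

    results = {}
    for grp in ("below", "above"):
        grp_persons = sub.loc[labels == grp]
        ac = build_analysis_cohort(grp_persons, cohort=None, outcome=outcome)
        try:
            fz = rd_fuzzy(ac, config=config)
            rel = relative_effect(fz, estimand="receipt")
            results[grp] = {"absolute": fz.to_dict(), "relative": rel.to_dict()}
        except EstimationError as err:
            results[grp] = {"error": str(err)}
    return results


# ---------------------------------------------------------------------------
# relative effects
# ---------------------------------------------------------------------------

@dataclass
class RelativeEffect:
    absolute_effect: float
    denominator_left_limit: float
    relative_estimate: float
    ci: tuple
    p: float
    se: float
    estimand: str = "eligibility"

    def to_dict(self) -> dict:
        out = dict(self.__dict__)
        out["ci"] = list(out["ci"])
        return out


def relative_effect(rd_result, estimand: str = "eligibility",
                    denominator_guard: float = 1e-3,
                    alpha: float = 0.05) -> RelativeEffect:
    """Relative (percent-style) effect with a delta-method interval.

    For ``eligibility`` the denominator is the predicted outcome level just
    left of the threshold (the ITT fit's left intercept). For ``receipt`` it
    is the untreated-complier left limit, computed under one-sided
    noncompliance as (left limit of Y minus right limit of Y*(1-V)) divided
    by the first-stage jump; since the receipt effect carries the same
    first-stage denominator, the ratio simplifies to the ITT jump divided by
    the complier share of the left-limit level.
    """
    internals = rd_result._internals
    if not internals:
        raise EstimationError("relative_effect needs a result with retained internals")
    fit = internals["fit"]
    config = internals["rdconfig"]
    mode = config.variance_estimator
    ycol = rd_result.outcome
    oy = fit["per_outcome"][ycol]

    if estimand == "eligibility":
        num, den = oy["tau"], oy["alpha"]
        w_num, e_num = fit["a_tau"], oy["resid_p"]
        w_den, e_den = fit["a_alpha"], oy["resid_p"]
        var_num = _sandwich(w_num, e_num, fit["x"], fit["clusters"], mode, leverage=oy["lev_p"])
        var_den = _sandwich(w_den, e_den, fit["x"], fit["clusters"], mode, leverage=oy["lev_p"])
        cov = _covariance(w_num, e_num, w_den, e_den, fit["clusters"], mode)
    elif estimand == "receipt":
        if rd_result.kind != "fuzzy":
            raise EstimationError("receipt relative effect needs a fuzzy RD result")
        ot = fit["per_outcome"].get("vaccinated") or next(
            v for k, v in fit["per_outcome"].items() if k != ycol)
        # auxiliary outcome Y*(1-V): its right limit is alpha + tau of the same
        # conventional weighted fit applied to the auxiliary column
        yv = oy["y"] * (1.0 - ot["y"])
        a_alpha, a_tau = fit["a_alpha"], fit["a_tau"]
        w_right = a_alpha + a_tau
        rho = float(w_right @ yv)
        num = oy["tau"]
        den = oy["alpha"] - rho
        beta_aux = fit["Ap"] @ yv
        resid_aux = yv - fit["Xp"] @ beta_aux
        var_num = _sandwich(a_tau, oy["resid_p"], fit["x"], fit["clusters"], mode,
                            leverage=oy["lev_p"])
        var_rho = _sandwich(w_right, resid_aux, fit["x"], fit["clusters"], mode,
                            leverage=oy["lev_p"])
        var_alpha = _sandwich(a_alpha, oy["resid_p"], fit["x"], fit["clusters"], mode,
                              leverage=oy["lev_p"])
        cov_ta = _covariance(a_tau, oy["resid_p"], a_alpha, oy["resid_p"], fit["clusters"], mode)
        cov_tr = _covariance(a_tau, oy["resid_p"], w_right, resid_aux, fit["clusters"], mode)
        cov_ar = _covariance(a_alpha, oy["resid_p"], w_right, resid_aux, fit["clusters"], mode)
        var_den = var_alpha + var_rho - 2.0 * cov_ar
        cov = cov_ta - cov_tr
    else:
        raise EstimationError(f"unknown estimand {estimand!r}")

    if abs(den) < denominator_guard:
        raise EstimationError(
            f"relative effect undefined: denominator {den:.5f} within guard "
            f"{denominator_guard} of zero")
    rel = num / den
    var_rel = (var_num + rel**2 * var_den - 2.0 * rel * cov) / den**2
    se = float(np.sqrt(max(var_rel, 0.0)))
    z = stats.norm.ppf(1 - alpha / 2)
    p = 2 * stats.norm.sf(abs(rel) / se) if se > 0 else float("nan")
    # for the receipt estimand report the CACE and the complier-scale level;
    # both carry the same first-stage divisor, which cancels in the ratio
    abs_eff, den_rep = float(num), float(den)
    if estimand == "receipt":
        fs = rd_result.first_stage_jump
        abs_eff, den_rep = abs_eff / fs, den_rep / fs
    return RelativeEffect(
        absolute_effect=abs_eff, denominator_left_limit=den_rep,
        relative_estimate=float(rel), ci=(rel - z * se, rel + z * se),
        p=float(p), se=se, estimand=estimand,
    )


def dementia_type_relative_effects(persons: pd.DataFrame,
                                   types: tuple = ("alzheimer", "vascular", "mixed"),
                                   cohort: str = "no_cognitive_impairment",
                                   config: RDConfig | None = None,
                                   women_only: bool = True,
                                   estimand: str = "receipt") -> dict:
    """Per-dementia-type relative effect point estimates (no intervals).

    Point estimates only: there is no established interval procedure for
    relative effects in this design, so none is reported. Types with zero
    incidence are omitted with a warning. Defaults to women only, where the
    observed effects concentrate.
    """
    config = config or RDConfig()
    sub = persons.loc[persons["gender"] == "female"] if women_only else persons
    out = {}
    for t in types:
        ac = build_analysis_cohort(sub, cohort=cohort, outcome=f"dementia_type:{t}")
        if ac["outcome"].sum() == 0:
            warnings.warn(f"dementia type {t!r} has zero incidence; omitted", UserWarning)
            continue
        try:
            if estimand == "receipt":
                res = rd_fuzzy(ac, config=config)
            else:
                res = rd_sharp(ac, config=config)
            rel = relative_effect(res, estimand=estimand)
            out[t] = rel.relative_estimate
        except EstimationError as err:
            warnings.warn(f"dementia type {t!r} failed: {err}", UserWarning)
    return out
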