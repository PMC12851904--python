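"""Birth-season difference-in-differences triangulation.

The design restricts to persons born March 1, 1926 - February 28, 1934,
groups them into yearly birth cohorts centered on September 1 (cohort
"1933/34" spans March 1, 1933 - February 28, 1934), and splits each cohort
into a pre-September season (born March-August) and a post-September season
(born September-February of the succeeding year). Only in the 1933/34 cohort
does vaccination eligibility differ between the seasons, so a season-by-
cohort interaction identifies the program effect while month and cohort
fixed effects absorb seasonality and cohort trends.

Linear probability models throughout; heteroskedasticity-robust standard
errors by default with optional clustering on cohort-season cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from hzrd.cohort import OutcomeSpec, ascertain_outcomes
from hzrd.exceptions import EstimationError, WeakInstrumentError

DID_START = np.datetime64("1926-03-01")
DID_END = np.datetime64("1934-02-28")
REFERENCE_COHORT = "1932/33"
TREATED_COHORT = "1933/34"


def _cohort_label(year: int) -> str:
    return f"{year}/{(year + 1) % 100:02d}"


def build_did_frame(persons: pd.DataFrame, outcome_spec: OutcomeSpec | str = "death_due_to_dementia",
                    receipt_window_years: int = 9) -> pd.DataFrame:
    """Rows (person_id, season, yearly_cohort, birth_month, outcome, receipt).

    Persons outside the March 1926 - February 1934 birth restriction are
    silently excluded (their count is recorded in ``frame.attrs['n_excluded']``).
    February 29 birthdays fall in the post-September season of their cohort by
    the stated date ranges.
    """
    if isinstance(outcome_spec, str):
        outcome_spec = OutcomeSpec(name=outcome_spec)
    dob = persons["date_of_birth"].to_numpy().astype("datetime64[D]")
    keep = (dob >= DID_START) & (dob <= DID_END)
    n_excluded = int((~keep).sum())
    sub = persons.loc[keep].reset_index(drop=True)
    dob = dob[keep]
    months = pd.DatetimeIndex(sub["date_of_birth"]).month.to_numpy()
    years = pd.DatetimeIndex(sub["date_of_birth"]).year.to_numpy()

    pre = (months >= 3) & (months <= 8)
    season = np.where(pre, "pre_september", "post_september")
    cohort_year = np.where(pre, years, np.where(months >= 9, years, years - 1))
    labels = np.array([_cohort_label(int(y)) for y in cohort_year], dtype=object)

    y = ascertain_outcomes(sub, outcome_spec)
    v = sub["vaccination_date"].notna().to_numpy().astype("int8")

    frame = pd.DataFrame({
        "person_id": sub["person_id"].to_numpy(),
        "season": season,
        "yearly_cohort": labels,
        "birth_month": months.astype("int64"),
        "outcome": y,
        "receipt": v,
    })
    frame.attrs["n_excluded"] = n_excluded
    return frame


@dataclass
class DIDResult:
    """Estimates from the season-by-cohort two-stage least squares."""

    beta_2sls: float
    se: float
    ci: tuple
    p: float
    first_stage_gamma: float
    first_stage_se: float
    reduced_form: float
    reduced_form_se: float
    gamma_by_cohort: dict = field(default_factory=dict)
    pretest_flag: bool | None = None
    n: int = 0

    def to_dict(self) -> dict:
        out = {
            "beta_2sls": self.beta_2sls, "se": self.se, "ci": list(self.ci), "p": self.p,
            "first_stage_gamma": self.first_stage_gamma, "first_stage_se": self.first_stage_se,
            "reduced_form": self.reduced_form, "reduced_form_se": self.reduced_form_se,
            "gamma_by_cohort": {k: {"estimate": v[0], "se": v[1], "ci": list(v[2]), "p": v[3]}
                                for k, v in self.gamma_by_cohort.items()},
            "pretest_flag": self.pretest_flag, "n": self.n,
        }
        return out


def _fe_design(frame: pd.DataFrame):
    """Intercept + month and cohort fixed-effect dummies (drop-first)."""
    month_d = pd.get_dummies(frame["birth_month"], prefix="m", drop_first=True, dtype=float)
    coh_d = pd.get_dummies(frame["yearly_cohort"], prefix="c", drop_first=True, dtype=float)
    X = np.hstack([np.ones((len(frame), 1)), month_d.to_numpy(), coh_d.to_numpy()])
    names = ["const"] + month_d.columns.tolist() + coh_d.columns.tolist()
    return X, names


def _ols_robust(X, y, names, cluster=None):
    """OLS with HC0 (or cluster-robust) sandwich; returns beta, se, bread."""
    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX) < X.shape[1]:
        raise EstimationError(f"collinear DID design; columns {names}")
    bread = np.linalg.inv(XtX)
    beta = bread @ (X.T @ y)
    e = y - X @ beta
    if cluster is None:
        meat = (X * (e**2)[:, None]).T @ X
    else:
        meat = np.zeros_like(XtX)
        for g in np.unique(cluster):
            m = cluster == g
            s = X[m].T @ e[m]
            meat += np.outer(s, s)
    V = bread @ meat @ bread
    return beta, np.sqrt(np.diag(V)), V


def did_pretrend_test(frame: pd.DataFrame, alpha: float = 0.05,
                      cluster_by_cell: bool = False) -> dict:
    """Between-season outcome gaps per cohort relative to the reference cohort.

    Estimates the season-by-cohort interactions (all cohorts except the
    1932/33 reference) with month and cohort fixed effects. The returned
    ``any_pretrend_significant`` flag covers the non-treated cohorts only and
    is the design's go/no-go check: a significant seasonal gap outside the
    1933/34 cohort means the parallel-seasons assumption fails.
    """
    cohorts = sorted(frame["yearly_cohort"].unique())
    if len(cohorts) < 2:
        raise EstimationError("pretrend test needs at least two cohorts")
    if REFERENCE_COHORT not in cohorts:
        raise EstimationError(f"reference cohort {REFERENCE_COHORT} absent from frame")
    Xfe, names = _fe_design(frame)
    S = (frame["season"] == "post_september").to_numpy(dtype=float)
    inter_cols, inter_names = [], []
    for c in cohorts:
        if c == REFERENCE_COHORT:
            continue
        inter_cols.append(S * (frame["yearly_cohort"] == c).to_numpy(dtype=float))
        inter_names.append(c)
    X = np.hstack([Xfe, np.column_stack(inter_cols)])
    y = frame["outcome"].to_numpy(dtype=float)
    cl = None
    if cluster_by_cell:
        cl = (frame["yearly_cohort"].astype(str) + ":" + frame["season"].astype(str)).to_numpy()
    beta, se, _ = _ols_robust(X, y, names + inter_names, cluster=cl)
    k0 = Xfe.shape[1]
    z = stats.norm.ppf(1 - alpha / 2)
    gammas = {}
    flag = False
    for j, c in enumerate(inter_names):
        est, s = float(beta[k0 + j]), float(se[k0 + j])
        p = 2 * stats.norm.sf(abs(est) / s) if s > 0 else float("nan")
        gammas[c] = (est, s, (est - z * s, est + z * s), p)
        if c != TREATED_COHORT and p < alpha:
            flag = True
    return {"gamma_by_cohort": gammas, "any_pretrend_significant": flag}


def did_2sls(frame: pd.DataFrame, alpha: float = 0.05, first_stage_guard: float = 0.01,
             cluster_by_cell: bool = False, run_pretest: bool = True) -> DIDResult:
    """Receipt effect via 2SLS with the season-x-1933/34 cell as instrument.

    First stage: receipt on the instrument plus month/cohort fixed effects;
    second stage instruments receipt with the interaction. The identity
    beta = reduced-form / first-stage holds exactly when the designs coincide.
    """
    Xfe, names = _fe_design(frame)
    S = (frame["season"] == "post_september").to_numpy(dtype=float)
    C = (frame["yearly_cohort"] == TREATED_COHORT).to_numpy(dtype=float)
    inst = S * C
    y = frame["outcome"].to_numpy(dtype=float)
    v = frame["receipt"].to_numpy(dtype=float)
    cl = None
    if cluster_by_cell:
        cl = (frame["yearly_cohort"].astype(str) + ":" + frame["season"].astype(str)).to_numpy()

    Xfs = np.hstack([inst[:, None], Xfe])
    beta_fs, se_fs, _ = _ols_robust(Xfs, v, ["inst"] + names, cluster=cl)
    gamma = float(beta_fs[0])
    if abs(gamma) < first_stage_guard:
        raise WeakInstrumentError(f"DID first-stage gamma {gamma:.4f} below guard")
    beta_rf, se_rf, _ = _ols_robust(Xfs, y, ["inst"] + names, cluster=cl)

    # just-identified 2SLS: beta = (Z'X)^-1 Z'y
    Z = np.hstack([inst[:, None], Xfe])
    Xm = np.hstack([v[:, None], Xfe])
    ZtX = Z.T @ Xm
    if np.linalg.matrix_rank(ZtX) < Z.shape[1]:
        raise EstimationError("rank-deficient 2SLS design")
    binv = np.linalg.inv(ZtX)
    beta = binv @ (Z.T @ y)
    e = y - Xm @ beta
    if cl is None:
        meat = (Z * (e**2)[:, None]).T @ Z
    else:
        meat = np.zeros_like(ZtX)
        for g in np.unique(cl):
            m = cl == g
            s = Z[m].T @ e[m]
            meat += np.outer(s, s)
    V = binv @ meat @ binv.T
    b2 = float(beta[0])
    se2 = float(np.sqrt(V[0, 0]))
    z = stats.norm.ppf(1 - alpha / 2)
    p = 2 * stats.norm.sf(abs(b2) / se2) if se2 > 0 else float("nan")

    gammas, flag = {}, None
    if run_pretest:
        pre = did_pretrend_test(frame, alpha=alpha, cluster_by_cell=cluster_by_cell)
        gammas, flag = pre["gamma_by_cohort"], pre["any_pretrend_significant"]
        if flag:
            warnings.warn(
                "significant between-season gaps outside the treated cohort: "
                "the parallel-seasons assumption looks violated for this outcome; "
                "interpret the DID estimate with caution", UserWarning)

    return DIDResult(
        beta_2sls=b2, se=se2, ci=(b2 - z * se2, b2 + z * se2), p=float(p),
        first_stage_gamma=gamma, first_stage_se=float(se_fs[0]),
        reduced_form=float(beta_rf[0]), reduced_form_se=float(se_rf[0]),
        gamma_by_cohort=gammas, pretest_flag=flag, n=len(frame),
    )
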