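"""Local-polynomial regression discontinuity engine.

Implements, from first principles:

- triangular-kernel weighted local polynomial estimation of the outcome jump
  at the threshold (sharp intent-to-treat effect),
- fuzzy RD: the complier average causal effect via weighted two-stage least
  squares with eligibility as the instrument for receipt,
- plug-in MSE-optimal bandwidth selection for the boundary estimator and for
  the higher-order bias estimate (Imbens-Kalyanaraman-style pilot stages with
  exact triangular-kernel boundary constants),
- robust bias-corrected inference: the order-(p+1) local fit at the bias
  bandwidth estimates the leading curvature bias, which is subtracted from
  the point estimate; because both the estimate and the bias estimate are
  linear in the outcomes, their combined linear weights give a variance that
  accounts for the bias-estimation step (the "robust" variance).

The running variable here is discrete (week of birth), so the default
variance estimator clusters on week-of-birth mass points.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from hzrd.exceptions import (
    BandwidthFallbackWarning,
    EstimationError,
    WeakInstrumentError,
)

VARIANCE_ESTIMATORS = ("cluster_by_week", "hc0", "hc1", "hc3", "nearest_neighbor")


def kernel_weight(u):
    """Triangular kernel: weight ``max(0, 1 - |u|)`` at bandwidth-scaled distance u."""
    u = np.asarray(u, dtype=float)
    w = np.maximum(0.0, 1.0 - np.abs(u))
    return w if w.ndim else float(w)


@dataclass
class RDConfig:
    """Estimation settings for the RD fits."""

    polynomial_order: int = 1  # local linear; 2 = local quadratic robustness check
    kernel: str = "triangular"
    bandwidth_policy: str = "mse_optimal"  # or "fixed:<weeks>" / "multiplier:<factor>"
    bias_order: int | None = None  # default polynomial_order + 1
    bias_bandwidth_policy: str = "mse_optimal_derivative"  # or "same_as_h"
    variance_estimator: str = "cluster_by_week"
    covariates: tuple = ()
    fixed_effects: tuple = ()  # e.g. ("rollout_cohort",)
    alpha: float = 0.05
    min_per_side: int = 50
    first_stage_guard: float = 0.01

    def __post_init__(self):
        if self.polynomial_order not in (1, 2):
            raise EstimationError("polynomial_order must be 1 or 2")
        if self.kernel != "triangular":
            raise EstimationError(f"unsupported kernel {self.kernel!r}")
        if not (0.0 < self.alpha < 1.0):
            raise EstimationError("alpha must be in (0, 1)")
        if self.variance_estimator not in VARIANCE_ESTIMATORS:
            raise EstimationError(f"unknown variance_estimator {self.variance_estimator!r}")

    @property
    def q(self) -> int:
        return self.bias_order if self.bias_order is not None else self.polynomial_order + 1

    def replace(self, **kw) -> "RDConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class RDResult:
    """Point estimate plus conventional and robust bias-corrected inference.

    ``estimate`` is the conventional local-polynomial estimate; ``ci_robust``
    is centered on the bias-corrected estimate and therefore need not contain
    ``estimate`` — a documented property of robust bias-corrected inference.
    """

    estimate: float
    estimate_bc: float
    se_conventional: float
    se_robust: float
    ci_robust: tuple
    p_robust: float
    p_conventional: float
    bandwidth_h: float
    bandwidth_b: float
    n_eff_left: int
    n_eff_right: int
    kind: str = "sharp"
    outcome: str = ""
    first_stage_jump: float | None = None
    left_limit: float | None = None
    config: dict = field(default_factory=dict)
    _internals: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        out = {k: v for k, v in dataclasses.asdict(self).items() if not k.startswith("_")}
        out["ci_robust"] = list(out["ci_robust"])
        return out


# ---------------------------------------------------------------------------
# design matrices and linear-functional weights
# ---------------------------------------------------------------------------

def _poly_design(x, d, order, scale=1.0):
    """Columns [1, D, z, D*z, ..., z^order, D*z^order] with z = x / scale.

    The jump coefficient (index 1) is invariant to the scaling, which exists
    purely to keep the normal equations well conditioned at wide bandwidths.
    """
    z = x / scale
    cols = [np.ones_like(z), d.astype(float)]
    for k in range(1, order + 1):
        cols.append(z**k)
        cols.append(d * z**k)
    return np.column_stack(cols)


def _encode_extras(df: pd.DataFrame | None, covariates, fixed_effects, n, x=None,
                   weights=None):
    """Additive covariate columns plus dummy-encoded fixed effects.

    Fixed-effect reference levels are the levels adjacent to the threshold on
    each side (when ``x`` is given): the constant then absorbs the
    just-ineligible level and the eligibility indicator the just-eligible
    one, so the jump coefficient remains the contrast at the threshold.
    """
    if not covariates and not fixed_effects:
        return np.empty((n, 0)), []
    blocks, names = [], []
    for c in covariates:
        blocks.append(df[c].to_numpy(dtype=float)[:, None])
        names.append(c)
    for fe in fixed_effects:
        vals = df[fe].to_numpy()
        refs = set()
        if x is not None and len(x):
            w = weights if weights is not None else kernel_weight(x / max(np.max(np.abs(x)), 1))
            for side in (x < 0, x >= 0):
                if side.any():
                    tab = pd.Series(w[side]).groupby(pd.Series(vals[side])).sum()
                    refs.add(tab.idxmax())
        dummies = pd.get_dummies(pd.Series(vals), prefix=fe, dtype=float,
                                 drop_first=not refs)
        drop_cols = [f"{fe}_{r}" for r in refs if f"{fe}_{r}" in dummies.columns]
        dummies = dummies.drop(columns=drop_cols)
        blocks.append(dummies.to_numpy())
        names.extend(dummies.columns.tolist())
    return np.hstack(blocks), names


def _solve_weights(X, w, names=None):
    """Weight matrix A with beta = A @ y for WLS; errors name collinear columns."""
    Xw = X * w[:, None]
    M = X.T @ Xw
    k = X.shape[1]
    rank = np.linalg.matrix_rank(M)
    if rank < k:
        offenders = names if names else [f"col{j}" for j in range(k)]
        raise EstimationError(f"collinear design; check columns {offenders}")
    A = np.linalg.solve(M, Xw.T)
    return A


def _prune_dependent(base: np.ndarray, extras: np.ndarray, names: list, w: np.ndarray,
                     covariate_names: tuple):
    """Drop extra columns that are linearly dependent on the base design.

    Fixed-effect dummies are structurally collinear with the eligibility
    indicator (cohort labels partition along the threshold), so dependent
    dummies are silently absorbed; an explicit covariate that turns out
    collinear is an error naming it.
    """
    if extras.shape[1] == 0:
        return extras, names
    sw = np.sqrt(w)[:, None]
    kept_idx, dropped = [], []
    work = base * sw
    for j in range(extras.shape[1]):
        cand = np.hstack([work, extras[:, [j]] * sw])
        if np.linalg.matrix_rank(cand.T @ cand) == cand.shape[1]:
            work = cand
            kept_idx.append(j)
        else:
            dropped.append(names[j])
    bad_covs = [n for n in dropped if n in covariate_names]
    if bad_covs:
        raise EstimationError(f"collinear covariates: {bad_covs}")
    return extras[:, kept_idx], [names[j] for j in kept_idx]


def _check_support(x, w, side_mask, order, side_name):
    vals = np.unique(x[side_mask & (w > 0)])
    if vals.size <= order + 1:
        raise EstimationError(
            f"insufficient support on the {side_name} side of the threshold: "
            f"{vals.size} distinct running-variable values within bandwidth, "
            f"need > {order + 1}")


def _sandwich(wvec, resid, x, clusters, mode, leverage=None):
    """Variance of the linear functional sum(wvec * y) under the chosen estimator."""
    e = resid
    if mode == "cluster_by_week":
        key = clusters
        order = np.argsort(key, kind="stable")
        ck = key[order]
        contrib = (wvec * e)[order]
        cuts = np.flatnonzero(np.r_[True, ck[1:] != ck[:-1]])
        sums = np.add.reduceat(contrib, cuts)
        return float(np.sum(sums**2))
    if mode in ("hc0", "hc1"):
        v = float(np.sum(wvec**2 * e**2))
        if mode == "hc1":
            nz = int(np.sum(wvec != 0))
            v *= nz / max(nz - 1, 1)
        return v
    if mode == "hc3":
        lev = leverage if leverage is not None else np.zeros_like(e)
        return float(np.sum(wvec**2 * (e / (1.0 - np.clip(lev, 0, 0.99)))**2))
    if mode == "nearest_neighbor":
        # sigma_i^2 from the spread of y within the same running-variable mass
        # point (weeks hold many observations here); falls back to residual^2
        # for singleton mass points
        df_ = pd.DataFrame({"k": clusters, "e": e})
        grp = df_.groupby("k")["e"]
        var = grp.transform("var").to_numpy()
        cnt = grp.transform("count").to_numpy()
        sig2 = np.where(cnt > 1, var, e**2)
        return float(np.sum(wvec**2 * sig2))
    raise EstimationError(f"unknown variance estimator {mode!r}")


def _covariance(w1, e1, w2, e2, clusters, mode):
    """Covariance of two linear functionals sharing the same rows."""
    if mode == "cluster_by_week":
        order = np.argsort(clusters, kind="stable")
        ck = clusters[order]
        c1 = (w1 * e1)[order]
        c2 = (w2 * e2)[order]
        cuts = np.flatnonzero(np.r_[True, ck[1:] != ck[:-1]])
        return float(np.sum(np.add.reduceat(c1, cuts) * np.add.reduceat(c2, cuts)))
    return float(np.sum(w1 * w2 * e1 * e2))


# ---------------------------------------------------------------------------
# triangular-kernel boundary constants (exact polynomial integrals)
# ---------------------------------------------------------------------------

def _boundary_constants(nu: int, order: int):
    """(bias, variance) constants for the nu-th coefficient of a boundary
    local polynomial fit of the given order with a triangular kernel.

    Gamma[j,k] = int_0^1 u^{j+k} K(u) du, theta[j] = int_0^1 u^{j+order+1} K(u) du,
    Psi[j,k] = int_0^1 u^{j+k} K(u)^2 du with K(u) = 1 - u; the bias constant is
    (Gamma^-1 theta)[nu], the variance constant (Gamma^-1 Psi Gamma^-1)[nu, nu].
    """
    m = order + 1

    def ik(p):  # int_0^1 u^p (1-u) du
        return 1.0 / (p + 1) - 1.0 / (p + 2)

    def ik2(p):  # int_0^1 u^p (1-u)^2 du
        return 1.0 / (p + 1) - 2.0 / (p + 2) + 1.0 / (p + 3)

    gamma = np.array([[ik(j + k) for k in range(m)] for j in range(m)])
    theta = np.array([ik(j + order + 1) for j in range(m)])
    psi = np.array([[ik2(j + k) for k in range(m)] for j in range(m)])
    ginv = np.linalg.inv(gamma)
    return float((ginv @ theta)[nu]), float((ginv @ psi @ ginv)[nu, nu])


# ---------------------------------------------------------------------------
# plug-in MSE-optimal bandwidths
# ---------------------------------------------------------------------------

def _side_poly_deriv(x, y, order, deriv):
    """deriv-th derivative at 0 from a global polynomial fit on one side.

    The fit runs on a rescaled abscissa for numerical stability; the
    derivative is mapped back to the original scale.
    """
    if np.unique(x).size <= order:
        return 0.0, 0
    s = float(np.max(np.abs(x)))
    if s == 0:
        return 0.0, len(x)
    z = x / s
    X = np.column_stack([z**k for k in range(order + 1)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    import math
    return float(beta[deriv] * math.factorial(deriv) / s**deriv), len(x)


def select_bandwidth_mse(cohort: pd.DataFrame, outcome_col: str = "outcome",
                         config: RDConfig | None = None,
                         x_col: str = "centered_wob"):
    """Plug-in MSE-optimal main bandwidth h and bias bandwidth b (in weeks).

    Pilot curvature comes from global polynomial side fits; variance and
    density at the threshold come from residual-based estimates near the
    boundary; the optimum follows
    ``h = [ (2nu+1) V (s2l+s2r)/f / (2(q+1-nu) B_diff^2) ]^(1/(2q+3)) n^(-1/(2q+3))``
    with exact triangular boundary constants and an Imbens-Kalyanaraman-style
    regularization term guarding against near-zero curvature estimates.
    """
    config = config or RDConfig()
    p = config.polynomial_order
    x = cohort[x_col].to_numpy(dtype=float)
    y = cohort[outcome_col].to_numpy(dtype=float)
    n = x.size
    nl = int(np.sum(x < 0))
    nr = int(np.sum(x >= 0))
    if nl < config.min_per_side or nr < config.min_per_side:
        raise EstimationError(
            f"bandwidth selection needs >= {config.min_per_side} observations per side "
            f"(have {nl} left, {nr} right)")

    sx = float(np.std(x))
    h1 = 1.84 * sx * n**-0.2
    rot_h = h1
    rot_b = 2.58 * sx * n ** (-1.0 / 7.0)

    near = np.abs(x) <= h1
    fhat = float(np.sum(near)) / (2.0 * h1 * n)
    s2l = float(np.var(y[near & (x < 0)])) if np.sum(near & (x < 0)) > 1 else 0.0
    s2r = float(np.var(y[near & (x >= 0)])) if np.sum(near & (x >= 0)) > 1 else 0.0
    if fhat <= 0 or (s2l + s2r) <= 0:
        warnings.warn("degenerate variance or density at the threshold; "
                      "falling back to rule-of-thumb bandwidths",
                      BandwidthFallbackWarning)
        return min(rot_h, _max_span(x)), min(rot_b, _max_span(x))

    xl, yl = x[x < 0], y[x < 0]
    xr, yr = x[x >= 0], y[x >= 0]

    # third derivatives from global cubic side fits -> pilot bandwidths h2
    m3l, _ = _side_poly_deriv(xl, yl, 3, 3)
    m3r, _ = _side_poly_deriv(xr, yr, 3, 3)

    def pilot_h2(s2, m3, nside):
        denom = fhat * max(m3**2, 1e-30)
        return 3.56 * (s2 / denom) ** (1.0 / 7.0) * max(nside, 2) ** (-1.0 / 7.0)

    h2l = min(pilot_h2(s2l, m3l, nl), _max_span(xl))
    h2r = min(pilot_h2(s2r, m3r, nr), _max_span(xr))

    # curvature (second derivatives) from unweighted quadratics within h2
    def curvature(xs, ys, h2):
        m = np.abs(xs) <= h2
        m2, n2 = _side_poly_deriv(xs[m], ys[m], 2, 2)
        return m2, max(n2, 2)

    m2l, n2l = curvature(xl, yl, h2l)
    m2r, n2r = curvature(xr, yr, h2r)
    reg_l = 2160.0 * s2l / (n2l * h2l**4)
    reg_r = 2160.0 * s2r / (n2r * h2r**4)

    bias0, var0 = _boundary_constants(0, p)
    import math
    fact = math.factorial(p + 1)
    b_diff_sq = (bias0 / fact) ** 2 * ((m2r - m2l) ** 2 + reg_l + reg_r)
    num = var0 * (s2l + s2r) / fhat
    # MSE(h) = bias^2 h^{2(p+1)} + V/(f n h): optimum h^{2p+3} = C / (2(p+1) A)
    den = 2.0 * (p + 1) * b_diff_sq
    if den <= 0 or not np.isfinite(den):
        warnings.warn("zero curvature in bandwidth plug-in; using rule of thumb",
                      BandwidthFallbackWarning)
        h = rot_h
    else:
        h = (num / den) ** (1.0 / (2 * p + 3)) * n ** (-1.0 / (2 * p + 3))

    # bias bandwidth: MSE-optimal for the q-th derivative (order-q fit),
    # pilot fourth... (q+1)-th derivatives from global order-(q+1) side fits
    q = config.q
    mql, _ = _side_poly_deriv(xl, yl, q + 1, q + 1)
    mqr, _ = _side_poly_deriv(xr, yr, q + 1, q + 1)
    bias_q, var_q = _boundary_constants(q, q)
    factq = math.factorial(q + 1)
    reg_b = 2160.0 * (s2l / (n2l * h2l ** (2 * q + 2)) + s2r / (n2r * h2r ** (2 * q + 2)))
    bq_diff_sq = (bias_q / factq) ** 2 * ((mqr - mql) ** 2 + reg_b)
    numb = (2 * q + 1) * var_q * (s2l + s2r) / fhat
    denb = 2.0 * (q + 1 - q) * bq_diff_sq  # 2(q+1-nu) with nu=q
    if denb <= 0 or not np.isfinite(denb):
        warnings.warn("zero higher-order curvature in bias-bandwidth plug-in; "
                      "using rule of thumb", BandwidthFallbackWarning)
        b = rot_b
    else:
        b = (numb / denb) ** (1.0 / (2 * q + 3)) * n ** (-1.0 / (2 * q + 3))

    span = _max_span(x)
    # smallest h with > p+1 distinct support points per side (scale-equivariant)
    kth = p + 2
    low = 0.0
    for xs in (np.abs(xl), xr):
        vals = np.unique(xs[xs >= 0])
        if vals.size >= kth:
            low = max(low, float(vals[kth - 1]))
    h = float(np.clip(h, low if low > 0 else None, span))
    b = float(np.clip(b, h, span))
    return h, b


def _max_span(x):
    return float(max(np.max(np.abs(x)), 1.0))


def _resolve_bandwidths(cohort, outcome_col, config, x_col="centered_wob"):
    policy = config.bandwidth_policy
    if isinstance(policy, (int, float)):
        h = float(policy)
        b = h if config.bias_bandwidth_policy == "same_as_h" else 2.0 * h
        return h, b
    if policy == "mse_optimal" or policy.startswith("multiplier:"):
        h, b = select_bandwidth_mse(cohort, outcome_col, config, x_col)
        if policy.startswith("multiplier:"):
            h *= float(policy.split(":", 1)[1])
        if config.bias_bandwidth_policy == "same_as_h":
            b = h
        else:
            b = max(b, h)
        return h, b
    if policy.startswith("fixed:"):
        h = float(policy.split(":", 1)[1])
        b = h if config.bias_bandwidth_policy == "same_as_h" else 2.0 * h
        return h, b
    raise EstimationError(f"unknown bandwidth_policy {policy!r}")


# ---------------------------------------------------------------------------
# core fit
# ---------------------------------------------------------------------------

def _fit_functionals(cohort, ycols, config, h, b, x_col="centered_wob"):
    """Shared machinery: conventional and bias-corrected linear weights for the
    jump (and intercept) functional, applied to one or more outcome columns.

    Returns a dict with, per outcome column: conventional estimate, bias-
    corrected estimate, weight vectors, residuals, and the shared row subset.
    """
    p, q = config.polynomial_order, config.q
    x_all = cohort[x_col].to_numpy(dtype=float)
    hb = max(h, b)
    S = np.abs(x_all) <= hb
    sub = cohort.loc[S]
    x = x_all[S]
    d = (x >= 0).astype(float)
    wh = kernel_weight(x / h)
    wb = kernel_weight(x / b)
    _check_support(x, wh, x < 0, p, "left")
    _check_support(x, wh, x >= 0, p, "right")
    _check_support(x, wb, x < 0, q, "left")
    _check_support(x, wb, x >= 0, q, "right")

    extras, extra_names = _encode_extras(sub, config.covariates, config.fixed_effects,
                                         len(sub), x=x, weights=wh)
    base_names_p = ["const", "D"] + [n for k in range(1, p + 1) for n in (f"x^{k}", f"D*x^{k}")]
    base_names_q = ["const", "D"] + [n for k in range(1, q + 1) for n in (f"x^{k}", f"D*x^{k}")]
    base_p = _poly_design(x, d, p, scale=h)
    extras, extra_names = _prune_dependent(base_p, extras, extra_names, wh,
                                           tuple(config.covariates))
    Xp = np.hstack([base_p, extras])
    Xq = np.hstack([_poly_design(x, d, q, scale=b), extras])

    Ap = _solve_weights(Xp, wh, base_names_p + extra_names)
    Aq = _solve_weights(Xq, wb, base_names_q + extra_names)
    a_tau = Ap[1]
    a_alpha = Ap[0]

    # leading-bias functionals: the q-order fit's (x/b)^q coefficient estimates
    # m^(q)(0) b^q / q!, so dividing its weight rows by b^q recovers the x^q
    # curvature coefficient; columns 2q (left side) and 2q+1 (jump in it)
    u = x**q
    v = d * x**q
    lam_u = float(a_tau @ u)
    lam_v = float(a_tau @ v)
    aq_c = Aq[2 * q] / b**q
    aq_d = Aq[2 * q + 1] / b**q
    w_bc = a_tau - lam_u * aq_c - lam_v * aq_d
    lam_u0 = float(a_alpha @ u)
    lam_v0 = float(a_alpha @ v)
    w_bc0 = a_alpha - lam_u0 * aq_c - lam_v0 * aq_d

    clusters = x.astype(np.int64)
    lev_p = np.einsum("ij,ji->i", Xp, Ap)  # leverages of the order-p fit
    lev_q = np.einsum("ij,ji->i", Xq, Aq)

    out = {"x": x, "d": d, "wh": wh, "wb": wb, "clusters": clusters, "subset": S,
           "Ap": Ap, "Xp": Xp,
           "a_tau": a_tau, "a_alpha": a_alpha, "w_bc": w_bc, "w_bc_alpha": w_bc0,
           "n_eff_left": int(np.sum((x < 0) & (wh > 0))),
           "n_eff_right": int(np.sum((x >= 0) & (wh > 0))),
           "per_outcome": {}}
    for ycol in ycols:
        y = sub[ycol].to_numpy(dtype=float)
        beta_p = Ap @ y
        beta_q = Aq @ y
        resid_p = y - Xp @ beta_p
        resid_q = y - Xq @ beta_q
        out["per_outcome"][ycol] = {
            "y": y,
            "tau": float(beta_p[1]),
            "alpha": float(beta_p[0]),
            "tau_bc": float(w_bc @ y),
            "alpha_bc": float(w_bc0 @ y),
            "resid_p": resid_p,
            "resid_q": resid_q,
            "lev_p": lev_p,
            "lev_q": lev_q,
        }
    return out


def _variance_pair(fit, od, config):
    """(conventional, robust) variances of the jump functional for one outcome."""
    mode = config.variance_estimator
    v_conv = _sandwich(fit["a_tau"], od["resid_p"], fit["x"], fit["clusters"], mode,
                       leverage=od["lev_p"])
    v_rob = _sandwich(fit["w_bc"], od["resid_q"], fit["x"], fit["clusters"], mode,
                      leverage=od["lev_q"])
    return v_conv, v_rob


def _normal_inference(est_bc, se_rob, est_conv, se_conv, alpha):
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    ci = (est_bc - z * se_rob, est_bc + z * se_rob)
    p_rob = 2.0 * stats.norm.sf(abs(est_bc) / se_rob) if se_rob > 0 else float("nan")
    p_conv = 2.0 * stats.norm.sf(abs(est_conv) / se_conv) if se_conv > 0 else float("nan")
    return ci, p_rob, p_conv


def rd_sharp(cohort: pd.DataFrame, outcome_col: str = "outcome",
             config: RDConfig | None = None, x_col: str = "centered_wob") -> RDResult:
    """Sharp RD: the discontinuity in the outcome at the threshold (ITT).

    Weighted least squares of the outcome on eligibility, the centered running
    variable and their interaction (order per config), restricted to the
    bandwidth with triangular weights; covariates and fixed effects enter
    additively. Robust bias-corrected CI/p attached.
    """
    config = config or RDConfig()
    h, b = _resolve_bandwidths(cohort, outcome_col, config, x_col)
    fit = _fit_functionals(cohort, [outcome_col], config, h, b, x_col)
    od = fit["per_outcome"][outcome_col]
    v_conv, v_rob = _variance_pair(fit, od, config)
    se_c, se_r = np.sqrt(v_conv), np.sqrt(v_rob)
    ci, p_rob, p_conv = _normal_inference(od["tau_bc"], se_r, od["tau"], se_c, config.alpha)
    return RDResult(
        estimate=od["tau"], estimate_bc=od["tau_bc"],
        se_conventional=float(se_c), se_robust=float(se_r),
        ci_robust=ci, p_robust=float(p_rob), p_conventional=float(p_conv),
        bandwidth_h=float(h), bandwidth_b=float(b),
        n_eff_left=fit["n_eff_left"], n_eff_right=fit["n_eff_right"],
        kind="sharp", outcome=outcome_col, left_limit=od["alpha"],
        config={"polynomial_order": config.polynomial_order,
                "variance_estimator": config.variance_estimator,
                "covariates": list(config.covariates),
                "fixed_effects": list(config.fixed_effects)},
        _internals={"fit": fit, "rdconfig": config},
    )


def rd_fuzzy(cohort: pd.DataFrame, outcome_col: str = "outcome",
             receipt_col: str = "vaccinated", config: RDConfig | None = None,
             x_col: str = "centered_wob") -> RDResult:
    """Fuzzy RD: receipt effect (CACE) via 2SLS with eligibility as instrument.

    Shares the bandwidth and kernel weights with the ITT fit (bandwidth
    selected on the outcome); with no covariates the point estimate equals
    ITT / first-stage jump (Wald identity). Robust bias-corrected inference
    uses the delta method on the separately bias-corrected numerator and
    denominator including their covariance.
    """
    config = config or RDConfig()
    h, b = _resolve_bandwidths(cohort, outcome_col, config, x_col)
    fit = _fit_functionals(cohort, [outcome_col, receipt_col], config, h, b, x_col)
    oy = fit["per_outcome"][outcome_col]
    ot = fit["per_outcome"][receipt_col]
    tau_t = ot["tau"]
    if abs(tau_t) < config.first_stage_guard:
        raise WeakInstrumentError(
            f"first-stage jump {tau_t:.4f} below guard {config.first_stage_guard}")
    mode = config.variance_estimator

    if config.covariates or config.fixed_effects:
        # weighted just-identified 2SLS on the full design
        x, d, wh = fit["x"], fit["d"], fit["wh"]
        sub = cohort.loc[fit["subset"]]
        extras, extra_names = _encode_extras(sub, config.covariates, config.fixed_effects,
                                             len(sub), x=x, weights=wh)
        p = config.polynomial_order
        slope = [c for k in range(1, p + 1) for c in ((x / h)**k, d * (x / h)**k)]
        base = np.column_stack([np.ones_like(x), d, *slope])
        extras, _ = _prune_dependent(base, extras, extra_names, wh,
                                     tuple(config.covariates))
        exog = np.hstack([np.column_stack([np.ones_like(x), *slope]), extras])
        Z = np.hstack([d[:, None], exog])  # instrument first
        Xm = np.hstack([sub[receipt_col].to_numpy(dtype=float)[:, None], exog])
        y = oy["y"]
        ZW = Z * wh[:, None]
        beta = np.linalg.solve(ZW.T @ Xm, ZW.T @ y)
        tau_conv = float(beta[0])
    else:
        tau_conv = oy["tau"] / tau_t

    tau_bc = oy["tau_bc"] / ot["tau_bc"]

    # delta-method variances of the ratio, conventional and robust
    def ratio_var(wy, ey, wt, et, num, den):
        vy = _sandwich(wy, ey, fit["x"], fit["clusters"], mode, leverage=oy["lev_q"])
        vt = _sandwich(wt, et, fit["x"], fit["clusters"], mode, leverage=ot["lev_q"])
        cov = _covariance(wy, ey, wt, et, fit["clusters"], mode)
        r = num / den
        return (vy + r**2 * vt - 2.0 * r * cov) / den**2

    v_conv = ratio_var(fit["a_tau"], oy["resid_p"], fit["a_tau"], ot["resid_p"],
                       oy["tau"], tau_t)
    v_rob = ratio_var(fit["w_bc"], oy["resid_q"], fit["w_bc"], ot["resid_q"],
                      oy["tau_bc"], ot["tau_bc"])
    se_c, se_r = np.sqrt(max(v_conv, 0.0)), np.sqrt(max(v_rob, 0.0))
    ci, p_rob, p_conv = _normal_inference(tau_bc, se_r, tau_conv, se_c, config.alpha)
    return RDResult(
        estimate=tau_conv, estimate_bc=float(tau_bc),
        se_conventional=float(se_c), se_robust=float(se_r),
        ci_robust=ci, p_robust=float(p_rob), p_conventional=float(p_conv),
        bandwidth_h=float(h), bandwidth_b=float(b),
        n_eff_left=fit["n_eff_left"], n_eff_right=fit["n_eff_right"],
        kind="fuzzy", outcome=outcome_col, first_stage_jump=float(tau_t),
        left_limit=oy["alpha"],
        config={"polynomial_order": config.polynomial_order,
                "variance_estimator": config.variance_estimator,
                "covariates": list(config.covariates),
                "fixed_effects": list(config.fixed_effects)},
        _internals={"fit": fit, "rdconfig": config},
    )


def robust_bc_inference(result: RDResult) -> dict:
    """Expose the robust bias-corrected pieces of a fitted RD result."""
    return {
        "bias_estimate": result.estimate - result.estimate_bc,
        "estimate_bc": result.estimate_bc,
        "se_robust": result.se_robust,
        "ci_robust": result.ci_robust,
        "p_robust": result.p_robust,
    }
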