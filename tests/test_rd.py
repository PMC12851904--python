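"""RD engine: closed-form oracles, identities, bandwidths, inference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from hzrd.exceptions import EstimationError, WeakInstrumentError
from hzrd.rd import (
    RDConfig,
    kernel_weight,
    rd_fuzzy,
    rd_sharp,
    select_bandwidth_mse,
)


def make_cohort(x, y, v=None):
    df = pd.DataFrame({"centered_wob": np.asarray(x, float),
                       "outcome": np.asarray(y, float),
                       "eligible": (np.asarray(x) >= 0).astype(int)})
    if v is not None:
        df["vaccinated"] = np.asarray(v, float)
    return df


def oracle_wls_jump(x, y, h, order=1):
    """Independent closed-form weighted least squares via the sqrt-weight
    transform and lstsq — the oracle route, no normal equations shared with
    the implementation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    m = np.abs(x) <= h
    xs, ys = x[m], y[m]
    d = (xs >= 0).astype(float)
    w = np.maximum(0, 1 - np.abs(xs / h))
    cols = [np.ones_like(xs), d]
    for k in range(1, order + 1):
        cols += [(xs / h) ** k, d * (xs / h) ** k]
    X = np.column_stack(cols)
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], ys * sw, rcond=None)
    return beta[1]


class TestKernel:
    @pytest.mark.parametrize("u, expected", [(0.0, 1.0), (0.5, 0.5), (-0.5, 0.5),
                                             (1.2, 0.0), (-3.0, 0.0), (1.0, 0.0)])
    def test_triangular_values(self, u, expected):
        assert kernel_weight(u) == pytest.approx(expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-5, 5))
    def test_bounds(self, u):
        w = kernel_weight(u)
        assert 0.0 <= w <= 1.0


class TestSharpOracle:
    @pytest.mark.parametrize("seed, h, order", [(0, 10, 1), (1, 15, 1), (2, 12, 2),
                                                (3, 8, 1), (4, 20, 2)])
    def test_equals_closed_form_wls(self, seed, h, order):
        """Fixed-bandwidth sharp estimate equals the independent WLS solution."""
        rng = np.random.default_rng(seed)
        x = rng.integers(-25, 25, 40).astype(float)
        y = 0.2 + 0.01 * x + 0.15 * (x >= 0) + rng.normal(0, 0.1, 40)
        res = rd_sharp(make_cohort(x, y),
                       config=RDConfig(bandwidth_policy=f"fixed:{h}",
                                       polynomial_order=order))
        assert res.estimate == pytest.approx(oracle_wls_jump(x, y, h, order), abs=1e-10)

    def test_noiseless_dgp_recovered_exactly(self):
        x = np.repeat(np.arange(-30, 30), 2).astype(float)
        y = 0.1 + 0.002 * x + 0.2 * (x >= 0)
        for h in (10, 25):
            res = rd_sharp(make_cohort(x, y), config=RDConfig(bandwidth_policy=f"fixed:{h}"))
            assert res.estimate == pytest.approx(0.2, abs=1e-12)
            assert res.estimate_bc == pytest.approx(0.2, abs=1e-9)

    def test_left_limit(self):
        x = np.arange(-30, 30).astype(float)
        y = 0.3 - 0.004 * x + 0.1 * (x >= 0)
        res = rd_sharp(make_cohort(x, y), config=RDConfig(bandwidth_policy="fixed:25"))
        assert res.left_limit == pytest.approx(0.3, abs=1e-10)

    def test_covariate_adjustment_exact_on_additive_dgp(self):
        rng = np.random.default_rng(5)
        x = rng.integers(-40, 40, 300).astype(float)
        z = rng.normal(size=300)
        y = 0.1 + 0.003 * x + 0.25 * (x >= 0) + 0.5 * z
        df = make_cohort(x, y)
        df["z"] = z
        res = rd_sharp(df, config=RDConfig(bandwidth_policy="fixed:30", covariates=("z",)))
        assert res.estimate == pytest.approx(0.25, abs=1e-10)

    def test_collinear_covariate_named(self):
        x = np.arange(-20, 20).astype(float)
        df = make_cohort(x, x * 0.01)
        df["dup"] = df["eligible"].astype(float)
        with pytest.raises(EstimationError, match="dup"):
            rd_sharp(df, config=RDConfig(bandwidth_policy="fixed:15", covariates=("dup",)))

    def test_insufficient_support_names_side(self):
        x = np.array([-1.0, -1.0, 0.0, 1.0, 2.0, 3.0, 4.0])
        with pytest.raises(EstimationError, match="left"):
            rd_sharp(make_cohort(x, x * 0.1), config=RDConfig(bandwidth_policy="fixed:5"))


class TestInvariances:
    def _fit(self, x, y, h=20):
        return rd_sharp(make_cohort(x, y), config=RDConfig(bandwidth_policy=f"fixed:{h}"))

    def test_constant_shift_leaves_jump(self):
        rng = np.random.default_rng(7)
        x = rng.integers(-30, 30, 200).astype(float)
        y = rng.normal(0.3, 0.1, 200) + 0.1 * (x >= 0)
        r1, r2 = self._fit(x, y), self._fit(x, y + 7.0)
        assert r1.estimate == pytest.approx(r2.estimate, abs=1e-10)
        assert r1.se_robust == pytest.approx(r2.se_robust, rel=1e-8)

    def test_sign_flip_negates_jump(self):
        """Mirroring the running variable swaps the sides, so the jump
        (right minus left limit) changes sign; on a symmetric-support grid
        with ties broken identically the magnitudes agree closely."""
        rng = np.random.default_rng(8)
        x = np.concatenate([np.arange(-30, 0), np.arange(1, 31)]).astype(float)
        y = 0.2 + 0.004 * x + 0.12 * (x >= 0) + rng.normal(0, 0.01, x.size)
        r1 = self._fit(x, y)
        r2 = self._fit(-x, y)
        assert r2.estimate == pytest.approx(-r1.estimate, abs=0.02)

    def test_doubling_outcome_doubles_jump(self):
        x = np.arange(-25, 25).astype(float)
        y = 0.1 + 0.002 * x + 0.2 * (x >= 0)
        assert self._fit(x, 2 * y).estimate == pytest.approx(2 * self._fit(x, y).estimate,
                                                             abs=1e-10)


class TestFuzzy:
    def test_sharp_compliance_equals_itt(self):
        rng = np.random.default_rng(9)
        x = rng.integers(-30, 30, 400).astype(float)
        v = (x >= 0).astype(float)  # full uptake on the right, none left
        y = 0.2 + 0.003 * x - 0.1 * v + rng.normal(0, 0.05, 400)
        coh = make_cohort(x, y, v)
        cfg = RDConfig(bandwidth_policy="fixed:25")
        fz = rd_fuzzy(coh, config=cfg)
        sh = rd_sharp(coh, config=cfg)
        assert fz.estimate == pytest.approx(sh.estimate, abs=1e-10)
        assert fz.first_stage_jump == pytest.approx(1.0, abs=1e-10)

    def test_wald_identity(self):
        """Fuzzy estimate times first stage equals the ITT, exactly."""
        rng = np.random.default_rng(10)
        x = rng.integers(-40, 40, 600).astype(float)
        v = (rng.uniform(size=600) < 0.5 * (x >= 0)).astype(float)
        y = 0.3 + 0.002 * x - 0.04 * v + rng.normal(0, 0.05, 600)
        coh = make_cohort(x, y, v)
        cfg = RDConfig(bandwidth_policy="fixed:30")
        fz = rd_fuzzy(coh, config=cfg)
        sh = rd_sharp(coh, config=cfg)
        assert fz.estimate * fz.first_stage_jump == pytest.approx(sh.estimate, abs=1e-10)

    def test_constructed_ratio(self):
        """Noiseless Wald arithmetic: ITT -0.01 over first stage 0.5 gives -0.02."""
        x = np.repeat(np.arange(-20, 20), 4).astype(float)
        d = (x >= 0)
        v = np.where(d, np.tile([1.0, 1.0, 0.0, 0.0], 40)[: x.size], 0.0)
        v = v * d  # exactly 0.5 uptake right of the threshold
        y = 0.2 - 0.02 * v
        fz = rd_fuzzy(make_cohort(x, y, v), config=RDConfig(bandwidth_policy="fixed:15"))
        assert fz.first_stage_jump == pytest.approx(0.5, abs=1e-10)
        assert fz.estimate == pytest.approx(-0.02, abs=1e-10)

    def test_weak_instrument_error(self):
        rng = np.random.default_rng(11)
        x = rng.integers(-30, 30, 300).astype(float)
        v = np.full(300, 0.3)  # receipt probability without any discontinuity
        y = rng.normal(0.2, 0.05, 300)
        with pytest.raises(WeakInstrumentError):
            rd_fuzzy(make_cohort(x, y, v), config=RDConfig(bandwidth_policy="fixed:25"))


# ---------------------------------------------------------------------------
# bandwidth selection
# ---------------------------------------------------------------------------

def reference_bandwidths(x, y, p=1):
    """Independent implementation of the same plug-in formulas, using
    numerically integrated kernel constants and numpy polynomial fits."""
    import math

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size

    def consts(nu, order):
        m = order + 1
        K = lambda u: 1 - u
        G = np.array([[integrate.quad(lambda u: u ** (j + k) * K(u), 0, 1)[0]
                       for k in range(m)] for j in range(m)])
        th = np.array([integrate.quad(lambda u: u ** (j + order + 1) * K(u), 0, 1)[0]
                       for j in range(m)])
        P = np.array([[integrate.quad(lambda u: u ** (j + k) * K(u) ** 2, 0, 1)[0]
                       for k in range(m)] for j in range(m)])
        gi = np.linalg.inv(G)
        return (gi @ th)[nu], (gi @ P @ gi)[nu, nu]

    sx = np.std(x)
    h1 = 1.84 * sx * n ** -0.2
    near = np.abs(x) <= h1
    fhat = near.sum() / (2 * h1 * n)
    s2l = np.var(y[near & (x < 0)])
    s2r = np.var(y[near & (x >= 0)])

    def deriv(xs, ys, order, k):
        poly = np.polynomial.Polynomial.fit(xs, ys, order).convert()
        return poly.deriv(k)(0.0)

    xl, yl, xr, yr = x[x < 0], y[x < 0], x[x >= 0], y[x >= 0]
    m3l, m3r = deriv(xl, yl, 3, 3), deriv(xr, yr, 3, 3)
    h2l = 3.56 * (s2l / (fhat * max(m3l**2, 1e-30))) ** (1 / 7) * len(xl) ** (-1 / 7)
    h2r = 3.56 * (s2r / (fhat * max(m3r**2, 1e-30))) ** (1 / 7) * len(xr) ** (-1 / 7)
    h2l = min(h2l, np.abs(xl).max())
    h2r = min(h2r, np.abs(xr).max())
    ml = xl[np.abs(xl) <= h2l]
    mr = xr[np.abs(xr) <= h2r]
    m2l = deriv(ml, yl[np.abs(xl) <= h2l], 2, 2)
    m2r = deriv(mr, yr[np.abs(xr) <= h2r], 2, 2)
    rl = 2160 * s2l / (len(ml) * h2l**4)
    rr = 2160 * s2r / (len(mr) * h2r**4)
    B, V = consts(0, p)
    num = V * (s2l + s2r) / fhat
    den = 4 * (B / math.factorial(p + 1)) ** 2 * ((m2r - m2l) ** 2 + rl + rr)
    return (num / den) ** (1 / (2 * p + 3)) * n ** (-1 / (2 * p + 3))


@pytest.fixture(scope="module")
def benchmark_xy():
    rng = np.random.default_rng(123)
    n = 40_000
    x = rng.integers(-400, 400, n).astype(float)
    p = 1 / (1 + np.exp(2.5 + 0.0013 * x + 2e-6 * x**2))
    y = (rng.uniform(size=n) < p).astype(float)
    return x, y


class TestBandwidth:
    def test_matches_reference_implementation(self, benchmark_xy):
        """Plug-in h agrees with an independently coded route within 2%."""
        x, y = benchmark_xy
        h, _ = select_bandwidth_mse(make_cohort(x, y))
        href = reference_bandwidths(x, y)
        assert abs(h - href) / href < 0.02

    def test_scale_equivariance(self, benchmark_xy):
        x, y = benchmark_xy
        h1, b1 = select_bandwidth_mse(make_cohort(x, y))
        h2, b2 = select_bandwidth_mse(make_cohort(2.5 * x, y))
        assert h2 / h1 == pytest.approx(2.5, rel=1e-6)
        assert b2 / b1 == pytest.approx(2.5, rel=1e-6)

    def test_rate_in_n(self):
        """Tenfold data shrinks h by about n^(-1/5) under asymmetric curvature."""
        rng = np.random.default_rng(42)
        ratios = []
        for _ in range(3):
            hs = {}
            for n in (20_000, 200_000):
                x = rng.uniform(-1, 1, n)
                y = np.where(x < 0, 0.5 * x**2, -0.5 * x**2) + rng.normal(0, 0.2, n)
                hs[n], _ = select_bandwidth_mse(make_cohort(x, y))
            ratios.append(hs[200_000] / hs[20_000])
        assert np.mean(ratios) == pytest.approx(10 ** (-1 / 5), abs=0.04)

    def test_bias_bandwidth_not_smaller_than_h(self, benchmark_xy):
        x, y = benchmark_xy
        h, b = select_bandwidth_mse(make_cohort(x, y))
        assert b >= h

    def test_floor_per_side(self):
        x = np.concatenate([np.full(30, -5.0), np.arange(100)]).astype(float)
        with pytest.raises(EstimationError, match="per side"):
            select_bandwidth_mse(make_cohort(x, np.zeros_like(x)))


# ---------------------------------------------------------------------------
# robust bias-corrected inference
# ---------------------------------------------------------------------------

def simulate_coverage(curved, n_reps=300, n=8000, h=150, true_jump=0.08, seed=77):
    rng = np.random.default_rng(seed)
    conv_cover = rob_cover = 0
    for _ in range(n_reps):
        x = rng.integers(-300, 300, n).astype(float)
        m = 0.3 + 0.0003 * x + true_jump * (x >= 0)
        if curved:
            m = m + np.where(x < 0, 1.2e-5 * x**2, 0.0)
        y = (rng.uniform(size=n) < m).astype(float)
        res = rd_sharp(make_cohort(x, y), config=RDConfig(bandwidth_policy=f"fixed:{h}"))
        z = 1.959963984540054
        lo_c = res.estimate - z * res.se_conventional
        hi_c = res.estimate + z * res.se_conventional
        conv_cover += lo_c <= true_jump <= hi_c
        rob_cover += res.ci_robust[0] <= true_jump <= res.ci_robust[1]
    return conv_cover / n_reps, rob_cover / n_reps


class TestRobustInference:
    def test_linear_dgp_bias_correction_inert(self):
        rng = np.random.default_rng(13)
        x = rng.integers(-100, 100, 5000).astype(float)
        y = 0.3 + 0.001 * x + 0.05 * (x >= 0) + rng.normal(0, 0.1, 5000)
        res = rd_sharp(make_cohort(x, y), config=RDConfig(bandwidth_policy="fixed:80"))
        assert abs(res.estimate - res.estimate_bc) < 2 * res.se_conventional
        assert res.se_robust >= 0.8 * res.se_conventional

    def test_null_coverage_nominal(self):
        _, rob = simulate_coverage(curved=False, true_jump=0.0, n_reps=250, seed=55)
        assert abs(rob - 0.95) <= 3 * np.sqrt(0.95 * 0.05 / 250)

    def test_curvature_restores_coverage(self):
        """Under one-sided curvature the conventional interval under-covers;
        the bias-corrected robust interval restores the nominal level."""
        conv, rob = simulate_coverage(curved=True, n_reps=250, seed=66)
        tol = 3 * np.sqrt(0.95 * 0.05 / 250)
        assert conv < 0.95 - tol
        assert abs(rob - 0.95) <= tol

    @pytest.mark.parametrize("mode", ["hc0", "hc1", "hc3", "nearest_neighbor",
                                      "cluster_by_week"])
    def test_variance_estimators_agree_in_order(self, mode):
        rng = np.random.default_rng(14)
        x = rng.integers(-60, 60, 4000).astype(float)
        y = (rng.uniform(size=4000) < 0.3 + 0.1 * (x >= 0)).astype(float)
        base = rd_sharp(make_cohort(x, y),
                        config=RDConfig(bandwidth_policy="fixed:50"))
        alt = rd_sharp(make_cohort(x, y),
                       config=RDConfig(bandwidth_policy="fixed:50",
                                       variance_estimator=mode))
        assert 0.5 < alt.se_robust / base.se_robust < 2.0
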