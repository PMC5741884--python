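"""Cascade reduction, binomial CIs and random-intercept pooling.

The Clopper-Pearson checks use a brute-force inversion of the binomial CDF
(bisection on the tail probabilities) as the oracle, and the GLMM check uses
a dense-grid + polish maximisation of the marginal likelihood computed with
scipy.integrate.quad — both fully independent of the implementation paths
they validate.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, optimize, stats
from scipy.special import expit

from popimpact import (
    CascadeError,
    RecruitmentCascade,
    RecruitmentLevel,
    SimScenario,
    binomial_ci,
    cascade_uptake,
    marginal_mean,
    pool_uptake_glmm,
    simulate_recruitment,
    single_trial_uptake,
)
from conftest import make_cascade


class TestCascadeUptake:
    def test_nested_practice_then_gp(self, delayed_cascade):
        prop, num, eff = cascade_uptake(delayed_cascade)
        assert prop == pytest.approx((22 / 61) * (48 / 92), rel=1e-15)
        assert num == 48
        assert eff == pytest.approx(92 * 61 / 22, rel=1e-15)
        assert round(eff) == 255
        # the unrounded denominator reproduces the proportion exactly
        assert prop == pytest.approx(num / eff, rel=1e-15)

    def test_single_level(self):
        prop, num, eff = cascade_uptake(make_cascade("pct", 53, 345))
        assert prop == pytest.approx(53 / 345, rel=1e-15)
        assert (num, eff) == (53, 345)

    def test_full_participation(self):
        prop, num, eff = cascade_uptake(make_cascade("t", 40, 40))
        assert prop == 1.0

    def test_zero_outer_participation_undefined(self):
        c = RecruitmentCascade(
            "t", "iv",
            (RecruitmentLevel("practice", 0, 10), RecruitmentLevel("gp", 3, 5)),
        )
        with pytest.raises(CascadeError, match="practice"):
            cascade_uptake(c)

    @settings(max_examples=50, deadline=None)
    @given(
        x1=st.integers(1, 50), n1_extra=st.integers(0, 50),
        x2=st.integers(1, 80), n2_extra=st.integers(0, 40),
        full=st.integers(1, 200), pos=st.integers(0, 2),
    )
    def test_full_participation_level_is_neutral(self, x1, n1_extra, x2, n2_extra,
                                                 full, pos):
        """Inserting an (n, n) level anywhere leaves the uptake unchanged."""
        levels = [RecruitmentLevel("a", x1, x1 + n1_extra),
                  RecruitmentLevel("b", x2, x2 + n2_extra)]
        base = RecruitmentCascade("t", "iv", tuple(levels))
        levels.insert(pos, RecruitmentLevel("neutral", full, full))
        augmented = RecruitmentCascade("t", "iv", tuple(levels))
        assert cascade_uptake(augmented)[0] == pytest.approx(
            cascade_uptake(base)[0], rel=1e-12
        )


def clopper_pearson_oracle(x, n, level=0.95, tol=1e-10):
    """Invert the binomial tail probabilities by bisection: the lower bound
    solves P(X >= x | p) = alpha/2, the upper solves P(X <= x | p) = alpha/2."""
    alpha = 1 - level

    def bisect(f, increasing):
        # find p in (0,1) with f(p) = alpha/2
        lo, hi = 0.0, 1.0
        while hi - lo > tol:
            mid = (lo + hi) / 2
            if (f(mid) < alpha / 2) == increasing:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    lower = 0.0 if x == 0 else bisect(lambda p: stats.binom.sf(x - 1, n, p),
                                      increasing=True)
    upper = 1.0 if x == n else bisect(lambda p: stats.binom.cdf(x, n, p),
                                      increasing=False)
    return lower, upper


class TestBinomialCI:
    def test_delayed_prescribing_interval_matches_oracle(self):
        lo, hi = binomial_ci(48, 255, 0.95, "clopper_pearson")
        olo, ohi = clopper_pearson_oracle(48, 255)
        assert lo == pytest.approx(olo, abs=1e-6)
        assert hi == pytest.approx(ohi, abs=1e-6)
        assert (round(100 * lo), round(100 * hi)) == (14, 24)

    def test_zero_numerator_floors_at_zero(self):
        lo, hi = binomial_ci(0, 10, 0.95, "clopper_pearson")
        assert lo == 0.0
        assert 0 < hi < 1

    @pytest.mark.parametrize("method", ["clopper_pearson", "wilson", "wald"])
    def test_all_methods_bracket_point(self, method):
        lo, hi = binomial_ci(35, 125, 0.95, method)
        assert lo < 35 / 125 < hi

    def test_width_ordering_at_moderate_n(self):
        # checked empirically rather than assumed: the exact (CP) interval is
        # the widest of the three here, and Wald is in fact slightly wider
        # than Wilson at 35/125 — no Wald <= Wilson ordering is asserted
        widths = {
            m: np.diff(binomial_ci(35, 125, 0.95, m))[0]
            for m in ("wald", "wilson", "clopper_pearson")
        }
        assert widths["wilson"] <= widths["clopper_pearson"]
        assert widths["wald"] <= widths["clopper_pearson"]

    @pytest.mark.parametrize("n", [10, 23, 30])
    @pytest.mark.parametrize("p", [0.1, 0.3, 0.5])
    def test_clopper_pearson_attains_nominal_coverage(self, n, p):
        """Exhaustive (non-sampled) coverage over all outcomes x = 0..n."""
        coverage = sum(
            stats.binom.pmf(x, n, p)
            for x in range(n + 1)
            if binomial_ci(x, n, 0.95)[0] <= p <= binomial_ci(x, n, 0.95)[1]
        )
        assert coverage >= 0.95

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown CI method"):
            binomial_ci(1, 2, method="exactish")


def glmm_quad_oracle(x, n, span=2.0, steps=41):
    """Independent maximiser of the marginal likelihood: per-observation
    integrals by scipy.integrate.quad, coarse grid then Nelder-Mead polish."""
    x, n = np.asarray(x, float), np.asarray(n, float)

    def nll(theta):
        b0, s = theta
        s = abs(s)
        total = 0.0
        for xj, nj in zip(x, n):
            def integrand(z):
                eta = b0 + s * z
                ll = xj * eta - nj * np.logaddexp(0, eta)
                return math.exp(ll - ref) * stats.norm.pdf(z)

            ref = xj * math.log(max(xj / nj, 1e-12)) + (nj - xj) * math.log(
                max(1 - xj / nj, 1e-12)
            )
            val, _ = integrate.quad(integrand, -8, 8, limit=200)
            total += math.log(val) + ref
        return -total

    p0 = math.log(x.sum() / (n.sum() - x.sum()))
    grid = [
        (b, s)
        for b in np.linspace(p0 - span, p0 + span, steps)
        for s in np.linspace(0.0, 2.0, steps)
    ]
    start = min(grid, key=nll)
    res = optimize.minimize(nll, start, method="Nelder-Mead",
                            options=dict(xatol=1e-7, fatol=1e-9))
    return float(res.x[0]), abs(float(res.x[1]))


class TestGlmmPooling:
    def test_no_between_trial_variation_hits_boundary(self):
        cs = [make_cascade(t, 30, 100) for t in "abc"]
        est, fit = pool_uptake_glmm(cs)
        assert fit.sigma == 0.0
        assert fit.boundary
        assert est.proportion == pytest.approx(0.30, abs=1e-6)

    def test_reconstructed_sdm_counts_match_quad_oracle(self):
        counts = [(45, 345), (101, 2036), (135, 1008)]
        cs = [make_cascade(f"t{i}", x, n) for i, (x, n) in enumerate(counts)]
        est, fit = pool_uptake_glmm(cs)
        b0, s = glmm_quad_oracle([c[0] for c in counts], [c[1] for c in counts])
        assert fit.beta0 == pytest.approx(b0, abs=1e-3)
        assert fit.sigma == pytest.approx(s, abs=1e-3)
        assert est.proportion == pytest.approx(marginal_mean(b0, s), abs=1e-4)
        assert est.numerator == 281
        assert est.effective_denominator == 3389
        assert est.ci[0] >= 0.0

    def test_sigma_fixed_at_zero_reproduces_pooled_binomial(self):
        cs = [make_cascade("a", 45, 345), make_cascade("b", 101, 2036),
              make_cascade("c", 135, 1008)]
        est, fit = pool_uptake_glmm(cs, fix_sigma=0.0)
        pooled = (45 + 101 + 135) / (345 + 2036 + 1008)
        assert est.proportion == pytest.approx(pooled, abs=1e-8)
        assert fit.beta0 == pytest.approx(math.log(pooled / (1 - pooled)), abs=1e-6)

    def test_single_cascade_directs_to_binomial_path(self):
        with pytest.raises(ValueError, match="single"):
            pool_uptake_glmm([make_cascade("a", 30, 100)])

    def test_non_population_based_excluded(self):
        cs = [make_cascade("a", 30, 100), make_cascade("b", 40, 100),
              make_cascade("c", 90, 100, population_based=False)]
        est, _ = pool_uptake_glmm(cs)
        assert est.numerator == 70
        assert est.effective_denominator == 200

    def test_parameter_recovery_on_synthetic_cascades(self):
        """50 single-level trials of n = 300 drawn at beta0 = -1.8, sigma = 0.5
        recover beta0 within 0.15 and sigma within 0.2."""
        s = SimScenario(
            trials_per_intervention=50, uptake_beta0=-1.8, uptake_sigma=0.5,
            practices_approached_range=(300, 300),
            clinicians_per_practice_range=None, seed=77,
        )
        est, fit = pool_uptake_glmm(simulate_recruitment(s))
        assert abs(fit.beta0 - (-1.8)) < 0.15
        assert abs(fit.sigma - 0.5) < 0.2
        assert fit.converged


class TestSingleTrialUptake:
    def test_delayed_prescribing_estimate(self, delayed_cascade):
        est = single_trial_uptake(delayed_cascade)
        assert est.numerator == 48
        assert est.effective_denominator == 255
        assert round(100 * est.proportion) == 19
        assert est.method == "single_trial"
        assert est.ci[0] <= est.proportion <= est.ci[1]
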