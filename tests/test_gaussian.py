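"""Known-variance z-test machinery: significance testing and NP design."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pcalib import (
    MeanTestSpec,
    critical_value,
    np_decide,
    np_design,
    p_two_sided,
    p_value,
    power,
    required_n,
    required_n_continuous,
    sampling_sd,
    significance_test,
    tail_probability,
    z_statistic,
)


class TestSamplingDistribution:
    def test_painkiller_standard_error_is_two(self, painkiller):
        assert sampling_sd(painkiller) == pytest.approx(2.0)

    @pytest.mark.parametrize(
        "sigma2, n, expected",
        [(1.0, 1, 1.0), (200.0, 200, 1.0), (4.0, 16, 0.5)],
    )
    def test_sqrt_sigma2_over_n(self, sigma2, n, expected):
        assert sampling_sd(MeanTestSpec(0.0, sigma2, n)) == pytest.approx(expected)

    def test_spec_validation(self):
        with pytest.raises(ValueError, match="sigma2"):
            MeanTestSpec(0.0, -1.0, 10)
        with pytest.raises(ValueError, match="n"):
            MeanTestSpec(0.0, 1.0, 0)


class TestSignificanceTest:
    @pytest.mark.parametrize(
        "xbar, z, p",
        [(26.0, 1.0, 0.3173), (28.0, 2.0, 0.0455), (24.0, 0.0, 1.0)],
    )
    def test_painkiller_worked_example(self, painkiller, xbar, z, p):
        assert z_statistic(painkiller, xbar) == pytest.approx(z)
        assert p_two_sided(z_statistic(painkiller, xbar)) == pytest.approx(p, abs=5e-5)
        res = significance_test(painkiller, xbar)
        assert res.z == pytest.approx(z) and res.p == pytest.approx(p, abs=5e-5)

    def test_one_sided_variants_halve_the_symmetric_case(self):
        assert p_value(1.0, "greater") == pytest.approx(p_two_sided(1.0) / 2)
        assert p_value(-1.0, "less") == pytest.approx(p_two_sided(1.0) / 2)
        with pytest.raises(ValueError, match="sided"):
            p_value(1.0, "both")

    def test_nonfinite_z_rejected(self):
        for bad in (float("inf"), float("nan")):
            with pytest.raises(ValueError):
                p_two_sided(bad)

    def test_tail_probability_worked_example(self, painkiller):
        assert tail_probability(painkiller, 20.0, 28.0) == pytest.approx(
            0.0455, abs=5e-5
        )
        assert tail_probability(painkiller, 22.0, 26.0) == pytest.approx(
            0.3173, abs=5e-5
        )

    def test_tail_probability_symmetric_interval_equals_two_sided_p(self, painkiller):
        sd = sampling_sd(painkiller)
        for k in (0.5, 1.0, 1.96, 3.0):
            assert tail_probability(
                painkiller, painkiller.mu0 - k * sd, painkiller.mu0 + k * sd
            ) == pytest.approx(p_two_sided(k), abs=1e-12)

    def test_tail_probability_rejects_degenerate_interval(self, painkiller):
        with pytest.raises(ValueError, match="low < high"):
            tail_probability(painkiller, 28.0, 20.0)


class TestCriticalValue:
    def test_conventional_value(self):
        assert critical_value(0.05) == pytest.approx(1.96, abs=5e-3)

    def test_stringent_value_against_bisection_oracle(self):
        # independent inversion of Phi by bisection
        lo, hi = 0.0, 10.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if 2 * stats.norm.sf(mid) > 0.005:
                lo = mid
            else:
                hi = mid
        assert critical_value(0.005) == pytest.approx((lo + hi) / 2, abs=1e-9)
        assert critical_value(0.005) == pytest.approx(2.807, abs=5e-4)

    def test_degenerate_alpha_one(self):
        assert critical_value(1.0) == 0.0

    @pytest.mark.parametrize("alpha", [0.0, -0.1, 1.1])
    def test_domain(self, alpha):
        with pytest.raises(ValueError, match="alpha"):
            critical_value(alpha)

    @pytest.mark.parametrize("alpha", [0.2, 0.1, 0.05, 0.01, 0.005, 0.001])
    def test_mutual_inverse_with_two_sided_p(self, alpha):
        assert p_two_sided(critical_value(alpha)) == pytest.approx(alpha, abs=1e-10)


class TestNPDecision:
    def test_painkiller_decisions(self, painkiller):
        assert np_decide(painkiller, 26.0, 0.05) == "accept"
        assert np_decide(painkiller, 28.0, 0.05) == "reject"
        assert np_decide(painkiller, 24.0, 0.2) == "accept"

    def test_boundary_tie_accepts(self):
        # z lands exactly on the critical value: strict inequality -> accept
        spec = MeanTestSpec(mu0=0.0, sigma2=1.0, n=1)
        c = critical_value(0.05)
        assert np_decide(spec, c, 0.05) == "accept"
        assert np_decide(spec, np.nextafter(c, 2.0), 0.05) == "reject"

    @given(
        xbar=st.floats(-50, 100),
        alpha=st.sampled_from([0.2, 0.1, 0.05, 0.01, 0.001]),
    )
    @settings(derandomize=True, max_examples=300)
    def test_p_below_alpha_iff_np_rejects(self, xbar, alpha):
        """Fisher's p < alpha and the NP rejection region agree off the boundary."""
        spec = MeanTestSpec(mu0=24.0, sigma2=200.0, n=50)
        p = p_two_sided(z_statistic(spec, xbar))
        if abs(p - alpha) < 1e-12:
            return
        assert (p < alpha) == (np_decide(spec, xbar, alpha) == "reject")


class TestPower:
    def test_painkiller_power_at_28(self, painkiller):
        assert power(painkiller, 28.0, 0.05) == pytest.approx(0.516, abs=1e-3)

    def test_monte_carlo_cross_check(self, painkiller):
        """Brute-force power: simulate the test under the alternative mean."""
        rng = np.random.default_rng(20260924)
        n_sim = 1_000_000
        sd = sampling_sd(painkiller)
        xbars = rng.normal(28.0, sd, n_sim)
        rejected = np.abs((xbars - painkiller.mu0) / sd) > critical_value(0.05)
        mc = rejected.mean()
        se = math.sqrt(mc * (1 - mc) / n_sim)
        assert power(painkiller, 28.0, 0.05) == pytest.approx(mc, abs=3 * se)

    def test_power_at_the_null_equals_alpha(self, painkiller):
        for alpha in (0.2, 0.05, 0.005):
            assert power(painkiller, painkiller.mu0, alpha) == pytest.approx(
                alpha, abs=1e-12
            )

    def test_power_tends_to_one_for_huge_effects(self, painkiller):
        assert power(painkiller, 1000.0, 0.05) == pytest.approx(1.0, abs=1e-12)

    def test_strictly_increasing_in_effect_n_and_alpha(self):
        spec = lambda n: MeanTestSpec(0.0, 100.0, n)
        effects = [1.0, 2.0, 3.0, 5.0]
        pws = [power(spec(30), e, 0.05) for e in effects]
        assert all(a < b for a, b in zip(pws, pws[1:]))
        ns = [10, 20, 40, 80]
        pws = [power(spec(n), 2.0, 0.05) for n in ns]
        assert all(a < b for a, b in zip(pws, pws[1:]))
        alphas = [0.001, 0.01, 0.05, 0.2]
        pws = [power(spec(30), 2.0, a) for a in alphas]
        assert all(a < b for a, b in zip(pws, pws[1:]))

    def test_np_design_assembles_beta(self, painkiller):
        d = np_design(painkiller, 28.0, 0.05)
        assert d.beta == pytest.approx(1.0 - d.power)
        assert d.critical_z == pytest.approx(1.96, abs=5e-3)


class TestRequiredN:
    def test_worked_example(self):
        # closed form 200*(1.959964+0.841621)^2/16 = 98.1 -> exact search
        n = required_n(4.0, 200.0, 0.05, 0.8)
        assert n == 99
        assert required_n_continuous(4.0, 200.0, 0.05, 0.8) == pytest.approx(
            98.1, abs=0.05
        )

    def test_stringent_alpha_needs_seventy_percent_more(self):
        ratio = required_n_continuous(4.0, 200.0, 0.005, 0.8) / required_n_continuous(
            4.0, 200.0, 0.05, 0.8
        )
        assert round(ratio, 2) == 1.70
        # ratio is scale-free: the same at any effect/variance
        ratio2 = required_n_continuous(1.0, 1.0, 0.005, 0.8) / required_n_continuous(
            1.0, 1.0, 0.05, 0.8
        )
        assert ratio2 == pytest.approx(ratio, abs=1e-12)

    @pytest.mark.parametrize(
        "effect, sigma2, alpha, target",
        [
            (4.0, 200.0, 0.05, 0.8),
            (4.0, 200.0, 0.005, 0.8),
            (1.0, 10.0, 0.05, 0.9),
            (2.5, 50.0, 0.01, 0.5),
            (3.0, 5.0, 0.05, 0.1),
        ],
    )
    def test_returns_the_exact_integer_minimum(self, effect, sigma2, alpha, target):
        n = required_n(effect, sigma2, alpha, target)
        pw = lambda m: power(MeanTestSpec(0.0, sigma2, m), effect, alpha)
        assert pw(n) >= target
        assert n == 1 or pw(n - 1) < target

    def test_degenerate_low_target_still_satisfied(self):
        n = required_n(1.0, 1.0, 0.05, 0.06)
        assert power(MeanTestSpec(0.0, 1.0, n), 1.0, 0.05) >= 0.06

    def test_zero_effect_rejected(self):
        with pytest.raises(ValueError, match="effect"):
            required_n(0.0, 1.0, 0.05, 0.8)
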