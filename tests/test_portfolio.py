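"""Parallel-programme sizing and hypergeometric target sampling."""

import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from targetodds.portfolio import (
    PortfolioSpec,
    causal_in_sample_pmf,
    development_success_prob,
    expected_causal_in_sample,
    expected_true_vs_false_positives,
    n_programmes_exact,
    n_programmes_needed,
    tp_fp_breakeven_frame,
)
from targetodds.simulate import SimulationConfig, simulate_portfolio


class TestProgrammesNeeded:
    def test_ninety_percent_chance_needs_114(self):
        assert n_programmes_needed(0.02, 0.9) == 114

    def test_evens_chance_reported_as_34(self):
        """The 'on average' rounding of the crossing point gives 34; the
        strict guarantee needs one more programme."""
        assert n_programmes_needed(0.02, 0.5, rule="round") == 34
        assert n_programmes_needed(0.02, 0.5, rule="ceil") == 35

    def test_near_certain_programme(self):
        assert n_programmes_needed(0.99, 0.9) == 1

    def test_zero_success_rate_rejected(self):
        with pytest.raises(ValueError):
            n_programmes_needed(0.0, 0.9)

    @given(p=st.floats(1e-4, 0.999), c=st.floats(1e-4, 0.999))
    @settings(max_examples=200, derandomize=True)
    def test_guarantee_rule_is_exact_threshold(self, p, c):
        n = n_programmes_needed(p, c, rule="ceil")
        assert 1.0 - (1.0 - p) ** n >= c - 1e-12
        if n > 1:
            assert 1.0 - (1.0 - p) ** (n - 1) < c + 1e-12

    @given(
        p1=st.floats(1e-3, 0.99), p2=st.floats(1e-3, 0.99),
        c1=st.floats(1e-3, 0.99), c2=st.floats(1e-3, 0.99),
    )
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_success_rate_and_confidence(self, p1, p2, c1, c2):
        lo_p, hi_p = sorted((p1, p2))
        lo_c, hi_c = sorted((c1, c2))
        assert n_programmes_needed(hi_p, lo_c) <= n_programmes_needed(lo_p, lo_c)
        assert n_programmes_needed(lo_p, hi_c) >= n_programmes_needed(lo_p, lo_c)


class TestCausalInSample:
    def test_matches_sequential_avoidance_product(self):
        """P(no causal target drawn) equals the direct product
        prod (3980-i)/(4000-i) over the 20 draws."""
        spec = PortfolioSpec(frame_size=4000, n_causal_in_frame=20, n_programmes=20)
        brute = math.prod((3980 - i) / (4000 - i) for i in range(20))
        assert causal_in_sample_pmf(spec, 0) == pytest.approx(brute, rel=1e-12)

    def test_pmf_normalises_at_scale(self):
        spec = PortfolioSpec(frame_size=4000, n_causal_in_frame=20, n_programmes=200)
        a = np.arange(0, 21)
        assert causal_in_sample_pmf(spec, a).sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_causal_frame(self):
        spec = PortfolioSpec(frame_size=20, n_causal_in_frame=20, n_programmes=5)
        assert causal_in_sample_pmf(spec, 5) == pytest.approx(1.0)

    @pytest.mark.parametrize("frame, c, n", [(10, 4, 5), (8, 8, 3), (12, 0, 6)])
    def test_matches_exhaustive_enumeration(self, frame, c, n):
        """For small frames the pmf equals counting subsets directly."""
        spec = PortfolioSpec(frame_size=frame, n_causal_in_frame=c, n_programmes=n)
        counts = {}
        for subset in combinations(range(frame), n):
            a = sum(1 for g in subset if g < c)
            counts[a] = counts.get(a, 0) + 1
        total = math.comb(frame, n)
        for a in range(n + 1):
            assert causal_in_sample_pmf(spec, a) == pytest.approx(
                counts.get(a, 0) / total, abs=1e-12
            )

    @pytest.mark.parametrize(
        "n, mean, sd",
        [(200, 1.0, None), (4000, 20.0, 0.0), (50, 0.25, None)],
    )
    def test_expected_value_and_sd(self, n, mean, sd):
        spec = PortfolioSpec(frame_size=4000, n_causal_in_frame=20, n_programmes=n)
        m, s = expected_causal_in_sample(spec)
        assert m == pytest.approx(mean)
        if sd is not None:
            assert s == pytest.approx(sd, abs=1e-12)
        else:
            # cross-check the finite-population SD against exact pmf moments
            a = np.arange(0, 21)
            pmf = causal_in_sample_pmf(spec, a)
            var = float((pmf * (a - m) ** 2).sum())
            assert s == pytest.approx(math.sqrt(var), rel=1e-9)


class TestDevelopmentSuccess:
    def test_all_causal_perfect_power(self):
        spec = PortfolioSpec(frame_size=20, n_causal_in_frame=20, n_programmes=10)
        assert development_success_prob(spec, alpha=0.05, beta=0.0) == pytest.approx(1.0)

    def test_nothing_causal(self):
        spec = PortfolioSpec(frame_size=4000, n_causal_in_frame=0, n_programmes=50)
        assert development_success_prob(spec, alpha=0.05, beta=0.2) == 0.0

    def test_base_scenario_matches_frozen_monte_carlo_oracle(self):
        """Reference value 0.069607 (SE 0.000254) from a 10^6-replicate
        draw-test-advance simulation of the same scenario."""
        spec = PortfolioSpec(frame_size=4000, n_causal_in_frame=20, n_programmes=50)
        exact = development_success_prob(spec, alpha=0.05, beta=0.2)
        assert abs(exact - 0.069607) < 3 * 0.000254

    @pytest.mark.parametrize(
        "frame, c, n",
        [(400, 20, 40), (1000, 20, 100), (4000, 20, 200), (100, 5, 30), (50, 40, 10)],
    )
    def test_agrees_with_simulator(self, frame, c, n):
        spec = PortfolioSpec(frame_size=frame, n_causal_in_frame=c, n_programmes=n)
        exact = development_success_prob(spec, alpha=0.05, beta=0.2)
        mc = simulate_portfolio(
            spec, 0.05, 0.2, SimulationConfig(replicates=200_000, seed=11)
        )
        assert mc.within(exact, 3.0)

    def test_more_causal_targets_never_hurt(self):
        vals = [
            development_success_prob(
                PortfolioSpec(frame_size=400, n_causal_in_frame=c, n_programmes=50),
                0.05,
                0.2,
            )
            for c in (0, 5, 20, 50)
        ]
        assert vals == sorted(vals)


class TestExpectedPositives:
    def test_large_frame_false_positives_dominate(self):
        spec = PortfolioSpec(frame_size=4000, n_causal_in_frame=20, n_programmes=200)
        e_tp, e_fp = expected_true_vs_false_positives(spec, 0.05, 0.2)
        assert e_tp == pytest.approx(0.8)
        assert e_fp == pytest.approx(9.95)

    def test_breakeven_frame_is_under_400(self):
        """True positives outnumber false ones only below ~340 candidates
        (with 20 causal targets, alpha 0.05, power 0.8)."""
        f_star = tp_fp_breakeven_frame(20, 0.05, 0.2)
        assert f_star == pytest.approx(340.0)
        assert f_star < 400
        spec = PortfolioSpec(frame_size=400, n_causal_in_frame=20, n_programmes=400)
        e_tp, e_fp = expected_true_vs_false_positives(spec, 0.05, 0.2)
        assert e_tp == pytest.approx(16.0)
        assert e_fp == pytest.approx(19.0)
        assert not e_tp > e_fp

    def test_zero_alpha_means_no_false_positives(self):
        spec = PortfolioSpec(frame_size=4000, n_causal_in_frame=20, n_programmes=50)
        assert expected_true_vs_false_positives(spec, 0.0, 0.2)[1] == 0.0
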