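import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonex.placement import (ExclusivityData, ShiftParams, SmoothingParams,
                              _exact_table, llr_placement, loglik_null,
                              min_possible_p, p_chisq, p_exact, p_monte_carlo,
                              shift_rate)

PARAMS = ShiftParams()


class TestShiftRate:
    def test_reported_effect_sizes(self):
        # a shift of -4 from the mean null rate 0.40 reaches 97% exclusivity,
        # a shift of -3 reaches 93%
        assert round(shift_rate(0.40, -4.0), 2) == 0.97
        assert round(shift_rate(0.40, -3.0), 2) == 0.93

    def test_identity_and_fixed_points(self):
        assert shift_rate(0.37, 0.0) == pytest.approx(0.37)
        assert shift_rate(0.0, -5.0) == 0.0
        assert shift_rate(1.0, 7.0) == 1.0

    def test_inverse(self):
        r = shift_rate(shift_rate(0.3, -2.5), 2.5)
        assert r == pytest.approx(0.3)


class TestLoglikNull:
    def test_single_bernoulli(self):
        d = ExclusivityData(np.array([0.5]), np.array([1.0]))
        assert loglik_null(d) == pytest.approx(math.log(0.5))

    def test_fractional_outcomes_entropy(self):
        r = np.array([0.2, 0.6, 0.9])
        d = ExclusivityData(r, r.copy())
        expected = float(np.sum(r * np.log(r) + (1 - r) * np.log(1 - r)))
        assert loglik_null(d) == pytest.approx(expected)

    def test_empty_is_zero(self):
        assert loglik_null(ExclusivityData(np.array([]), np.array([]))) == 0.0

    def test_boundary_rate_rejected(self):
        with pytest.raises(ValueError):
            ExclusivityData(np.array([0.0, 0.5]), np.array([0.0, 1.0]))


class TestLlrPlacement:
    def test_symmetric_data_zero(self):
        d = ExclusivityData(np.array([0.5, 0.5]), np.array([1.0, 0.0]))
        delta, llr = llr_placement(d)
        assert delta == 0.0 and llr == pytest.approx(0.0, abs=1e-8)

    def test_single_patient_closed_form_at_bound(self):
        d = ExclusivityData(np.array([0.5]), np.array([1.0]))
        delta, llr = llr_placement(d)
        # the optimum saturates at Delta = -10: llr = 2(log sigma(10) - log 0.5)
        expected = 2 * (math.log(1 / (1 + math.exp(-10))) - math.log(0.5))
        assert llr == pytest.approx(expected, abs=1e-6)
        assert delta == -math.inf

    def test_all_exclusive_hits_lower_bound(self):
        d = ExclusivityData(np.array([0.3, 0.6, 0.4]), np.ones(3))
        delta, _ = llr_placement(d)
        assert delta == -math.inf

    def test_permutation_invariance(self, rng):
        r = rng.uniform(0.05, 0.95, 7)
        o = (rng.random(7) < 0.5).astype(float)
        perm = rng.permutation(7)
        _, llr1 = llr_placement(ExclusivityData(r, o))
        _, llr2 = llr_placement(ExclusivityData(r[perm], o[perm]))
        assert llr1 == pytest.approx(llr2, rel=1e-9)

    def test_llr_nonnegative_random(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 9))
            r = rng.uniform(0.01, 0.99, n)
            o = (rng.random(n) < r).astype(float)
            _, llr = llr_placement(ExclusivityData(r, o))
            assert llr >= 0.0


class TestPChisq:
    def test_reference_points(self):
        assert p_chisq(0.0) == 1.0
        assert p_chisq(3.841) == pytest.approx(0.05, abs=5e-4)
        assert p_chisq(1e6) == pytest.approx(0.0, abs=1e-12)

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            p_chisq(-0.5)


class TestPExact:
    def test_single_patient_tied_half(self):
        for o in (0.0, 1.0):
            d = ExclusivityData(np.array([0.5]), np.array([o]))
            assert p_exact(d) == pytest.approx(0.5)

    def test_two_patient_enumeration(self):
        # outcomes (1,1) tie with (0,0); (1,0),(0,1) have lower LLR:
        # p = P(0,0 or 1,1)/2 + P(1,1)/2 ... = 0.25 at r = (1/2, 1/2)
        d = ExclusivityData(np.array([0.5, 0.5]), np.array([1.0, 1.0]))
        assert p_exact(d) == pytest.approx(0.25)

    def test_rejects_large_n_and_fractional(self):
        n = PARAMS.exact_max_n + 1
        with pytest.raises(ValueError, match="exceeds"):
            p_exact(ExclusivityData(np.full(n, 0.4), np.zeros(n)))
        with pytest.raises(ValueError, match="binary"):
            p_exact(ExclusivityData(np.array([0.4]), np.array([0.5])))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.02, 0.98), min_size=1, max_size=6))
    def test_probability_conservation(self, rates):
        _, _, probs = _exact_table(np.array(rates), PARAMS)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)


class TestMonteCarlo:
    def test_seed_determinism(self):
        d = ExclusivityData(np.array([0.3, 0.7]), np.array([1.0, 1.0]))
        sm = SmoothingParams(nu=10.0, n_samples=500, seed=7)
        assert p_monte_carlo(d, PARAMS, sm) == p_monte_carlo(d, PARAMS, sm)

    def test_single_sample_degenerate(self):
        d = ExclusivityData(np.array([0.3]), np.array([1.0]))
        p = p_monte_carlo(d, PARAMS, SmoothingParams(nu=10.0, n_samples=1))
        assert p in (0.0, 1.0)


class TestMinPossibleP:
    def test_single_patient(self):
        assert min_possible_p(np.array([0.5])) == pytest.approx(0.5)

    def test_equals_all_exclusive_outcome(self):
        # with all rates below 1/2, the most extreme pattern is all-exclusive
        r = np.full(4, 0.4)
        d = ExclusivityData(r, np.ones(4))
        assert min_possible_p(r) == pytest.approx(p_exact(d))

    def test_lower_bounds_observed_p(self, rng):
        for _ in range(10):
            n = int(rng.integers(1, 7))
            r = rng.uniform(0.05, 0.95, n)
            o = (rng.random(n) < r).astype(float)
            assert min_possible_p(r) <= p_exact(ExclusivityData(r, o)) + 1e-12
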