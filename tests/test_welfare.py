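"""Atkinson index, EDE standard, its inversion, and the GE link."""

import math

import numpy as np
import pytest

import ineqkit as iq
from ineqkit import ConsistencyError, DomainError, make_distribution
from .conftest import random_distributions
from .oracles import oracle_atkinson

EPS_GRID = (0.25, 0.5, 1.0, 1.5, 2.0, 3.0)


class TestAtkinson:
    def test_epsilon_zero_always_zero(self):
        for d in random_distributions(20, seed=51):
            assert iq.atkinson(d, 0.0) == 0.0

    def test_uniform_always_zero(self, uniform5):
        for eps in EPS_GRID:
            assert iq.atkinson(uniform5, eps) == pytest.approx(0.0, abs=1e-12)

    def test_reference_geometric_mean_case(self, dist_a):
        ai = iq.atkinson(dist_a, 1.0)
        assert ai == pytest.approx(0.06012, abs=5e-5)
        gm = (360 * 250 * 150) ** (1 / 3)
        assert ai == pytest.approx(1 - gm / (760 / 3), abs=1e-12)

    def test_negative_epsilon_rejected(self, dist_a):
        with pytest.raises(DomainError):
            iq.atkinson(dist_a, -0.5)

    def test_zero_units_limits(self):
        d = make_distribution([10, 0, 5])
        assert iq.atkinson(d, 1.0) == 1.0
        assert iq.atkinson(d, 2.0) == 1.0
        assert 0 < iq.atkinson(d, 0.5) < 1

    def test_strictly_increasing_in_epsilon(self):
        for d in random_distributions(20, seed=52, concentration=2.0):
            if np.any(d.units == 0) or np.ptp(d.units) < 1e-9 * d.mean:
                continue
            values = [iq.atkinson(d, e) for e in EPS_GRID]
            assert all(a < b for a, b in zip(values, values[1:]))

    def test_bounded_unit_interval(self):
        for d in random_distributions(50, seed=53):
            for eps in EPS_GRID:
                assert 0.0 <= iq.atkinson(d, eps) <= 1.0

    def test_scale_invariance(self):
        for d in random_distributions(10, seed=54):
            scaled = make_distribution(7.3 * d.units)
            for eps in (0.5, 1.0, 2.0):
                assert iq.atkinson(scaled, eps) == pytest.approx(
                    iq.atkinson(d, eps), abs=1e-12
                )

    def test_matches_power_mean_oracle(self):
        for d in random_distributions(20, seed=55, concentration=2.0):
            if np.any(d.units == 0):
                continue
            for eps in EPS_GRID:
                assert iq.atkinson(d, eps) == pytest.approx(
                    oracle_atkinson(d.units.tolist(), eps), abs=1e-12
                )


class TestEdeStandard:
    def test_epsilon_zero_gives_mean(self, dist_a):
        assert iq.ede_standard(dist_a, 0.0) == pytest.approx(dist_a.mean)

    def test_reference_geometric_mean(self, dist_a):
        assert iq.ede_standard(dist_a, 1.0) == pytest.approx(238.1, abs=0.05)

    def test_one_minus_ai_arithmetic(self):
        """An Atkinson index of 0.4 means the common standard is reachable
        with 60% of the total unit sum."""
        for d in random_distributions(10, seed=56):
            for eps in (0.5, 1.5):
                ai = iq.atkinson(d, eps)
                ede = iq.ede_standard(d, eps)
                assert ede / d.mean == pytest.approx(1 - ai, abs=1e-12)
                # fraction of total needed = k * ede / N = 1 - AI
                assert d.k * ede / d.total == pytest.approx(1 - ai, abs=1e-12)


class TestEpsilonForStandard:
    def test_target_mean_gives_zero(self, dist_a):
        assert iq.epsilon_for_standard(dist_a, dist_a.mean) == 0.0

    def test_reference_inverse(self, dist_a):
        eps = iq.epsilon_for_standard(dist_a, 238.1084)
        assert eps == pytest.approx(1.0, abs=1e-3)

    def test_round_trip(self):
        rng = np.random.default_rng(57)
        for d in random_distributions(10, seed=58, concentration=2.0):
            if np.any(d.units == 0):
                continue
            lo = float(np.min(d.units))
            target = rng.uniform(0.6 * d.mean + 0.4 * lo, d.mean)
            if target <= lo:
                continue
            eps = iq.epsilon_for_standard(d, target)
            assert iq.ede_standard(d, eps) == pytest.approx(
                target, abs=1e-7 * d.mean
            )

    def test_out_of_range_targets_report_interval(self, dist_a):
        with pytest.raises(DomainError, match="achievable"):
            iq.epsilon_for_standard(dist_a, dist_a.mean * 1.1)
        with pytest.raises(DomainError, match="achievable"):
            iq.epsilon_for_standard(dist_a, 10.0)  # below min unit value


class TestGeLink:
    def test_zero_ge_maps_to_zero_ai(self):
        for eps in (0.5, 1.0, 2.0):
            assert iq.atkinson_ge_link(0.0, eps) == pytest.approx(0.0, abs=1e-15)

    def test_epsilon_one_uses_mean_log_deviation(self, dist_a):
        # at epsilon = 1 the GE member at alpha = 1 - eps = 0 is the MLD,
        # and 1 - exp(-MLD) is exactly the direct geometric-mean Atkinson
        mld = iq.mean_log_deviation(dist_a)
        ai = iq.atkinson_ge_link(mld, 1.0, dist_a)
        assert ai == pytest.approx(iq.atkinson(dist_a, 1.0), abs=1e-12)

    def test_general_branch_agrees_with_direct(self):
        for d in random_distributions(15, seed=59, concentration=2.0):
            if np.any(d.units == 0):
                continue
            for eps in (0.25, 0.5, 1.0, 1.5, 2.0, 3.0):
                ge = iq.generalized_entropy(d, 1.0 - eps)
                ai = iq.atkinson_ge_link(ge, eps, d)
                assert ai == pytest.approx(iq.atkinson(d, eps), abs=1e-10)

    def test_mismatched_pairing_raises(self, dist_a):
        # feeding the Theil index (alpha = 1) into the epsilon = 1 branch
        # is the classic transcription mistake; it must not pass silently
        with pytest.raises(ConsistencyError):
            iq.atkinson_ge_link(iq.theil(dist_a), 1.0, dist_a)

    def test_uniform_maps_to_zero(self, uniform5):
        assert iq.atkinson_ge_link(0.0, 1.0, uniform5) == 0.0
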