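"""Unit distribution construction, shares, tables and aliquot merging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ineqkit as iq
from ineqkit import (
    EmptyInputError,
    Kind,
    NegativeValueError,
    NonNumericError,
    distribution_table,
    make_distribution,
    merge_to_aliquots,
)

NAN = float("nan")


class TestConstruction:
    def test_reference_distribution(self, dist_a):
        assert dist_a.total == 760.0
        assert dist_a.k == 3
        assert dist_a.mean == pytest.approx(760 / 3)
        np.testing.assert_allclose(
            dist_a.shares, [360 / 760, 250 / 760, 150 / 760], atol=1e-15
        )

    @pytest.mark.parametrize(
        "raw, expected",
        [
            ((5, None, 5), (5.0, 5.0)),
            ((5, NAN, 5), (5.0, 5.0)),
            ((1, 2, NAN, None, 3), (1.0, 2.0, 3.0)),
        ],
    )
    def test_missing_entries_dropped(self, raw, expected):
        d = make_distribution(raw)
        assert tuple(d.units) == expected

    def test_negative_policy_error_names_indices(self):
        with pytest.raises(NegativeValueError, match=r"\[1\]"):
            make_distribution((3, -1, 2))

    def test_negative_policy_remove(self):
        d = make_distribution((3, -1, 2), negative_policy="remove")
        assert tuple(d.units) == (3.0, 2.0)

    def test_zeros_retained(self):
        assert make_distribution((100, 0, 0)).k == 3

    def test_all_missing_is_empty_input(self):
        with pytest.raises(EmptyInputError):
            make_distribution([None, NAN])

    def test_non_numeric_entry(self):
        with pytest.raises(NonNumericError):
            make_distribution([1, "abc", 3])

    def test_all_zero_total_rejected(self):
        with pytest.raises(EmptyInputError):
            make_distribution([0, 0])

    def test_k1_accepted(self):
        d = make_distribution([5.0])
        assert d.k == 1 and d.shares[0] == 1.0

    def test_labels_follow_na_and_negative_removal(self):
        d = make_distribution(
            [1, None, -2, 3], labels=list("abcd"), negative_policy="remove"
        )
        assert d.labels == ("a", "d")

    def test_counts_from_string(self):
        d = iq.counts_from_labels("AABBC")
        assert d.kind is Kind.CATEGORICAL
        assert d.labels == ("A", "B", "C")
        assert tuple(d.units) == (2.0, 2.0, 1.0)


class TestShares:
    @pytest.mark.parametrize(
        "units, expected",
        [
            ((1, 1, 1, 1), (0.25, 0.25, 0.25, 0.25)),
            ((100, 0, 0), (1.0, 0.0, 0.0)),
        ],
    )
    def test_known_shares(self, units, expected):
        np.testing.assert_allclose(iq.shares(make_distribution(units)), expected)

    @given(
        st.lists(st.floats(0.0, 1e6), min_size=1, max_size=60).filter(
            lambda xs: sum(xs) > 0
        )
    )
    @settings(deadline=None)
    def test_shares_normalise(self, xs):
        p = iq.shares(make_distribution(xs))
        assert abs(p.sum() - 1.0) < 1e-12

    @given(
        st.lists(st.floats(0.01, 1e4), min_size=2, max_size=40),
        st.floats(1e-3, 1e3),
    )
    @settings(deadline=None)
    def test_scale_invariance(self, xs, c):
        base = iq.shares(make_distribution(xs))
        scaled = iq.shares(make_distribution([c * x for x in xs]))
        np.testing.assert_allclose(scaled, base, atol=1e-12)


class TestDistributionTable:
    def test_reference_first_row(self, dist_a):
        t = distribution_table(dist_a)
        row = t.iloc[0]
        assert row["value"] == 150.0
        assert row["unit_share_pct"] == pytest.approx(19.7368, abs=5e-5)
        assert row["cum_unit_share_pct"] == pytest.approx(19.7368, abs=5e-5)
        assert row["component_share_pct"] == pytest.approx(33.3333, abs=5e-5)
        assert row["cum_component_share_pct"] == pytest.approx(33.3333, abs=5e-5)

    def test_cumulative_columns_end_at_100_and_monotone(self, dist_b):
        t = distribution_table(dist_b)
        for col in ("cum_unit_share_pct", "cum_component_share_pct"):
            assert t[col].iloc[-1] == pytest.approx(100.0, abs=1e-9)
            assert (np.diff(t[col]) >= -1e-12).all()

    def test_two_equal_components(self):
        t = distribution_table(make_distribution((1, 1)))
        assert (t["value"] == 1.0).all()
        assert (t["unit_share_pct"] == 50.0).all()

    def test_zero_component_first_row(self):
        t = distribution_table(make_distribution((100, 0)))
        assert t.iloc[0]["value"] == 0.0
        assert t.iloc[0]["unit_share_pct"] == 0.0

    def test_matches_lorenz_vertices(self, dist_b):
        t = distribution_table(dist_b)
        curve = iq.lorenz_curve(dist_b)
        np.testing.assert_allclose(
            t["cum_unit_share_pct"].to_numpy() / 100.0, curve.y[1:], atol=1e-12
        )


class TestAliquotMerging:
    def test_identity_below_threshold(self):
        d = make_distribution(range(1, 11))
        assert merge_to_aliquots(d, 20) is d

    def test_uniform_preserved(self):
        d = make_distribution([2.0] * 40)
        m = merge_to_aliquots(d, 20)
        assert m.k == 20
        np.testing.assert_allclose(m.units, 4.0)
        assert m.total == d.total

    def test_consecutive_slices(self):
        d = make_distribution(range(1, 101))
        m = merge_to_aliquots(d, 20)
        expected = [sum(range(5 * i + 1, 5 * i + 6)) for i in range(20)]
        np.testing.assert_allclose(m.units, expected, atol=1e-9)
        assert m.total == pytest.approx(5050.0, abs=1e-9)

    def test_fractional_boundaries_conserve_total(self):
        d = make_distribution(range(1, 48))  # 47 not divisible by 20
        m = merge_to_aliquots(d, 20)
        assert m.k == 20
        assert m.total == pytest.approx(d.total, abs=1e-9)
        assert (np.diff(m.units) >= -1e-9).all()  # ascending input stays monotone

    def test_merge_never_changes_unmerged_indices(self):
        d = make_distribution(np.arange(1, 101, dtype=float))
        g_before = iq.gini(d)
        merge_to_aliquots(d, 20)
        assert iq.gini(d) == g_before

    def test_invalid_parts(self):
        with pytest.raises(ValueError):
            merge_to_aliquots(make_distribution([1, 2]), 0)
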