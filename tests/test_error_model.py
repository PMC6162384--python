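"""Closed-form assignment-error model vs the exhaustive outcome oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diplomethyl import (
    DEFAULT_ERROR_PROFILE,
    ErrorProfile,
    assignment_error_probability,
    error_curve,
    exact_outcome_distribution,
    simulate_assignment_outcomes,
)

# rates (ins, del, sub) keeping del + sub <= 1
profiles = st.tuples(
    st.floats(0, 1), st.floats(0, 0.5), st.floats(0, 0.5)
).map(lambda t: ErrorProfile(*t))


class TestClosedForm:
    def test_default_profile_site_probabilities(self):
        p = DEFAULT_ERROR_PROFILE
        assert p.p_support_wrong == pytest.approx(0.01, abs=1e-15)
        assert p.p_miss == pytest.approx(0.07, abs=1e-15)
        assert p.p_support_correct == pytest.approx(0.92, abs=1e-15)

    @pytest.mark.parametrize(
        "n, expected, tol",
        [
            (1, 0.01, 1e-12),
            (2, 1.5e-3, 1e-12),
            (3, 4.7e-4, 5e-6),  # printed to two significant figures
            (4, 1.0e-4, 5e-6),
        ],
    )
    def test_reference_values(self, n, expected, tol):
        assert assignment_error_probability(n) == pytest.approx(expected, abs=tol)

    def test_two_snv_decomposition(self):
        """The N=2 value splits into double-substitution and miss+substitution."""
        p = DEFAULT_ERROR_PROFILE
        double_sub = p.p_support_wrong**2
        miss_plus_sub = 2 * p.p_miss * p.p_support_wrong
        assert double_sub == pytest.approx(1.0e-4, abs=1e-12)
        assert miss_plus_sub == pytest.approx(1.4e-3, abs=1e-12)
        assert assignment_error_probability(2) == pytest.approx(
            double_sub + miss_plus_sub, abs=1e-15
        )

    def test_zero_error_profile(self):
        clean = ErrorProfile(0.0, 0.0, 0.0)
        for n in (1, 3, 7):
            assert assignment_error_probability(n, clean) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            assignment_error_probability(0)
        with pytest.raises(TypeError):
            assignment_error_probability(1.5)
        with pytest.raises(ValueError):
            ErrorProfile(0.1, 0.8, 0.5)
        with pytest.raises(ValueError):
            ErrorProfile(-0.1, 0.05, 0.03)

    def test_strictly_decreasing_in_n(self):
        vals = [assignment_error_probability(n) for n in range(1, 11)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestExactOracle:
    def test_single_site_distribution(self):
        d = exact_outcome_distribution(1)
        assert d.astuple() == pytest.approx((0.01, 0.07, 0.92), abs=1e-15)

    def test_agrees_with_closed_form_at_small_n(self):
        # the dropped support-correct factor is 1 when no site remains free
        for n in (1, 2):
            assert exact_outcome_distribution(n).wrong_assignment == pytest.approx(
                assignment_error_probability(n), abs=1e-15
            )

    def test_n3_exact_value(self):
        # enumeration keeps the support-correct factor the closed form drops
        assert exact_outcome_distribution(3).wrong_assignment == pytest.approx(
            4.45e-4, abs=1e-12
        )

    def test_closed_form_upper_bounds_exact(self):
        for n in range(1, 11):
            assert (
                assignment_error_probability(n) + 1e-15
                >= exact_outcome_distribution(n).wrong_assignment
            )

    def test_capacity_error(self):
        with pytest.raises(ValueError):
            exact_outcome_distribution(16)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(profile=profiles, n=st.integers(1, 10))
    def test_triple_sums_to_one(self, profile, n):
        d = exact_outcome_distribution(n, profile)
        assert sum(d.astuple()) == pytest.approx(1.0, abs=1e-12)
        assert all(0.0 <= v <= 1.0 + 1e-12 for v in d.astuple())

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(profile=profiles, n=st.integers(1, 10))
    def test_closed_form_upper_bounds_exact_any_profile(self, profile, n):
        assert (
            assignment_error_probability(n, profile) + 1e-12
            >= exact_outcome_distribution(n, profile).wrong_assignment
        )

    def test_monotone_decrease_when_wrong_possible(self):
        profile = ErrorProfile(0.02, 0.10, 0.09)  # support-wrong 3%, miss 16%
        vals = [
            exact_outcome_distribution(n, profile).wrong_assignment
            for n in range(1, 11)
        ]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestErrorCurve:
    def test_matches_reference_values(self):
        table = error_curve(4)
        assert list(table["n_snvs"]) == [1, 2, 3, 4]
        assert table["approx_probability"].iloc[0] == pytest.approx(0.01)
        assert table["approx_probability"].iloc[1] == pytest.approx(1.5e-3)

    def test_single_row_and_monotone(self):
        assert len(error_curve(1)) == 1
        probs = error_curve(10)["approx_probability"].to_numpy()
        assert np.all(np.diff(probs) < 0)

    def test_exact_column(self):
        table = error_curve(3, exact=True)
        assert "exact_probability" in table.columns
        assert table["exact_probability"].iloc[2] == pytest.approx(4.45e-4)


class TestMonteCarloAgreement:
    @pytest.mark.parametrize("n_snvs", [1, 2, 3])
    def test_simulation_matches_exact_distribution(self, n_snvs):
        """Simulated vote outcomes match the enumeration within 3 SE."""
        n_reads = 1_000_000
        counts = simulate_assignment_outcomes(n_reads, n_snvs, seed=123)
        exact = exact_outcome_distribution(n_snvs)
        for key, expected in (
            ("wrong", exact.wrong_assignment),
            ("unassigned", exact.unassigned),
            ("correct", exact.correct_assignment),
        ):
            observed = counts[key] / n_reads
            se = math.sqrt(expected * (1 - expected) / n_reads)
            assert abs(observed - expected) <= 3 * se + 1e-12, (key, observed)
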