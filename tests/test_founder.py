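"""Unit and property tests for the binomial founder-mutation model."""

from fractions import Fraction

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gistkit.founder import (
    FounderModelParams,
    InvalidParameterError,
    build_threshold_table,
    classify_founder,
    count_founder_snvs,
    founder_threshold,
)
from conftest import oracle_threshold


class TestFounderThreshold:
    @pytest.mark.parametrize(
        "n, expected",
        [(13, 1), (14, 2), (28, 5), (33, 6), (37, 7)],
    )
    def test_printed_boundaries(self, n, expected, default_params):
        """Thresholds at the published coverage boundaries (purity 0.6)."""
        assert founder_threshold(n, default_params) == expected

    @pytest.mark.parametrize(
        "n, expected",
        [
            (24, 4),  # first coverage where k reaches 4 (exact-oracle value)
            (1, 1),  # floor: no k retains 95% of founders at n = 1
            (19, 3),  # derived value at the inconsistent printed entry
        ],
    )
    def test_derived_values(self, n, expected, default_params):
        assert founder_threshold(n, default_params) == expected

    def test_monotone_in_coverage(self, default_params):
        ks = [founder_threshold(n, default_params) for n in range(1, 501)]
        assert all(b >= a for a, b in zip(ks, ks[1:]))
        assert min(ks) >= 1

    def test_inclusion_guarantee(self, default_params):
        """For every k(n) > 1 the exact tail brackets the inclusion level.

        Cross-checked with scipy's survival function, a different code
        path from the package's own pmf summation.
        """
        q = default_params.success_prob
        for n in range(1, 501):
            k = founder_threshold(n, default_params)
            if k > 1:
                assert stats.binom.sf(k - 1, n, q) >= default_params.inclusion
                assert stats.binom.sf(k, n, q) < default_params.inclusion

    def test_matches_exact_rational_oracle(self, default_params):
        """Spot grid against the Fraction-arithmetic brute-force oracle
        (the full n <= 200 x 5 purity sweep runs in the acceptance suite)."""
        for pur_num in (1, 3, 5):
            params = FounderModelParams(purity=pur_num / 5)
            q = Fraction(pur_num, 5) / 2
            for n in (1, 7, 14, 29, 50, 97):
                assert founder_threshold(n, params) == oracle_threshold(n, q)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(purity=0.0),
            dict(purity=1.5),
            dict(inclusion=0.0),
            dict(inclusion=1.0),
            dict(het_factor=0.0),
        ],
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(InvalidParameterError):
            FounderModelParams(**kwargs)

    def test_invalid_coverage(self, default_params):
        with pytest.raises(InvalidParameterError):
            founder_threshold(0, default_params)


class TestThresholdTable:
    def test_jumps_at_printed_boundaries(self, default_params):
        table = build_threshold_table(10, 40, default_params)
        assert table[13] == 1 and table[14] == 2
        assert table[27] == 4 and table[28] == 5

    def test_single_entry(self, default_params):
        table = build_threshold_table(5, 5, default_params)
        assert table.thresholds == {5: 1}

    def test_non_decreasing_invariant(self, default_params):
        ks = list(build_threshold_table(1, 100, default_params).thresholds.values())
        assert ks == sorted(ks)

    def test_empty_range_rejected(self, default_params):
        with pytest.raises(InvalidParameterError):
            build_threshold_table(10, 9, default_params)


class TestClassifyFounder:
    @pytest.mark.parametrize(
        "alt, cov, expected",
        [
            (14, 53, True),  # KIT-like fraction, well above k(53) = 11
            (8, 37, True),  # boundary case: k(37) = 7
            (0, 50, False),
            (1, 100, False),  # k(100) far above a single supporting read
        ],
    )
    def test_examples(self, alt, cov, expected, default_params):
        assert classify_founder(alt, cov, default_params) is expected

    def test_alt_exceeding_coverage_rejected(self, default_params):
        with pytest.raises(InvalidParameterError):
            classify_founder(10, 5, default_params)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(n=st.integers(1, 300), alt=st.integers(0, 300))
    def test_consistent_with_threshold(self, n, alt):
        params = FounderModelParams()
        alt = min(alt, n)
        assert classify_founder(alt, n, params) == (
            alt >= founder_threshold(n, params)
        )


class TestCountFounderSnvs:
    def test_candidate_table(self, founder_candidates, default_params):
        """All published candidates pass; the SNV count is 12 (one row is a
        frameshift deletion, classified but not counted as an SNV)."""
        assert count_founder_snvs(founder_candidates, default_params) == 12

    def test_empty_table(self, default_params):
        empty = pd.DataFrame(columns=["alt_count", "coverage", "variant_class"])
        assert count_founder_snvs(empty, default_params) == 0

    def test_low_fraction_row_not_counted(self, default_params):
        table = pd.DataFrame(
            [{"alt_count": 1, "coverage": 100, "variant_class": "SNV"}]
        )
        assert count_founder_snvs(table, default_params) == 0

    def test_malformed_row_names_identifier(self, default_params):
        table = pd.DataFrame(
            [{"gene": "BAD1", "alt_count": 60, "coverage": 50, "variant_class": "SNV"}]
        )
        with pytest.raises(ValueError, match="BAD1"):
            count_founder_snvs(table, default_params)
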