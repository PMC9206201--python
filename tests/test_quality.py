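import datetime

import pytest
from hypothesis import given, settings, strategies as st

from rhinodiary.quality import (
    IndexConfig,
    coefficient_of_variation,
    compute_all,
    consecutive_pairs,
    intravariation_index,
    pct_changes_in_trend,
    pct_variations,
    pct_zero_values,
    variation_range,
)
from rhinodiary.scoring import ScoreTrajectory

import oracles
from conftest import START

RECORD = IndexConfig(pairing="record")
integer_series = st.lists(st.integers(0, 4), min_size=0, max_size=12)


def days_from(values, gaps=None):
    """Consecutive day indices, or explicit ones."""
    return list(range(len(values))) if gaps is None else gaps


def make_traj(values, offsets=None, score="VAS"):
    offsets = offsets if offsets is not None else range(len(values))
    dates = tuple(START + datetime.timedelta(days=o) for o in offsets)
    return ScoreTrajectory("P1", score, dates=dates, values=tuple(float(v) for v in values))


class TestConsecutivePairs:
    def test_dense_days_same_in_both_modes(self):
        values, days = [1, 2, 3], [0, 1, 2]
        assert consecutive_pairs(values, days, "calendar") == [(1, 2), (2, 3)]
        assert consecutive_pairs(values, days, "record") == [(1, 2), (2, 3)]

    def test_gapped_days(self):
        values, days = [1, 2, 5, 6], [1, 2, 5, 6]
        assert consecutive_pairs(values, days, "calendar") == [(1, 2), (5, 6)]
        assert consecutive_pairs(values, days, "record") == [(1, 2), (2, 5), (5, 6)]

    def test_single_record(self):
        assert consecutive_pairs([3], [0], "calendar") == []

    def test_bad_mode(self):
        with pytest.raises(ValueError):
            consecutive_pairs([1, 2], [0, 1], "weekly")


class TestIntravariationIndex:
    def test_constant_series(self):
        assert intravariation_index([1, 1, 1], 1.0, [0, 1, 2]) == 0.0

    def test_alternating_series(self):
        # pctVar=100, rVAR=1
        assert intravariation_index([0, 1, 0, 1], 1.0, [0, 1, 2, 3]) == pytest.approx(100.0)

    def test_hand_computation(self):
        # pairs (0,2),(2,2),(2,4),(4,4): 2 of 4 change; rVAR=4
        assert intravariation_index([0, 2, 2, 4, 4], 1.0, range(5)) == pytest.approx(12.5)

    def test_csms_unit_step_scaling(self):
        values = [0.0, 1 / 6, 1 / 6]
        assert intravariation_index(values, 1 / 6, [0, 1, 2]) == pytest.approx(50.0)

    def test_single_value_undefined(self):
        assert intravariation_index([2], 1.0, [0]) is None

    def test_all_gapped_pairs_undefined(self):
        assert intravariation_index([0, 3], 1.0, [0, 5]) is None

    def test_rvar_plus_one_variant(self):
        config = IndexConfig(rvar_plus_one=True)
        # pctVar=100, rVAR=(1-0+1)/1=2
        assert intravariation_index([0, 1, 0], 1.0, [0, 1, 2], config) == pytest.approx(50.0)

    @given(integer_series, st.sampled_from([1.0, 0.5, 1 / 6]))
    def test_scale_invariance(self, values, step):
        days = days_from(values)
        base = intravariation_index(values, 1.0, days)
        scaled = intravariation_index([v * step for v in values], step, days)
        if base is None:
            assert scaled is None
        else:
            assert scaled == pytest.approx(base)

    @given(integer_series)
    def test_bounded_by_pct_var_on_integer_grid(self, values):
        days = days_from(values)
        ivi = intravariation_index(values, 1.0, days)
        if ivi is None:
            return
        pct_var = pct_variations(consecutive_pairs(values, days, "calendar"))
        assert 0.0 <= ivi <= pct_var + 1e-9


class TestPctZero:
    def test_half_zero(self):
        assert pct_zero_values([0, 0, 1, 2]) == 50.0

    def test_all_zero(self):
        assert pct_zero_values([0, 0, 0]) == 100.0

    def test_strictly_positive(self):
        assert pct_zero_values([1, 2, 3]) == 0.0

    def test_empty_undefined(self):
        assert pct_zero_values([]) is None


class TestCoefficientOfVariation:
    def test_constant_nonzero(self):
        assert coefficient_of_variation([2, 2, 2]) == 0.0

    def test_hand_computation(self):
        # mean 2, sample SD 2.828...
        assert coefficient_of_variation([0, 4]) == pytest.approx(141.42135, abs=1e-4)

    def test_zero_mean_undefined(self):
        assert coefficient_of_variation([0, 0, 0]) is None

    def test_single_value_undefined(self):
        assert coefficient_of_variation([3]) is None

    def test_population_sd_option(self):
        assert coefficient_of_variation([0, 4], ddof=0) == pytest.approx(100.0)

    @given(
        st.lists(st.integers(0, 4), min_size=2, max_size=10).filter(lambda v: sum(v) > 0),
        st.floats(0.1, 10.0),
    )
    def test_scale_invariance(self, values, c):
        base = coefficient_of_variation(values)
        scaled = coefficient_of_variation([v * c for v in values])
        assert scaled == pytest.approx(base, rel=1e-9)


class TestTrendChanges:
    def test_monotone_series(self):
        assert pct_changes_in_trend([1, 2, 3, 4], [0, 1, 2, 3]) == 0.0

    def test_zigzag(self):
        assert pct_changes_in_trend([1, 2, 1, 2], [0, 1, 2, 3]) == 100.0

    def test_constant_series(self):
        assert pct_changes_in_trend([5, 5, 5, 5], [0, 1, 2, 3]) == 0.0

    def test_too_short_undefined(self):
        assert pct_changes_in_trend([1, 2], [0, 1]) is None

    def test_gapped_signs_not_compared(self):
        # pairs (0,1) and (3,4): signs +,+ but separated by a gap
        assert pct_changes_in_trend([1, 2, 2, 3], [0, 1, 3, 4]) is None

    def test_record_mode_spans_gaps(self):
        # record signs +,0,+ give two comparisons, both transitions
        assert pct_changes_in_trend([1, 2, 2, 3], [0, 1, 3, 4], RECORD) == pytest.approx(100.0)

    def test_nonzero_diff_mode(self):
        config = IndexConfig(trend_mode="nonzero_diff")
        assert pct_changes_in_trend([1, 2, 2, 3], [0, 1, 2, 3], config) == pytest.approx(100 * 2 / 3)

    @given(integer_series, st.floats(0.1, 5.0), st.floats(-10.0, 10.0))
    def test_invariant_under_increasing_affine(self, values, a, b):
        days = days_from(values)
        base = pct_changes_in_trend(values, days)
        mapped = pct_changes_in_trend([a * v + b for v in values], days)
        if base is None:
            assert mapped is None
        else:
            assert mapped == pytest.approx(base)


class TestOracleEquivalence:
    @given(integer_series, st.sampled_from(["calendar", "record"]))
    @settings(max_examples=300)
    def test_random_series_match_bruteforce(self, values, mode):
        days = days_from(values)
        config = IndexConfig(pairing=mode)
        checks = [
            (intravariation_index(values, 1.0, days, config),
             oracles.oracle_ivi(values, days, 1.0, mode)),
            (pct_zero_values(values), oracles.oracle_pct_zero(values)),
            (coefficient_of_variation(values), oracles.oracle_cv(values)),
            (pct_changes_in_trend(values, days, config),
             oracles.oracle_trend(values, days, mode)),
        ]
        for got, want in checks:
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want)

    @given(
        st.lists(st.integers(0, 4), min_size=4, max_size=10),
        st.data(),
    )
    @settings(max_examples=150)
    def test_gapped_series_match_bruteforce(self, values, data):
        gaps = data.draw(
            st.lists(st.integers(1, 3), min_size=len(values) - 1, max_size=len(values) - 1)
        )
        days = [0]
        for g in gaps:
            days.append(days[-1] + g)
        for mode in ("calendar", "record"):
            config = IndexConfig(pairing=mode)
            got = intravariation_index(values, 1.0, days, config)
            want = oracles.oracle_ivi(values, days, 1.0, mode)
            assert (got is None) == (want is None)
            if want is not None:
                assert got == pytest.approx(want)
            got_t = pct_changes_in_trend(values, days, config)
            want_t = oracles.oracle_trend(values, days, mode)
            assert (got_t is None) == (want_t is None)
            if want_t is not None:
                assert got_t == pytest.approx(want_t)


class TestComputeAll:
    def test_empty_trajectory(self):
        result = compute_all(make_traj([]))
        assert result.n_observations == 0
        assert result.n_pairs == 0
        assert result.ivi is None
        assert result.pct_zero is None
        assert result.cv is None
        assert result.pct_trend_change is None
        assert result.rvar is None

    def test_constant_zero_trajectory(self):
        result = compute_all(make_traj([0, 0, 0, 0]))
        assert result.ivi == 0.0
        assert result.pct_zero == 100.0
        assert result.cv is None
        assert result.pct_trend_change == 0.0
        assert result.rvar == 0.0

    @given(st.lists(st.integers(0, 4), min_size=1, max_size=10))
    def test_consistent_with_standalone_operations(self, values):
        traj = make_traj(values)
        days = [d.toordinal() for d in traj.dates]
        result = compute_all(traj)
        assert result.ivi == intravariation_index(traj.values, 1.0, days)
        assert result.pct_zero == pct_zero_values(traj.values)
        assert result.cv == coefficient_of_variation(traj.values)
        assert result.pct_trend_change == pct_changes_in_trend(traj.values, days)
        assert result.n_observations == len(values)

    def test_variation_range_empty_raises(self):
        with pytest.raises(ValueError):
            variation_range([], 1.0)
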