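"""Noise-filter rule, checked against an index-by-index brute force."""

import numpy as np
import pytest
from hypothesis import given, seed, settings
from hypothesis import strategies as st

from spectraqc import (
    FLAG_PCT,
    FLAG_RUN,
    NoiseSegment,
    apply_noise_filter,
    flag_noise,
)
from spectraqc.errors import ConfigError

from conftest import make_dataset


def brute_force_flags(series, wavelengths, segment):
    """Literal restatement of the two-criterion rule, one index at a time."""
    n = len(series)
    flags = [0] * n
    in_seg = [
        segment.lower_nm <= w <= segment.upper_nm for w in wavelengths
    ]
    pct = [False] * n
    for i in range(1, n):
        prev, cur = series[i - 1], series[i]
        if np.isnan(prev) or np.isnan(cur) or not in_seg[i]:
            continue
        if abs(prev) < 1e-12:
            d = 0.0 if abs(cur) < 1e-12 else np.inf
        else:
            d = abs(cur - prev) / abs(prev) * 100.0
        pct[i] = d > segment.max_pct_change
    for i in range(n):
        if pct[i]:
            flags[i] = FLAG_PCT
    # maximal consecutive streaks of pct flags
    i = 0
    while i < n:
        if pct[i]:
            j = i
            while j + 1 < n and pct[j + 1]:
                j += 1
            if j - i + 1 >= segment.n_size:
                for t in range(i, j + 1):
                    flags[t] = FLAG_RUN
            i = j + 1
        else:
            i += 1
    return np.asarray(flags, dtype=np.int8)


WORKED_SERIES = [0.50, 0.50, 0.20, 0.45, 0.10, 0.30, 0.31]


class TestFlagNoise:
    def test_constant_series_never_flagged(self):
        wl = np.arange(400.0, 404.0)
        series = np.full(4, 0.5)
        seg = NoiseSegment(400, 403, max_pct_change=0.001, n_size=1)
        assert not flag_noise(series, wl, seg).any()

    def test_worked_example_pct_and_run(self):
        # |change| vs previous: -, 0, 60, 125, 77.8, 200, 3.3 (%)
        wl = np.arange(400.0, 407.0)
        seg = NoiseSegment(400, 406, max_pct_change=20, n_size=3)
        flags = flag_noise(np.asarray(WORKED_SERIES), wl, seg)
        assert list(flags) == [0, 0, FLAG_RUN, FLAG_RUN, FLAG_RUN, FLAG_RUN, 0]

    def test_worked_example_streak_shorter_than_n_size(self):
        wl = np.arange(400.0, 407.0)
        seg = NoiseSegment(400, 406, max_pct_change=20, n_size=5)
        flags = flag_noise(np.asarray(WORKED_SERIES), wl, seg)
        assert list(flags) == [0, 0, FLAG_PCT, FLAG_PCT, FLAG_PCT, FLAG_PCT, 0]

    def test_missing_cells_break_streaks_and_are_never_flagged(self):
        wl = np.arange(400.0, 407.0)
        series = np.asarray([0.5, 0.1, 0.5, np.nan, 0.5, 0.1, 0.5])
        seg = NoiseSegment(400, 406, max_pct_change=20, n_size=3)
        flags = flag_noise(series, wl, seg)
        assert flags[3] == 0
        assert FLAG_RUN not in flags  # streaks of 2 on each side of the gap

    def test_segment_outside_range_warns_and_flags_nothing(self):
        wl = np.arange(400.0, 410.0)
        seg = NoiseSegment(1800, 1950, max_pct_change=20, n_size=3)
        with pytest.warns(UserWarning):
            flags = flag_noise(np.full(10, 0.5), wl, seg)
        assert not flags.any()

    def test_run_implies_pct_level(self):
        rng = np.random.default_rng(0)
        wl = np.arange(400.0, 450.0)
        seg = NoiseSegment(405, 440, max_pct_change=15, n_size=2)
        for _ in range(20):
            series = rng.uniform(0.05, 0.9, size=50)
            flags = flag_noise(series, wl, seg)
            oracle = brute_force_flags(series, wl, seg)
            assert np.array_equal(flags, oracle)

    @seed(20240917)
    @settings(max_examples=150, deadline=None)
    @given(
        data=st.lists(
            st.one_of(st.floats(0.0, 1.0), st.none()), min_size=3, max_size=50
        ),
        pct=st.floats(1.0, 200.0),
        n_size=st.integers(1, 8),
    )
    def test_matches_brute_force(self, data, pct, n_size):
        series = np.asarray([np.nan if v is None else v for v in data])
        wl = np.arange(400.0, 400.0 + series.size)
        seg = NoiseSegment(wl[0], wl[-1], max_pct_change=pct, n_size=n_size)
        assert np.array_equal(
            flag_noise(series, wl, seg), brute_force_flags(series, wl, seg)
        )

    @seed(20240918)
    @settings(max_examples=80, deadline=None)
    @given(
        pct=st.floats(5.0, 100.0),
        pct_lower=st.floats(0.5, 1.0),
        n_size=st.integers(2, 6),
    )
    def test_flag_set_monotone_in_criteria(self, pct, pct_lower, n_size):
        """Lowering % or N size never shrinks the flagged set."""
        rng = np.random.default_rng(42)
        series = rng.uniform(0.05, 0.9, size=40)
        wl = np.arange(400.0, 440.0)
        base = flag_noise(series, wl, NoiseSegment(400, 439, pct, n_size))
        looser_pct = flag_noise(
            series, wl, NoiseSegment(400, 439, pct * pct_lower, n_size)
        )
        looser_n = flag_noise(
            series, wl, NoiseSegment(400, 439, pct, max(1, n_size - 1))
        )
        assert np.all((base > 0) <= (looser_pct > 0))
        assert np.all((base == FLAG_RUN) <= (looser_n == FLAG_RUN))


class TestApplyNoiseFilter:
    def _two_sample_dataset(self):
        """Sample A noisy over 410-415 nm, sample B over 412-418 nm."""
        wl = np.arange(400.0, 425.0)
        base = np.full(25, 0.5)
        a, b = base.copy(), base.copy()
        a[10:16] = [0.1, 0.5, 0.1, 0.5, 0.1, 0.5]
        b[12:19] = [0.1, 0.5, 0.1, 0.5, 0.1, 0.5, 0.1]
        quiet = base.copy()
        return make_dataset(np.vstack([a, b, quiet]), wavelengths=wl, k=1)

    def test_no_flags_returns_dataset_unchanged(self):
        ds = make_dataset(np.full((4, 10), 0.5), k=2)
        result = apply_noise_filter(ds, [NoiseSegment(400, 409, 20, 3)])
        assert np.array_equal(result.dataset.values, ds.values)
        assert result.report.empty

    def test_group_mode_deletes_union_envelope_for_all_samples(self):
        ds = self._two_sample_dataset()
        seg = NoiseSegment(400, 424, max_pct_change=20, n_size=3, mode="group")
        result = apply_noise_filter(ds, [seg])
        deleted = np.isnan(result.dataset.values)
        # B's trailing jump back to baseline is itself a flagged change, so
        # the union of per-sample envelopes spans indices 10..19
        assert deleted[:, 10:20].all()
        assert not deleted[:, :10].any() and not deleted[:, 20:].any()

    def test_individual_mode_cuts_each_sample_to_its_own_envelope(self):
        ds = self._two_sample_dataset()
        seg = NoiseSegment(400, 424, max_pct_change=20, n_size=3, mode="individual")
        result = apply_noise_filter(ds, [seg])
        deleted = np.isnan(result.dataset.values)
        assert deleted[0, 10:16].all() and not deleted[0, 16:].any()
        assert deleted[1, 12:19].all() and not deleted[1, :12].any()
        assert not deleted[2].any()  # quiet sample untouched

    def test_group_envelope_equals_union_of_individual_run_flags(self):
        rng = np.random.default_rng(9)
        wl = np.arange(400.0, 460.0)
        values = rng.uniform(0.3, 0.6, size=(5, 60))
        values[:, 20:35] *= rng.uniform(0.2, 1.8, size=(5, 15))
        ds = make_dataset(values, wavelengths=wl, k=1)
        seg_g = NoiseSegment(400, 459, 25, 3, mode="group")
        seg_i = NoiseSegment(400, 459, 25, 3, mode="individual")
        group = apply_noise_filter(ds, [seg_g]).dataset
        indiv = apply_noise_filter(ds, [seg_i]).dataset
        ind_cols = np.flatnonzero(np.isnan(indiv.values).any(axis=0))
        grp_cols = np.flatnonzero(np.isnan(group.values).all(axis=0))
        if ind_cols.size:
            expected = np.arange(ind_cols.min(), ind_cols.max() + 1)
            assert np.array_equal(grp_cols, expected)
        else:
            assert grp_cols.size == 0

    @pytest.mark.parametrize("mode", ["group", "individual"])
    def test_idempotent(self, mode):
        rng = np.random.default_rng(17)
        values = rng.uniform(0.05, 0.9, size=(6, 40))
        ds = make_dataset(values, k=3)
        seg = NoiseSegment(400, 439, 30, 2, mode=mode)
        once = apply_noise_filter(ds, [seg]).dataset
        twice = apply_noise_filter(once, [seg]).dataset
        assert np.array_equal(once.values, twice.values, equal_nan=True)

    def test_filters_only_turn_cells_missing(self):
        rng = np.random.default_rng(23)
        values = rng.uniform(0.05, 0.9, size=(4, 30))
        ds = make_dataset(values, k=2)
        seg = NoiseSegment(400, 429, 10, 2, mode="individual")
        out = apply_noise_filter(ds, [seg], drop_negatives=True).dataset
        survived = ~np.isnan(out.values)
        assert np.array_equal(out.values[survived], ds.values[survived])

    def test_drop_negatives_is_global(self):
        values = np.full((2, 6), 0.4)
        values[0, 1] = -0.01
        values[1, 5] = -0.2
        ds = make_dataset(values, k=1)
        result = apply_noise_filter(ds, [], drop_negatives=True)
        assert result.n_negatives_deleted == 2
        assert np.isnan(result.dataset.values[0, 1])
        assert np.isnan(result.dataset.values[1, 5])

    def test_more_than_ten_segments_rejected(self):
        ds = make_dataset(np.full((1, 30), 0.5), k=1)
        segs = [
            NoiseSegment(400 + 2 * i, 401 + 2 * i, 20, 2) for i in range(11)
        ]
        with pytest.raises(ConfigError):
            apply_noise_filter(ds, segs)

    def test_overlapping_segments_rejected(self):
        ds = make_dataset(np.full((1, 30), 0.5), k=1)
        with pytest.raises(ConfigError):
            apply_noise_filter(
                ds,
                [NoiseSegment(400, 410, 20, 2), NoiseSegment(405, 415, 20, 2)],
            )
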