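"""Unit and property tests for the pupil preprocessing chain.

The dilation-speed filter is checked sample-for-sample against an
independent brute-force implementation (pure-Python loops over nearest
valid neighbours, statistics.median).
"""

import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oddpupil import pupil_prep as pp
from oddpupil import synthetic_data as sd
from oddpupil.task_design import TrialSpec

DT = 1000.0 / 300.0


def make_series(left, right=None, valid_l=None, valid_r=None, t=None):
    left = np.asarray(left, dtype=float)
    right = left.copy() if right is None else np.asarray(right, dtype=float)
    n = len(left)
    return pp.PupilSeries(
        t=np.arange(n) * DT if t is None else np.asarray(t, float),
        left_mm=left,
        right_mm=right,
        valid_l=np.ones(n, bool) if valid_l is None else np.asarray(valid_l, bool),
        valid_r=np.ones(n, bool) if valid_r is None else np.asarray(valid_r, bool),
    )


def trial_spec(isi=1900.0, stimulus="standard", block=1):
    return TrialSpec(
        block=block, index_in_block=5, stimulus=stimulus, pitch_hz=500.0,
        onset_ms=0.0, isi_ms=isi, manipulation_phase="before",
        block_direction="forward",
    )


# ---------------------------------------------------------------------------
# range filter
# ---------------------------------------------------------------------------

class TestRangeFilter:
    @pytest.mark.parametrize(
        "value,expected_valid",
        [(1.9, False), (8.1, False), (5.0, True), (2.0, True), (8.0, True)],
    )
    def test_bounds(self, value, expected_valid):
        s = make_series([4.0, value, 4.0])
        out = pp.range_filter(s)
        assert out.valid_l[1] == expected_valid
        assert out.valid_l[0] and out.valid_l[2]

    def test_nan_marked_invalid(self):
        out = pp.range_filter(make_series([4.0, np.nan, 4.0]))
        assert not out.valid_l[1]

    def test_idempotent(self):
        s = make_series([1.0, 4.0, 9.0, 5.0])
        once = pp.range_filter(s)
        twice = pp.range_filter(once)
        assert np.array_equal(once.valid_l, twice.valid_l)
        assert np.array_equal(once.left_mm, twice.left_mm)

    def test_does_not_touch_values(self):
        s = make_series([1.0, 4.0, 9.0])
        out = pp.range_filter(s)
        assert np.array_equal(out.left_mm, s.left_mm)


# ---------------------------------------------------------------------------
# dilation-speed filter vs brute-force oracle
# ---------------------------------------------------------------------------

def oracle_dilation_filter(t, x, valid, k=3.0, passes=2):
    """Independent re-implementation: explicit loops, nearest valid
    neighbours, statistics.median, threshold median + k * MAD."""
    valid = list(valid)
    for _ in range(passes):
        vi = [i for i in range(len(t)) if valid[i]]
        if len(vi) < 3:
            break
        d = {}
        for pos, i in enumerate(vi):
            speeds = []
            if pos > 0:
                j = vi[pos - 1]
                speeds.append(abs(x[i] - x[j]) / (t[i] - t[j]))
            if pos < len(vi) - 1:
                j = vi[pos + 1]
                speeds.append(abs(x[j] - x[i]) / (t[j] - t[i]))
            d[i] = max(speeds)
        med = statistics.median(d.values())
        mad = statistics.median(abs(v - med) for v in d.values())
        flagged = [i for i, v in d.items() if v > med + k * mad]
        if not flagged:
            break
        for i in flagged:
            valid[i] = False
    return valid


short_series = st.lists(
    st.floats(min_value=2.0, max_value=8.0, allow_nan=False), min_size=3, max_size=20
)


class TestDilationSpeedFilter:
    def test_constant_series_untouched(self):
        out = pp.dilation_speed_filter(make_series([4.0] * 5))
        assert out.valid_l.all() and out.valid_r.all()

    def test_six_sample_example_matches_oracle(self):
        # threshold = median + 3*MAD = 0.15/dt + 3*0.15/dt exceeds every
        # speed (max 0.3/dt), so nothing is removed from this series
        x = [4.0, 4.0, 4.0, 7.0, 4.0, 4.0]
        t = np.arange(6) * DT
        expect = oracle_dilation_filter(t, x, [True] * 6)
        assert expect == [True] * 6
        out = pp.dilation_speed_filter(make_series(x))
        assert list(out.valid_l) == expect

    def test_isolated_spike_in_long_flat_series_removed(self):
        # majority-flat series: median and MAD are 0, so the spike and its
        # speed-contaminated neighbours are flagged
        x = [4.0] * 5 + [7.0] + [4.0] * 5
        t = np.arange(11) * DT
        expect = oracle_dilation_filter(t, x, [True] * 11)
        assert expect[5] is False
        out = pp.dilation_speed_filter(make_series(x))
        assert list(out.valid_l) == expect

    def test_fewer_than_three_valid_left_unchanged_with_warning(self):
        s = make_series([4.0, 7.0, 4.0], valid_l=[True, True, False])
        out = pp.dilation_speed_filter(s)
        assert np.array_equal(out.valid_l, s.valid_l)
        assert any("dilation_speed_filter" in w for w in out.warnings)

    def test_never_unmarks_invalid(self):
        s = make_series([4.0, 7.0, 4.0, 4.0, 4.0], valid_l=[1, 1, 0, 1, 1])
        out = pp.dilation_speed_filter(s)
        assert not out.valid_l[2]

    @given(values=short_series, data=st.data())
    @settings(max_examples=1000, deadline=None)
    def test_matches_oracle_on_random_series(self, values, data):
        n = len(values)
        valid = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n), label="valid"
        )
        t = np.arange(n) * DT
        s = make_series(values, valid_l=valid, valid_r=valid)
        out = pp.dilation_speed_filter(s)
        expect = oracle_dilation_filter(t, values, valid)
        assert list(out.valid_l) == expect
        assert list(out.valid_r) == expect

    @given(values=short_series)
    @settings(max_examples=200, deadline=None)
    def test_forward_speed_option_matches_loop_oracle(self, values):
        n = len(values)
        t = np.arange(n) * DT
        s = make_series(values)
        out = pp.dilation_speed_filter(s, passes=1, speed_method="forward")
        fwd = [abs(values[i + 1] - values[i]) / DT for i in range(n - 1)]
        d = fwd + [fwd[-1]]
        med = statistics.median(d)
        mad = statistics.median(abs(v - med) for v in d)
        expect = [d[i] <= med + 3 * mad for i in range(n)]
        assert list(out.valid_l) == expect


# ---------------------------------------------------------------------------
# blink detection
# ---------------------------------------------------------------------------

class TestDetectBlinks:
    def _gap_series(self, gap_samples, n=200, start=60):
        valid = np.ones(n, bool)
        valid[start:start + gap_samples] = False
        vals = np.full(n, 4.0)
        vals[~valid] = np.nan
        return pp.PupilSeries(
            t=np.arange(n) * DT, left_mm=vals, right_mm=vals.copy(),
            valid_l=valid.copy(), valid_r=valid.copy(),
        ), valid

    def test_100ms_gap_is_blink_with_padding(self):
        s, valid_before = self._gap_series(30)  # 30 samples = 100 ms
        out = pp.detect_blinks(s)
        assert out.blink_l[60:90].all()
        # 27 ms padding discards exactly 8 samples on each side at 300 Hz
        assert (~out.valid_l[52:60]).all()
        assert out.valid_l[51]
        assert (~out.valid_l[90:98]).all()
        assert out.valid_l[98]

    def test_50ms_gap_not_a_blink(self):
        s, valid_before = self._gap_series(15)  # 50 ms
        out = pp.detect_blinks(s)
        assert not out.blink_l.any()
        assert np.array_equal(out.valid_l, valid_before)

    def test_300ms_gap_not_a_blink(self):
        s, valid_before = self._gap_series(90)  # 300 ms > upper bound
        out = pp.detect_blinks(s)
        assert not out.blink_l.any()
        assert np.array_equal(out.valid_l, valid_before)

    def test_never_unmarks_invalid(self):
        s, valid_before = self._gap_series(30)
        out = pp.detect_blinks(s)
        assert not (out.valid_l & ~valid_before).any()


# ---------------------------------------------------------------------------
# gap interpolation
# ---------------------------------------------------------------------------

class TestInterpolateGaps:
    def test_200ms_interior_gap_linearly_imputed(self):
        n = 200
        valid = np.ones(n, bool)
        valid[100:160] = False  # 60 samples = 200 ms
        vals = np.full(n, 4.0)
        vals[160:] = 5.0
        vals[99] = 4.0
        s = pp.PupilSeries(
            t=np.arange(n) * DT, left_mm=vals.copy(), right_mm=vals.copy(),
            valid_l=valid.copy(), valid_r=valid.copy(),
        )
        out = pp.interpolate_gaps(s)
        assert out.imputed_l[100:160].all()
        imputed = out.left_mm[100:160]
        assert (np.diff(imputed) > 0).all()  # strictly increasing
        assert 4.0 < imputed[0] < imputed[-1] < 5.0

    def test_400ms_gap_left_missing(self):
        n = 300
        valid = np.ones(n, bool)
        valid[100:220] = False  # 120 samples = 400 ms
        vals = np.where(valid, 4.0, np.nan)
        s = pp.PupilSeries(
            t=np.arange(n) * DT, left_mm=vals.copy(), right_mm=vals.copy(),
            valid_l=valid.copy(), valid_r=valid.copy(),
        )
        out = pp.interpolate_gaps(s)
        assert not out.imputed_l.any()
        assert np.isnan(out.left_mm[150])

    def test_edge_gap_left_missing(self):
        valid = np.array([False, False, True, True, True])
        vals = np.where(valid, 4.0, np.nan)
        s = pp.PupilSeries(
            t=np.arange(5) * DT, left_mm=vals.copy(), right_mm=vals.copy(),
            valid_l=valid.copy(), valid_r=valid.copy(),
        )
        out = pp.interpolate_gaps(s)
        assert not out.imputed_l.any()


# ---------------------------------------------------------------------------
# eye averaging, baseline, SEPR, validity
# ---------------------------------------------------------------------------

class TestAverageEyes:
    def test_mean_of_both(self):
        s = make_series([4.0], right=[5.0])
        mono = pp.average_eyes(s)
        assert mono.value_mm[0] == pytest.approx(4.5)

    def test_single_eye_fallback(self):
        s = make_series([4.0], right=[np.nan], valid_r=[False])
        mono = pp.average_eyes(s)
        assert mono.value_mm[0] == pytest.approx(4.0)
        assert mono.usable[0]

    def test_neither_eye_missing(self):
        s = make_series([np.nan], right=[np.nan], valid_l=[False], valid_r=[False])
        mono = pp.average_eyes(s)
        assert not mono.usable[0]

    def test_imputed_counts_as_usable(self):
        s = make_series([4.0], right=[6.0], valid_l=[False])
        s.imputed_l[0] = True
        mono = pp.average_eyes(s)
        assert mono.value_mm[0] == pytest.approx(5.0)


def piecewise_series(n=600):
    """4.0 mm over the baseline window, 4.6 mm over the SEPR window."""
    t = np.arange(n) * DT
    vals = np.full(n, 4.0)
    vals[(t >= 250.0) & (t < 500.0)] = 4.3
    vals[(t >= 500.0) & (t < 1500.0)] = 4.6
    vals[t >= 1500.0] = 4.1
    return pp.MonoSeries(t=t, value_mm=vals, usable=np.ones(n, bool))


class TestBaselineAndSepr:
    def test_constant_series(self):
        mono = pp.MonoSeries(
            t=np.arange(400) * DT, value_mm=np.full(400, 5.0),
            usable=np.ones(400, bool),
        )
        corrected, bps = pp.baseline_correct(mono)
        assert bps == pytest.approx(5.0)
        assert np.allclose(corrected.value_mm, 0.0)

    def test_zero_mean_over_baseline_window_forced(self, rng):
        mono = pp.MonoSeries(
            t=np.arange(600) * DT, value_mm=4.0 + rng.normal(0, 0.3, 600),
            usable=np.ones(600, bool),
        )
        corrected, _bps = pp.baseline_correct(mono)
        mask = (corrected.t >= 0) & (corrected.t < 250)
        assert np.mean(corrected.value_mm[mask]) == pytest.approx(0.0, abs=1e-12)

    def test_piecewise_bps_and_sepr(self):
        corrected, bps = pp.baseline_correct(piecewise_series())
        assert bps == pytest.approx(4.0)
        assert pp.compute_sepr(corrected) == pytest.approx(0.6)

    def test_no_baseline_samples_raises(self):
        mono = pp.MonoSeries(
            t=np.arange(600) * DT, value_mm=np.full(600, 4.0),
            usable=np.zeros(600, bool),
        )
        with pytest.raises(pp.TrialUnusableError):
            pp.baseline_correct(mono)

    def test_sepr_of_constant_corrected(self):
        n = 600
        mono = pp.MonoSeries(
            t=np.arange(n) * DT, value_mm=np.full(n, 0.3),
            usable=np.ones(n, bool),
        )
        assert pp.compute_sepr(mono) == pytest.approx(0.3)

    def test_sepr_missing_when_window_empty(self):
        mono = pp.MonoSeries(
            t=np.arange(60) * DT, value_mm=np.zeros(60), usable=np.ones(60, bool)
        )
        assert np.isnan(pp.compute_sepr(mono))


class TestTrialValidity:
    @pytest.mark.parametrize(
        "n_valid,included", [(49, False), (50, True), (100, True)]
    )
    def test_threshold(self, n_valid, included):
        usable = np.zeros(100, bool)
        usable[:n_valid] = True
        mono = pp.MonoSeries(
            t=np.arange(100) * DT, value_mm=np.full(100, 4.0), usable=usable
        )
        frac, inc = pp.trial_validity(mono)
        assert frac == pytest.approx(n_valid / 100)
        assert inc == included


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

class TestPreprocessTrial:
    def test_clean_synthetic_trial_recovers_tonic_level(self, clean_params, rng):
        from dataclasses import replace

        params = replace(clean_params, pupil_noise_sd_mm=0.0, sepr_trial_sd_mm=0.0)
        series, truth = sd.simulate_pupil_trial(
            params, trial_spec(), sd.SubjectEffects(), rng
        )
        feats = pp.preprocess_trial(series)
        assert feats.included
        # flagged-then-interpolated samples cause only tiny deviations
        assert feats.bps == pytest.approx(truth["true_bps"], abs=0.01)
        assert feats.sepr == pytest.approx(truth["true_sepr"], abs=0.01)

    def test_all_missing_trial_excluded(self):
        n = 600
        s = pp.PupilSeries(
            t=np.arange(n) * DT,
            left_mm=np.full(n, np.nan), right_mm=np.full(n, np.nan),
            valid_l=np.zeros(n, bool), valid_r=np.zeros(n, bool),
        )
        feats = pp.preprocess_trial(s)
        assert not feats.included
        assert np.isnan(feats.bps) and np.isnan(feats.sepr)

    def test_blinked_trial_close_to_blink_free_twin(self, clean_params, rng):
        series, _ = sd.simulate_pupil_trial(
            clean_params, trial_spec(), sd.SubjectEffects(), rng
        )
        twin = series.copy()
        # insert a 100 ms blink at 700 ms in both eyes
        gap = (twin.t >= 700.0) & (twin.t < 800.0)
        twin.left_mm[gap] = np.nan
        twin.right_mm[gap] = np.nan
        twin.valid_l[gap] = False
        twin.valid_r[gap] = False
        a = pp.preprocess_trial(series)
        b = pp.preprocess_trial(twin)
        assert b.included and b.n_blinks == 2  # one run per eye
        assert b.sepr == pytest.approx(a.sepr, abs=0.02)

    def test_filters_never_unmark_invalid(self, rng):
        n = 300
        valid = rng.uniform(size=n) > 0.2
        vals = np.where(valid, rng.uniform(3, 6, n), np.nan)
        s = pp.PupilSeries(
            t=np.arange(n) * DT, left_mm=vals.copy(), right_mm=vals.copy(),
            valid_l=valid.copy(), valid_r=valid.copy(),
        )
        stage1 = pp.range_filter(s)
        stage2 = pp.dilation_speed_filter(stage1)
        stage3 = pp.detect_blinks(stage2)
        for before, after in ((s, stage1), (stage1, stage2), (stage2, stage3)):
            assert not (after.valid_l & ~before.valid_l).any()
            assert not (after.valid_r & ~before.valid_r).any()


class TestBatchEquivalence:
    def test_batch_matches_per_trial_on_messy_cohort(self):
        params = sd.GeneratorParams()  # default blink/spike/noise rates
        recs = sd.simulate_cohort(params, (1, 1, 1), seed=3, blocks=(1,),
                                  with_eeg=False)
        series = [s for r in recs for s in r.pupil if s is not None]
        batch = pp.preprocess_trials(series)
        single = [pp.preprocess_trial(s) for s in series]
        for a, b in zip(batch, single):
            assert np.isclose(a.bps, b.bps, equal_nan=True)
            assert np.isclose(a.sepr, b.sepr, equal_nan=True)
            assert a.valid_fraction == pytest.approx(b.valid_fraction)
            assert a.included == b.included
            assert a.n_blinks == b.n_blinks

    def test_heterogeneous_series_fall_back(self):
        s1 = make_series([4.0] * 100)
        s2 = make_series([4.0] * 80, t=50.0 + np.arange(80) * DT)
        batch = pp.preprocess_trials([s1, s2])
        single = [pp.preprocess_trial(s) for s in (s1, s2)]
        for a, b in zip(batch, single):
            assert np.isclose(a.bps, b.bps, equal_nan=True)

    def test_empty_list(self):
        assert pp.preprocess_trials([]) == []
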