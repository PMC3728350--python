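"""Waveform, nocturnality, alpha, onsets, precision and bout detection."""

import numpy as np
import pytest

import circabehave as cb
from circabehave.errors import InsufficientDataError, ValidationError
from conftest import square_wave_record


class TestAverageWaveform:
    def test_identical_days_have_zero_sem(self, dd):
        rec = square_wave_record(schedule=dd)
        wf = cb.average_waveform(cb.fold_days(rec))
        np.testing.assert_array_equal(wf.mean, rec.counts[:480])
        np.testing.assert_array_equal(wf.sem, np.zeros(480))

    def test_two_day_hand_case(self):
        dm = cb.DayMatrix(np.vstack([np.zeros(480), np.full(480, 2.0)]), 3.0)
        wf = cb.average_waveform(dm)
        np.testing.assert_array_equal(wf.mean, np.ones(480))
        np.testing.assert_array_equal(wf.sem, np.ones(480))

    def test_matches_columnwise_oracle(self):
        rng = np.random.default_rng(2)
        vals = rng.poisson(5, (8, 480)).astype(float)
        wf = cb.average_waveform(cb.DayMatrix(vals, 3.0))
        np.testing.assert_allclose(wf.mean, vals.mean(axis=0))
        np.testing.assert_allclose(wf.sem, vals.std(axis=0, ddof=1) / np.sqrt(8))

    def test_single_day_has_no_sem(self):
        wf = cb.average_waveform(cb.DayMatrix(np.ones((1, 480)), 3.0))
        assert wf.sem is None


class TestNocturnality:
    def test_all_dark_activity_is_100(self, ld):
        rec = square_wave_record(onset_min=720, duration_min=600, schedule=ld)
        assert cb.nocturnality(rec) == pytest.approx(100.0)

    def test_uniform_activity_is_50(self, ld):
        rec = cb.ActivityRecord(np.ones(4800), 3.0, 0.0, ld)
        assert cb.nocturnality(rec) == pytest.approx(50.0)

    def test_nocturnality_plus_diurnality_is_100(self, ld):
        rng = np.random.default_rng(9)
        rec = cb.ActivityRecord(rng.poisson(3, 4800).astype(float), 3.0, 0.0, ld)
        night = cb.nocturnality(rec, per_day=True)
        mask = ld.night_mask(3.0)
        dm = cb.fold_days(rec)
        day_pct = 100.0 * dm.values[:, ~mask].sum(axis=1) / dm.values.sum(axis=1)
        np.testing.assert_allclose(night + day_pct, 100.0)

    def test_zero_activity_day_excluded(self, ld):
        day = np.where(np.arange(480) >= 240, 5.0, 0.0)  # all dark
        counts = np.concatenate([day, np.zeros(480), day])
        rec = cb.ActivityRecord(counts, 3.0, 0.0, ld)
        per_day = cb.nocturnality(rec, per_day=True)
        assert np.isnan(per_day[1])
        assert cb.nocturnality(rec) == pytest.approx(100.0)

    def test_requires_a_dark_window(self, dd):
        rec = cb.ActivityRecord(np.ones(4800), 3.0, 0.0, dd)
        with pytest.raises(ValidationError):
            cb.nocturnality(rec)


class TestActivityRate:
    def test_24_counts_over_24h_is_one(self, dd):
        counts = np.zeros(480)
        counts[::20] = 1.0
        rec = cb.ActivityRecord(counts, 3.0, 0.0, dd)
        assert cb.activity_rate(rec) == pytest.approx(1.0)

    def test_linearity(self, dd):
        rng = np.random.default_rng(4)
        counts = rng.poisson(5, 960).astype(float)
        r1 = cb.activity_rate(cb.ActivityRecord(counts, 3.0, 0.0, dd))
        r2 = cb.activity_rate(cb.ActivityRecord(2 * counts, 3.0, 0.0, dd))
        assert r2 == pytest.approx(2 * r1)

    def test_gap_hours_excluded(self, dd):
        counts = np.ones(480)
        counts[:240] = np.nan
        rec = cb.ActivityRecord(counts, 3.0, 0.0, dd)
        # 240 counts over 12 valid hours
        assert cb.activity_rate(rec) == pytest.approx(20.0)

    def test_all_gap_record_errors(self, dd):
        with pytest.raises(InsufficientDataError):
            cb.activity_rate(cb.ActivityRecord(np.full(480, np.nan), 3.0, 0.0, dd))


class TestAlphaDuration:
    def test_12h_square_wave_gives_720(self, ld):
        wf = cb.average_waveform(cb.fold_days(square_wave_record(schedule=ld)))
        assert cb.alpha_duration(wf) == pytest.approx(720.0)

    def test_sinusoid_above_its_mean_half_the_cycle(self):
        t = (np.arange(480) + 0.5) / 480.0
        wf = cb.DailyWaveform(10.0 + 5.0 * np.sin(2 * np.pi * t), None, 3.0)
        assert cb.alpha_duration(wf) == pytest.approx(720.0)

    def test_flat_waveform_is_arrhythmic_zero(self):
        wf = cb.DailyWaveform(np.full(480, 3.0), None, 3.0)
        assert cb.alpha_duration(wf) == 0.0

    def test_wraps_across_midnight(self):
        m = np.zeros(480)
        m[-40:] = 10.0
        m[:40] = 10.0  # active phase spans ZT 22-02
        wf = cb.DailyWaveform(m, None, 3.0)
        assert cb.alpha_duration(wf) == pytest.approx(240.0)

    def test_invariant_to_additive_and_scaling_transforms(self):
        rng = np.random.default_rng(6)
        m = rng.random(480) * 10
        wf = cb.DailyWaveform(m, None, 3.0)
        a = cb.alpha_duration(wf)
        assert cb.alpha_duration(cb.DailyWaveform(m + 7.3, None, 3.0)) == a
        assert cb.alpha_duration(cb.DailyWaveform(m * 4.2, None, 3.0)) == a

    def test_total_mode_counts_all_suprathreshold_time(self):
        m = np.zeros(480)
        m[0:100] = 10.0
        m[200:300] = 10.0
        wf = cb.DailyWaveform(m, None, 3.0)
        assert cb.alpha_duration(wf, mode="span") == pytest.approx(300.0)
        assert cb.alpha_duration(wf, mode="total") == pytest.approx(600.0)


class TestOnsets:
    def test_square_wave_onset_at_zt12(self, dd):
        dm = cb.fold_days(square_wave_record(schedule=dd))
        np.testing.assert_allclose(cb.detect_onsets(dm), np.full(10, 720.0))

    def test_isolated_noise_bin_tolerated(self, dd):
        rec = square_wave_record(schedule=dd)
        counts = rec.counts.copy()
        counts[2 * 480 + 200] = 10.0  # lone suprathreshold bin at ZT 10, day 2
        dm = cb.fold_days(cb.ActivityRecord(counts, 3.0, 0.0, dd))
        np.testing.assert_allclose(cb.detect_onsets(dm), np.full(10, 720.0))

    def test_arrhythmic_noise_mostly_flagged_absent(self, dd):
        rng = np.random.default_rng(12)
        rec = cb.ActivityRecord(rng.poisson(5, 4800).astype(float), 3.0, 0.0, dd)
        onsets = cb.detect_onsets(cb.fold_days(rec))
        assert np.isnan(onsets).sum() >= 5

    def test_subbin_refinement_recovers_fractional_onset(self, dd):
        # tau 23.98 h: onsets drift by -1.2 min/day, landing inside bins
        params = cb.ActivitySimParams(tau_hours=23.98, alpha_minutes=480.0,
                                      nocturnality_target=None, mean_rate=1200.0)
        rec = cb.simulate_activity(params, dd, n_days=6)
        dm = cb.fold_days(rec)
        expected = 720.0 - 1.2 * np.arange(6)
        coarse = cb.detect_onsets(dm)
        fine = cb.detect_onsets(dm, subbin=True)
        np.testing.assert_allclose(coarse, np.floor(expected / 3.0) * 3.0)
        np.testing.assert_allclose(fine, expected, atol=1e-9)


class TestOnsetPrecision:
    def test_exactly_linear_onsets_give_zero(self):
        onsets = 720.0 - 22.8 * np.arange(10)
        assert cb.onset_precision(onsets % 1440.0) == pytest.approx(0.0, abs=1e-9)

    def test_alternating_pattern_orthogonal_to_line_gives_its_amplitude(self):
        resid = np.tile([10.0, -10.0, -10.0, 10.0], 2)
        onsets = 700.0 + 2.0 * np.arange(8) + resid
        assert cb.onset_precision(onsets) == pytest.approx(10.0)

    def test_matches_direct_regression_oracle(self):
        rng = np.random.default_rng(8)
        days = np.arange(10, dtype=float)
        onsets = 700.0 - 22.8 * days + rng.normal(0, 20, 10)
        a = np.vstack([days, np.ones(10)]).T
        coef, *_ = np.linalg.lstsq(a, onsets, rcond=None)
        expected = np.abs(onsets - a @ coef).mean()
        assert cb.onset_precision(onsets) == pytest.approx(expected, rel=1e-9)

    def test_unwraps_across_midnight(self):
        onsets = (100.0 - 40.0 * np.arange(10)) % 1440.0  # crosses ZT 0
        assert cb.onset_precision(onsets) == pytest.approx(0.0, abs=1e-9)

    def test_too_few_onsets_error(self):
        with pytest.raises(InsufficientDataError, match="insufficient onsets"):
            cb.onset_precision(np.array([700.0, 690.0, np.nan, np.nan]))


def oracle_bouts(counts, bin_min, threshold, max_gap, min_bout):
    """Independent run-length scan over bins (exhaustive, no merging logic)."""
    active = [np.isfinite(c) and c > threshold for c in counts]
    gap_bins = int(max_gap / bin_min)
    bouts, start, last = [], None, None
    for i, a in enumerate(active):
        if not a:
            continue
        if start is None:
            start, last = i, i
        elif i - last - 1 >= gap_bins:
            bouts.append((start, last))
            start, last = i, i
        else:
            last = i
    if start is not None:
        bouts.append((start, last))
    return [(s, e) for s, e in bouts if (e - s + 1) * bin_min >= min_bout]


class TestActivityBouts:
    def _record(self, day, dd, n_days=1):
        return cb.ActivityRecord(np.tile(day, n_days), 3.0, 0.0, dd)

    def test_blocks_separated_by_30min_are_two_bouts(self, dd):
        day = np.zeros(480)
        day[100:120] = 5.0  # 60 min
        day[130:150] = 5.0  # 30-min quiet gap >= maxgap
        table = cb.activity_bouts(self._record(day, dd))
        assert len(table) == 2
        assert list(table["duration_minutes"]) == [60.0, 60.0]

    def test_18min_gap_merges_into_one_bout(self, dd):
        day = np.zeros(480)
        day[100:120] = 5.0
        day[126:146] = 5.0  # 18-min gap < maxgap
        table = cb.activity_bouts(self._record(day, dd))
        assert len(table) == 1
        assert table["duration_minutes"].iloc[0] == pytest.approx(138.0)

    def test_short_isolated_block_discarded(self, dd):
        day = np.zeros(480)
        day[100:105] = 5.0  # 15 min < minimum bout length
        assert len(cb.activity_bouts(self._record(day, dd))) == 0

    def test_matches_run_length_oracle_on_random_records(self, dd):
        rng = np.random.default_rng(42)
        for _ in range(100):
            counts = rng.poisson(0.8, 480).astype(float)
            rec = cb.ActivityRecord(counts, 3.0, 0.0, dd)
            table = cb.activity_bouts(rec)
            expected = oracle_bouts(counts, 3.0, 0.0, 21.0, 21.0)
            got = [
                (int(r.start_minute / 3), int(r.end_minute / 3) - 1)
                for r in table.itertuples()
            ]
            assert got == expected

    def test_fragmentation_is_bouts_per_day(self, dd):
        day = np.zeros(480)
        day[100:120] = 5.0
        day[200:220] = 5.0
        rec = self._record(day, dd, n_days=5)
        assert cb.fragmentation(rec) == pytest.approx(2.0)
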