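import numpy as np
import pandas as pd
import pytest

from somnarc.config import PipelineConfig
from somnarc.detection import (ParticipantUnusable, PowerSeries, ScoreSeries,
                               SleepEpisode, _runs, build_activity_map,
                               detect_sleep_from_power, detect_wrist_off,
                               extract_major_episode, mean_activity_map,
                               minute_power, refine_and_merge, resample_to_grid,
                               score_percentiles, smooth_low_activity,
                               wrist_off_from_minute_sd)
from somnarc.io import RawRecording
from somnarc.synthetic import (CohortModel, generate_minute_power,
                               sample_participant_truth)

TS = pd.Timestamp("2015-06-01", tz="Europe/London")  # a Monday, midnight


def _uniform(xyz, rate=20.0, gap=None):
    from somnarc.detection import UniformRecording
    n = xyz.shape[1]
    return UniformRecording("p", TS, rate, xyz,
                            np.zeros(n, bool) if gap is None else gap)


def _scores(cats):
    return ScoreSeries(TS, np.asarray(cats, dtype=np.int16))


class TestResample:
    def test_on_grid_input_is_identity(self, cfg):
        t = np.arange(2400) / 20.0
        xyz = np.sin(np.arange(2400) * 0.1)[None, :] * np.ones((3, 1))
        rec = RawRecording("p", TS, t, xyz, 20.0)
        uni = resample_to_grid(rec, cfg)
        np.testing.assert_allclose(uni.xyz, xyz, atol=1e-12)
        assert not uni.gap_mask.any()

    def test_linear_ramp_downsampled_exactly(self, cfg):
        t = np.arange(4800) / 40.0
        xyz = np.vstack([0.1 * t, -0.05 * t, 0.02 * t + 1.0])
        rec = RawRecording("p", TS, t, xyz, 40.0)
        uni = resample_to_grid(rec, cfg)
        grid = np.arange(uni.xyz.shape[1]) / 20.0
        np.testing.assert_allclose(uni.xyz[0], 0.1 * grid, atol=1e-9)

    def test_dropout_gap_flagging_matches_brute_force(self, cfg):
        t = np.arange(0, 3600, 1 / 40.0)
        t = t[(t < 1000) | (t >= 1600)]  # 10-min dropout
        rec = RawRecording("p", TS, t, np.zeros((3, t.size)), 40.0)
        uni = resample_to_grid(rec, cfg)
        grid = np.arange(uni.xyz.shape[1]) / 20.0
        brute = np.array([np.min(np.abs(t - g)) > 1.0 for g in grid])
        np.testing.assert_array_equal(uni.gap_mask, brute)
        # a 600-s dropout at 20 Hz, minus the 1-s tolerance at each edge
        assert int(uni.gap_mask.sum()) == 11960

    def test_sub_minute_recording_rejected(self, cfg):
        t = np.arange(100) / 20.0
        rec = RawRecording("p", TS, t, np.zeros((3, 100)), 20.0)
        with pytest.raises(ParticipantUnusable, match="short_record"):
            resample_to_grid(rec, cfg)


class TestWristOff:
    def test_constant_signal_fully_off(self, cfg):
        rng = np.random.default_rng(0)
        xyz = np.ones((3, 20 * 60 * 300)) + rng.normal(0, 1e-5, (3, 20 * 60 * 300))
        worn = detect_wrist_off(_uniform(xyz), cfg)
        assert not worn.worn.any()

    def test_white_noise_fully_worn(self, cfg):
        rng = np.random.default_rng(1)
        xyz = rng.normal(0, 0.05, (3, 20 * 60 * 300))
        worn = detect_wrist_off(_uniform(xyz), cfg)
        assert worn.worn.all()

    def test_six_hour_block_detected_within_window_tolerance(self, cfg):
        """Constant 6-h block inside a worn week: one contiguous off run
        whose length is within one 150-min window of 360 min (brute-force
        windowed-mean oracle)."""
        sd = np.full(8 * 1440, 0.05)
        sd[7 * 1440 + 240: 7 * 1440 + 600] = 1e-4
        off = wrist_off_from_minute_sd(sd, cfg)
        runs = _runs(off)
        assert len(runs) == 1
        start, end = runs[0]
        assert abs((end - start) - 360) <= 150
        assert start >= 7 * 1440  # entirely within day 8
        # brute-force directional means agree
        w = cfg.wristoff_window
        fwd = np.array([sd[i:i + w].mean() for i in range(sd.size)])
        bwd = np.array([sd[max(0, i - w + 1):i + 1].mean() for i in range(sd.size)])
        brute = (fwd < cfg.wristoff_sd_threshold) | (bwd < cfg.wristoff_sd_threshold)
        np.testing.assert_array_equal(off, brute)


class TestMinutePower:
    def test_constant_gravity_minute_has_zero_power(self, cfg):
        xyz = np.tile([[0.1], [-0.2], [0.97]], (1, 20 * 60 * 2))
        uni = _uniform(xyz)
        from somnarc.detection import WornMask
        worn = WornMask(TS, np.ones(2, bool))
        power = minute_power(uni, worn, cfg)
        np.testing.assert_allclose(power.values, 0.0, atol=1e-8)

    def test_unit_sine_power_equals_rms(self, cfg):
        """Integrated periodogram area reproduces the closed-form RMS of
        a unit sine (1/sqrt 2) within 1% - the Parseval check."""
        t = np.arange(20 * 60 * 2) / 20.0
        xyz = np.vstack([np.sin(2 * np.pi * 2.0 * t) + 0.5,
                         np.zeros(t.size), np.ones(t.size)])
        from somnarc.detection import WornMask
        power = minute_power(_uniform(xyz), WornMask(TS, np.ones(2, bool)), cfg)
        np.testing.assert_allclose(power.values, 1 / np.sqrt(2), rtol=0.01)

    def test_power_is_homogeneous_of_degree_one(self, cfg):
        rng = np.random.default_rng(3)
        xyz = rng.normal(0, 0.05, (3, 20 * 60 * 3))
        from somnarc.detection import WornMask
        worn = WornMask(TS, np.ones(3, bool))
        p1 = minute_power(_uniform(xyz), worn, cfg).values
        p2 = minute_power(_uniform(2.0 * xyz), worn, cfg).values
        np.testing.assert_allclose(p2, 2.0 * p1, rtol=1e-9)


class TestScorePercentiles:
    def _power(self, values):
        return PowerSeries(TS, np.asarray(values, dtype=float))

    def test_brute_force_ranking_oracle(self, cfg):
        vals = np.tile(np.arange(1.0, 101.0), 15)  # 1500 worn minutes
        scores = score_percentiles(self._power(vals), cfg)
        expected = (np.ceil(vals / 5.0) * 5).astype(int)
        np.testing.assert_array_equal(scores.categories, expected)

    def test_degenerate_ties_take_lowest_category(self, cfg):
        scores = score_percentiles(self._power(np.ones(1500)), cfg)
        assert (scores.categories == 5).all()

    def test_rank_invariance_under_scaling(self, cfg):
        rng = np.random.default_rng(4)
        vals = rng.lognormal(size=2000)
        s1 = score_percentiles(self._power(vals), cfg)
        s2 = score_percentiles(self._power(vals * 10.0), cfg)
        np.testing.assert_array_equal(s1.categories, s2.categories)

    def test_threshold_fractions_match_nominal_levels(self, cfg):
        rng = np.random.default_rng(5)
        vals = rng.lognormal(size=5000)
        scores = score_percentiles(self._power(vals), cfg)
        for p, thr in scores.thresholds.items():
            frac = (vals <= thr).mean()
            assert abs(frac - p / 100.0) <= 0.02

    def test_too_few_worn_minutes_rejected(self, cfg):
        with pytest.raises(ParticipantUnusable, match="insufficient_worn_minutes"):
            score_percentiles(self._power(np.ones(100)), cfg)


class TestSmoothing:
    def test_all_low_is_fixed_point(self, cfg):
        cand = smooth_low_activity(_scores(np.full(2000, 5)), cfg)
        assert cand.all()

    def test_isolated_low_minute_eliminated(self, cfg):
        cats = np.full(2000, 80)
        cats[1000] = 5
        cand = smooth_low_activity(_scores(cats), cfg)
        assert not cand.any()

    def test_interrupted_block_bridged_to_single_run(self, cfg):
        cats = np.full(2000, 80)
        cats[600:1080] = 5    # 480-min low block
        cats[800:805] = 90    # 5-min interruption
        cand = smooth_low_activity(_scores(cats), cfg)
        runs = _runs(cand)
        assert len(runs) == 1
        start, end = runs[0]
        assert start <= 805 and end >= 1000  # spans the interruption

    def test_passes_never_increase_isolated_run_count(self, cfg):
        """Each smoothing pass is a consolidation: the number of short
        (<10 min) candidate runs never grows."""
        from somnarc.detection import _directional_means
        truth = sample_participant_truth(CohortModel(), 52, "XY",
                                         np.random.default_rng(6),
                                         start_date="2015-06-03")
        mp = generate_minute_power(truth, np.random.default_rng(60))
        scores = score_percentiles(PowerSeries(TS, mp), cfg)
        ind = ((scores.categories >= 0)
               & (scores.categories <= cfg.seed_percentile)).astype(float)

        def short_runs(mask):
            return sum(1 for s, e in _runs(mask) if e - s < 10)

        prev = short_runs(ind.astype(bool))
        for w in cfg.smoothing_windows:
            fwd, bwd = _directional_means(ind, w)
            ind = ((fwd + bwd) / 2.0 >= 0.5).astype(float)
            cur = short_runs(ind.astype(bool))
            assert cur <= prev
            prev = cur


class TestExtraction:
    def test_single_run_selected(self, cfg):
        cand = np.zeros(1440, bool)
        cand[400:800] = True
        ep = extract_major_episode(cand, _scores(np.full(1440, 10)), (0, 1440), cfg)
        assert (ep.onset_idx, ep.wake_idx) == (400, 800)

    def test_longest_run_wins(self, cfg):
        cand = np.zeros(1440, bool)
        cand[100:500] = True   # 400 min
        cand[900:990] = True   # 90 min
        ep = extract_major_episode(cand, _scores(np.full(1440, 10)), (0, 1440), cfg)
        assert (ep.onset_idx, ep.wake_idx) == (100, 500)

    def test_tie_broken_by_lower_mean_category_then_earlier(self, cfg):
        cats = np.full(1440, 80)
        cand = np.zeros(1440, bool)
        cand[100:300] = True
        cand[700:900] = True
        cats[100:300] = 25
        cats[700:900] = 10
        ep = extract_major_episode(cand, _scores(cats), (0, 1440), cfg)
        assert ep.onset_idx == 700  # category-10 run wins the tie
        cats[700:900] = 25
        ep = extract_major_episode(cand, _scores(cats), (0, 1440), cfg)
        assert ep.onset_idx == 100  # exact tie: earlier run

    def test_no_run_reaching_min_bout_flags_night(self, cfg):
        cand = np.zeros(1440, bool)
        cand[100:120] = True
        assert extract_major_episode(cand, _scores(np.full(1440, 10)),
                                     (0, 1440), cfg) is None


class TestRefinement:
    def _episode(self, onset, wake):
        return SleepEpisode(night_index=1, date="", dow="", stage="raw",
                            onset_min=float(onset), wake_min=float(wake),
                            onset_idx=onset, wake_idx=wake)

    def test_fixed_point_unchanged(self, cfg):
        cats = np.full(1440, 80)
        cats[400:800] = 5
        cand = np.zeros(1440, bool)
        cand[400:800] = True
        adj = refine_and_merge(self._episode(400, 800), cand, _scores(cats), cfg)
        assert (adj.onset_idx, adj.wake_idx) == (400, 800)
        assert adj.stage == "adjusted"

    def test_nearby_bout_merged_across_quiet_gap(self, cfg):
        cats = np.full(1440, 80)
        cats[400:800] = 5     # major episode
        cats[800:820] = 20    # 20-min quiet gap (<= 25th percentile)
        cats[820:865] = 5     # 45-min bout
        cand = np.zeros(1440, bool)
        cand[400:800] = True
        cand[820:865] = True
        adj = refine_and_merge(self._episode(400, 800), cand, _scores(cats), cfg)
        assert (adj.onset_idx, adj.wake_idx) == (400, 865)

    def test_loud_gap_not_merged(self, cfg):
        cats = np.full(1440, 80)
        cats[400:800] = 5
        cats[820:865] = 5     # gap minutes stay at 80
        cand = np.zeros(1440, bool)
        cand[400:800] = True
        cand[820:865] = True
        adj = refine_and_merge(self._episode(400, 800), cand, _scores(cats), cfg)
        assert adj.wake_idx == 800

    def test_high_category_boundary_minute_trimmed(self, cfg):
        cats = np.full(1440, 80)
        cats[400:800] = 5
        cats[400] = 75
        cand = np.zeros(1440, bool)
        cand[400:800] = True
        adj = refine_and_merge(self._episode(400, 800), cand, _scores(cats), cfg)
        assert adj.onset_idx == 401

    def test_collapse_keeps_raw_episode_with_flag(self, cfg):
        cats = np.full(1440, 80)  # nothing is quiet: trim eats everything
        cand = np.zeros(1440, bool)
        cand[400:450] = True
        adj = refine_and_merge(self._episode(400, 450), cand, _scores(cats), cfg)
        assert adj.stage == "raw"
        assert "refinement_collapsed" in adj.flags
        assert (adj.onset_idx, adj.wake_idx) == (400, 450)

    def test_adjusted_overlaps_raw(self, study_noisy_small):
        """Episode containment: every adjusted episode overlaps the noon
        window of its night (and thus its raw episode) substantially."""
        nights = study_noisy_small["nights"]
        assert (nights["duration_min"] >= 30).all()
        assert (nights["onset_min"] < 1440).all()


class TestEndToEnd:
    def test_square_wave_schedule_recovered_within_two_minutes(
            self, zero_noise_model, cfg):
        truth = sample_participant_truth(zero_noise_model, 50, "XX",
                                         np.random.default_rng(5),
                                         start_date="2015-06-03")
        mp = generate_minute_power(truth, np.random.default_rng(70),
                                   square_wave=True)
        det = detect_sleep_from_power(PowerSeries(truth.start_time, mp, "p"), cfg)
        assert len(det.episodes) == 7
        for ep in det.episodes:
            assert abs(ep.onset_min - truth.onsets[ep.night_index]) <= 2
            assert abs(ep.wake_min - truth.wakes[ep.night_index]) <= 2

    def test_scale_invariance_of_detected_episodes(self, cfg):
        """Positive rescaling of the power (keeping minutes worn) leaves
        categories, candidates and episodes unchanged."""
        truth = sample_participant_truth(CohortModel(), 55, "XX",
                                         np.random.default_rng(12),
                                         start_date="2015-06-08")
        mp = generate_minute_power(truth, np.random.default_rng(13))
        base = detect_sleep_from_power(PowerSeries(truth.start_time, mp, "p"), cfg)
        for c in (3.0, 10.0):
            scaled = detect_sleep_from_power(
                PowerSeries(truth.start_time, mp * c, "p"), cfg)
            assert [(e.onset_idx, e.wake_idx) for e in scaled.episodes] \
                == [(e.onset_idx, e.wake_idx) for e in base.episodes]

    def test_eight_day_recording_yields_seven_night_windows(self, cfg):
        truth = sample_participant_truth(CohortModel(), 48, "XY",
                                         np.random.default_rng(14),
                                         start_date="2015-06-08")
        mp = generate_minute_power(truth, np.random.default_rng(15))
        det = detect_sleep_from_power(PowerSeries(truth.start_time, mp, "p"), cfg)
        assert det.n_nights_expected == 7


class TestActivityMap:
    def test_constant_power_gives_unit_grid(self, cfg):
        power = PowerSeries(TS, np.ones(8 * 1440))
        grid = build_activity_map(power, cfg)
        assert grid.shape == (7, 1440)
        np.testing.assert_allclose(grid.to_numpy(), 1.0)

    def test_monday_morning_activity_lands_in_monday_row(self, cfg):
        values = np.zeros(8 * 1440)
        # Mondays 06:00-07:00; only June 8 has a complete 18:00 window
        for day in (0, 7):
            values[day * 1440 + 360: day * 1440 + 420] = 1.0
        grid = build_activity_map(PowerSeries(TS, values), cfg)
        assert int((grid.loc["Mon"] > 0).sum()) == 60
        others = grid.drop(index="Mon").to_numpy()
        assert np.nansum(others) == 0.0

    def test_cohort_map_is_mean_of_individual_maps(self, cfg):
        g1 = build_activity_map(PowerSeries(TS, np.ones(8 * 1440)), cfg)
        g2 = build_activity_map(PowerSeries(TS, 3.0 * np.ones(8 * 1440)), cfg)
        merged = mean_activity_map([g1, g2])
        np.testing.assert_allclose(merged.to_numpy(), 2.0)
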