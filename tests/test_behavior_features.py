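"""Epoch detection, per-frame features, and behavioral summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from freezecalc import behavior_features as bf
from freezecalc.exceptions import AlignmentError, ConfigError

from conftest import make_session
from oracles import brute_epoch_table, random_session_velocity


class TestDetectEpochs:
    def test_all_still_session_is_one_freeze_epoch(self):
        session = make_session(np.zeros(100))
        table = bf.detect_epochs(session)
        assert len(table.df) == 1
        row = table.df.iloc[0]
        assert (row["kind"], row["start"], row["end"]) == ("freeze", 0, 100)

    def test_eleven_still_frames_are_discarded_not_freezing(self):
        # 11 sub-threshold frames flanked by running stay below the
        # 12-frame minimum and must be discarded
        v = np.concatenate([np.full(20, 10.0), np.zeros(11), np.full(20, 10.0)])
        table = bf.detect_epochs(make_session(v))
        assert table.frames_of("freeze") == 0
        discarded = table.epochs_of("discarded")
        assert len(discarded) == 1
        assert (discarded.iloc[0]["start"], discarded.iloc[0]["end"]) == (20, 31)

    def test_twelve_still_frames_are_freezing(self):
        v = np.concatenate([np.full(20, 10.0), np.zeros(12), np.full(20, 10.0)])
        table = bf.detect_epochs(make_session(v))
        assert table.frames_of("freeze") == 12

    def test_single_above_threshold_frame_is_discarded(self):
        v = np.concatenate([np.zeros(20), [5.0], np.zeros(20)])
        table = bf.detect_epochs(make_session(v))
        assert table.frames_of("run") == 0
        assert table.frames_of("discarded") == 1

    def test_backtracking_detected_from_sustained_negative_velocity(self):
        v = np.concatenate([np.full(10, 5.0), np.full(5, -3.0), np.full(10, 5.0)])
        table = bf.detect_epochs(make_session(v))
        assert table.frames_of("backtrack") == 5

    def test_teleport_frames_never_enter_behavioral_states(self):
        v = np.full(40, 10.0)
        teleport = np.zeros(40, bool)
        teleport[15:25] = True
        v[15:25] = 0.0
        table = bf.detect_epochs(make_session(v, teleport))
        assert table.frames_of("teleport") == 10
        assert table.frames_of("freeze") == 0

    def test_empty_session_raises(self):
        with pytest.raises(ConfigError):
            bf.detect_epochs(make_session(np.empty(0)))

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_exhaustive_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 2000))
        velocity, teleport = random_session_velocity(rng, n)
        table = bf.detect_epochs(make_session(velocity, teleport))
        got = [tuple(r) for r in table.df[["kind", "start", "end"]].itertuples(index=False)]
        assert got == brute_epoch_table(velocity, teleport)

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_partition_invariant_on_random_sessions(self, seed):
        # every frame belongs to exactly one epoch and kinds cover the session
        rng = np.random.default_rng(seed)
        velocity, teleport = random_session_velocity(rng, 400)
        table = bf.detect_epochs(make_session(velocity, teleport))
        table.validate()
        assert sum(table.frames_of(k) for k in bf.EPOCH_KINDS) == 400


class TestFrameFeatures:
    def test_progress_is_zero_at_start_and_one_at_end_of_each_epoch(self):
        v = np.concatenate([np.zeros(13), np.full(10, 5.0), np.zeros(20)])
        session = make_session(v)
        table = bf.detect_epochs(session)
        feats = bf.compute_frame_features(session, table)
        for row in table.epochs_of("freeze").itertuples():
            assert feats["freeze_progress"].iloc[row.start] == 0.0
            assert feats["freeze_progress"].iloc[row.end - 1] == 1.0
        for row in table.epochs_of("run").itertuples():
            assert feats["running_progress"].iloc[row.start] == 0.0
            assert feats["running_progress"].iloc[row.end - 1] == 1.0

    def test_midpoint_of_13_frame_freeze_has_progress_half(self):
        v = np.concatenate([np.full(5, 5.0), np.zeros(13), np.full(5, 5.0)])
        session = make_session(v)
        feats = bf.compute_frame_features(session, bf.detect_epochs(session))
        assert feats["freeze_progress"].iloc[5 + 6] == pytest.approx(0.5)

    def test_elapsed_plus_remaining_is_length_minus_one(self):
        v = np.concatenate([np.zeros(20), np.full(15, 5.0)])
        session = make_session(v)
        feats = bf.compute_frame_features(session, bf.detect_epochs(session))
        freeze = feats.iloc[:20]
        assert (freeze["freeze_elapsed"] + freeze["freeze_remaining"] == 19).all()

    def test_interval_elapsed_resets_at_state_switches(self):
        v = np.concatenate([np.zeros(15), np.full(10, 5.0), np.zeros(15)])
        session = make_session(v)
        feats = bf.compute_frame_features(session, bf.detect_epochs(session))
        assert feats["interval_elapsed"].iloc[15] == 0.0  # freeze -> run
        assert feats["interval_elapsed"].iloc[25] == 0.0  # run -> freeze
        assert feats["interval_elapsed"].iloc[14] == 14.0

    def test_velocity_offsets_are_index_shifts_for_interior_frames(self):
        v = np.arange(1.0, 61.0)
        session = make_session(v)
        feats = bf.compute_frame_features(session, bf.detect_epochs(session))
        inner = slice(20, 40)
        assert np.array_equal(feats["velocity_fwd_8"].to_numpy()[inner], v[28:48])
        assert np.array_equal(feats["velocity_back_15"].to_numpy()[inner], v[5:25])
        # boundary frames hold the mean of the 15 edge frames
        assert feats["velocity_fwd_15"].iloc[-1] == pytest.approx(v[-15:].mean())

    def test_acceleration_is_first_difference_times_frame_rate(self):
        v = np.concatenate([np.full(10, 2.0), np.full(10, 6.0)])
        session = make_session(v)
        feats = bf.compute_frame_features(session, bf.detect_epochs(session))
        assert feats["acceleration"].iloc[10] == pytest.approx(4.0 * 15.49)
        assert feats["acceleration"].iloc[5] == 0.0

    def test_postfreeze_marks_the_epoch_after_a_freeze(self):
        v = np.concatenate([np.zeros(15), np.full(10, 5.0), np.full(10, 5.0)])
        session = make_session(v)
        feats = bf.compute_frame_features(session, bf.detect_epochs(session))
        assert feats["is_postfreeze"].iloc[15:25].all()
        assert not feats["is_postfreeze"].iloc[:15].any()

    def test_feature_matrix_columns_and_finiteness(self, tuned_bundle):
        feats = bf.compute_frame_features(tuned_bundle["session"], tuned_bundle["epochs"])
        assert list(feats.columns) == bf.FEATURE_COLUMNS
        assert np.isfinite(feats.to_numpy()).all()
        for col in ("freeze_progress", "running_progress", "interval_progress"):
            assert feats[col].between(0, 1).all()


class TestSummaries:
    def test_percent_time_freezing_limits(self):
        all_freeze = bf.detect_epochs(make_session(np.zeros(50)))
        assert bf.percent_time_freezing(all_freeze) == 100.0
        all_run = bf.detect_epochs(make_session(np.full(50, 5.0)))
        assert bf.percent_time_freezing(all_run) == 0.0

    def test_percent_time_freezing_half_split(self):
        v = np.concatenate([np.zeros(50), np.full(50, 5.0)])
        assert bf.percent_time_freezing(bf.detect_epochs(make_session(v))) == 50.0

    def test_percent_time_freezing_excludes_teleport_frames(self):
        v = np.concatenate([np.zeros(50), np.full(25, 5.0), np.zeros(25)])
        teleport = np.zeros(100, bool)
        teleport[75:] = True
        table = bf.detect_epochs(make_session(v, teleport))
        assert bf.percent_time_freezing(table) == pytest.approx(100 * 50 / 75)

    def test_baseline_delta_is_plain_subtraction(self):
        assert bf.baseline_delta(40, 10) == 30
        assert bf.baseline_delta(10, 10) == 0
        assert bf.baseline_delta(5, 10) == -5

    def test_relative_change_arithmetic(self):
        assert bf.relative_change(10, 10) == 0.0
        assert bf.relative_change(10, 25) == 150.0
        with pytest.raises(ConfigError):
            bf.relative_change(0, 5)

    def test_freeze_length_stats_in_seconds(self):
        v = np.concatenate([np.zeros(31), np.full(10, 5.0)])
        stats = bf.freeze_length_stats(bf.detect_epochs(make_session(v)))
        assert stats.count == 1
        assert stats.mean_s == pytest.approx(31 / 15.49, abs=1e-9)

    def test_freeze_length_stats_empty_signal(self):
        stats = bf.freeze_length_stats(bf.detect_epochs(make_session(np.full(50, 5.0))))
        assert stats.count == 0
        assert np.isnan(stats.mean_s)


class TestDiscriminationIndex:
    def test_symmetric_inputs_give_zero(self):
        assert bf.discrimination_index(50, 50) == 0.0

    def test_one_sided_freezing_gives_unity(self):
        assert bf.discrimination_index(30, 0) == 1.0

    def test_undefined_when_no_freezing(self):
        with pytest.raises(ConfigError):
            bf.discrimination_index(0, 0)

    @given(
        st.floats(0, 100, allow_nan=False),
        st.floats(0, 100, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_antisymmetric_and_bounded(self, a, b):
        if a + b == 0:
            return
        di = bf.discrimination_index(a, b)
        assert -1.0 <= di <= 1.0
        assert di == pytest.approx(-bf.discrimination_index(b, a))


class TestCleanPupil:
    def test_no_blinks_returns_smoothed_resampled_input(self):
        n = 300
        area = 50 + np.sin(np.linspace(0, 4 * np.pi, n))
        blink = np.full(n, 10.0)  # steady blink area: the 2sd rule fires nowhere
        out = bf.clean_pupil(area, area * 0, area * 0, blink, source_rate_hz=15.49)
        assert not out["blink_mask"].any()
        assert len(out["area"]) == n
        assert np.allclose(out["area"], area, atol=0.05)

    def test_constant_area_with_one_blink_stays_constant(self):
        n = 200
        area = np.full(n, 40.0)
        blink = np.full(n, 10.0)
        blink[100:103] = 1.0
        out = bf.clean_pupil(area, area * 0, area * 0, blink, source_rate_hz=15.49)
        assert np.allclose(out["area"], 40.0)

    def test_inserted_blinks_are_flagged_by_the_2sd_rule(self):
        rng = np.random.default_rng(1)
        n = 400
        blink = 10 + rng.normal(0, 0.3, n)
        blink[50:53] = 2.0
        blink[300:304] = 2.0
        mask = bf.blink_mask(blink)
        assert mask[50:53].all() and mask[300:304].all()
        expected = blink < blink.mean() - 2 * blink.std()
        assert np.array_equal(mask, expected)

    def test_misaligned_traces_raise(self):
        with pytest.raises(AlignmentError):
            bf.clean_pupil(np.ones(50), np.zeros(40), np.zeros(50), np.ones(50), 15.49)


def test_feature_matrix_rejects_mismatched_epoch_table(tuned_bundle):
    short = make_session(np.full(100, 5.0))
    with pytest.raises(AlignmentError):
        bf.compute_frame_features(short, tuned_bundle["epochs"])
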