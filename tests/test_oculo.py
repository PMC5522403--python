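"""Gaze calibration, saccade detection and trial scoring."""

import math

import numpy as np
import pytest

from topomem import oculo, synth
from topomem.oculo import (CalibrationModel, GazeTrace, ScoreConfig,
                           TrialEvents, apply_calibration, detect_saccades,
                           exclusion_summary, fit_calibration, read_asc,
                           read_gaze_csv, score_session, score_trial,
                           scores_to_frame, velocity_trace, write_asc,
                           write_gaze_csv)


def grid_points(n_side, span=8.0):
    v = np.linspace(-span, span, n_side)
    return np.array([(x, y) for x in v for y in v])


class TestCalibration:
    def test_identity_mapping_recovered(self):
        pts = grid_points(4)
        model = fit_calibration(pts, pts)
        assert model.residual_rms < 1e-9
        x, y = model(pts[:, 0], pts[:, 1])
        np.testing.assert_allclose(np.column_stack([x, y]), pts, atol=1e-9)

    def test_known_cubic_distortion_recovered_on_held_out_points(self):
        def distort(p):
            x, y = p[:, 0], p[:, 1]
            return np.column_stack([
                1.2 * x + 0.01 * x ** 3 + 0.002 * x * y ** 2 + 0.5,
                0.9 * y - 0.004 * y ** 3 + 0.003 * x ** 2 * y - 0.2])

        raw_train = grid_points(4)
        model = fit_calibration(raw_train, distort(raw_train))
        raw_held_out = grid_points(5, span=6.0)
        x, y = model(raw_held_out[:, 0], raw_held_out[:, 1])
        np.testing.assert_allclose(np.column_stack([x, y]),
                                   distort(raw_held_out), atol=1e-6)

    def test_nine_point_grid_uses_reduced_model(self):
        pts = grid_points(3)
        model = fit_calibration(pts * 1.1 + 0.3, pts)
        assert model.reduced
        assert model.residual_rms < 1e-9

    def test_collinear_points_rejected(self):
        x = np.linspace(-5, 5, 12)
        pts = np.column_stack([x, 2 * x])  # all on one line
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_calibration(pts, pts)

    def test_calibration_idempotent_on_degree_valued_trace(self):
        pts = grid_points(4)
        model = fit_calibration(pts, pts)
        t = np.arange(200.0)
        trace = GazeTrace(t, np.linspace(-3, 3, 200), np.linspace(2, -2, 200))
        out = apply_calibration(trace, model)
        assert np.abs(out.x - trace.x).max() < 1e-9
        assert np.abs(out.y - trace.y).max() < 1e-9


class TestVelocity:
    def test_stationary_gaze_has_near_zero_speed(self):
        t = np.arange(500.0)
        speed = velocity_trace(GazeTrace(t, np.zeros(500), np.zeros(500)))
        assert speed.max() < 1e-9

    def test_constant_drift_speed(self):
        t = np.arange(1000.0)
        trace = GazeTrace(t, 0.01 * t, np.zeros(1000))  # 10 deg/s in x
        speed = velocity_trace(trace)
        np.testing.assert_allclose(speed[20:-20], 10.0, rtol=1e-6)

    def test_peak_velocity_of_synthetic_saccade(self):
        # raised-cosine displacement: peak velocity = 2 A / D
        t = np.arange(800.0)
        pos = np.zeros((800, 2))
        amp, dur = 10.0, 64.0
        synth._add_movement(pos, t, 300.0, np.array([amp, 0.0]), dur)
        speed = velocity_trace(GazeTrace(t, pos[:, 0], pos[:, 1]))
        expected_peak = 2 * amp / dur * 1000.0  # deg/s
        assert speed.max() == pytest.approx(expected_peak, rel=0.05)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            velocity_trace(GazeTrace(np.arange(3.0), np.zeros(3), np.zeros(3)))


class TestDetection:
    def test_fixation_noise_produces_no_events(self):
        rng = np.random.default_rng(0)
        t = np.arange(3000.0)
        noise = synth._band_limited_noise(rng, 3000, 0.1, 20)
        trace = GazeTrace(t, noise[:, 0], noise[:, 1])
        assert detect_saccades(trace, min_amplitude=1.0) == []

    def test_single_saccade_detected_with_correct_amplitude(self):
        t = np.arange(1000.0)
        pos = np.zeros((1000, 2))
        synth._add_movement(pos, t, 400.0, np.array([10.0, 0.0]),
                            synth.main_sequence_duration_ms(10.0))
        events = detect_saccades(GazeTrace(t, pos[:, 0], pos[:, 1]),
                                 min_amplitude=1.0)
        assert len(events) == 1
        assert events[0].amplitude == pytest.approx(10.0, abs=0.2)
        assert events[0].onset_ms == pytest.approx(400.0, abs=6.0)

    def test_primary_then_corrective_detected_in_order(self):
        t = np.arange(1500.0)
        pos = np.zeros((1500, 2))
        synth._add_movement(pos, t, 400.0, np.array([10.0, 0.0]),
                            synth.main_sequence_duration_ms(10.0))
        synth._add_movement(pos, t, 600.0, np.array([-1.5, 0.0]),
                            synth.main_sequence_duration_ms(1.5))
        events = detect_saccades(GazeTrace(t, pos[:, 0], pos[:, 1]),
                                 min_amplitude=0.5)
        assert len(events) == 2
        assert events[0].amplitude == pytest.approx(10.0, abs=0.3)
        assert events[1].amplitude == pytest.approx(1.5, abs=0.3)
        assert events[0].onset_ms < events[1].onset_ms


def make_trial(planted=None, seed=0, **kwargs):
    cfg = synth.SaccadeSimConfig(**kwargs)
    rng = np.random.default_rng(seed)
    target = (10 * math.cos(math.radians(35)), 10 * math.sin(math.radians(35)))
    return synth.simulate_trial(cfg, target, planted=planted, rng=rng,
                                trial_id=f"{planted}-{seed}")


class TestScoreTrial:
    def test_euclidean_error_from_known_endpoint(self):
        # noiseless trial, endpoint forced 1 deg off in each axis
        t = np.arange(6000.0)
        pos = np.zeros((6000, 2))
        target = (10.0 * math.cos(math.radians(30)),
                  10.0 * math.sin(math.radians(30)))
        end = np.array([target[0] - 1.0, target[1] + 1.0])
        synth._add_movement(pos, t, 5000.0, end,
                            synth.main_sequence_duration_ms(10.0))
        ev = TrialEvents(target_x=target[0], target_y=target[1],
                         target_onset_ms=500, cue_ms=4700, feedback_ms=5500)
        score = score_trial(GazeTrace(t, pos[:, 0], pos[:, 1], events=ev))
        assert not score.excluded
        assert score.mgs_error == pytest.approx(math.sqrt(2), abs=0.05)
        assert score.fep_error == pytest.approx(math.sqrt(2), abs=0.05)

    @pytest.mark.parametrize("planted,reason", [
        ("rt_long", "rt_long"),
        ("rt_short", "rt_short"),
        ("fixation_break", "fixation_break"),
    ])
    def test_planted_violations_recovered(self, planted, reason):
        trace, truth = make_trial(planted=planted, seed=3)
        score = score_trial(trace)
        assert score.excluded
        assert score.reason == reason

    def test_scored_values_match_generator_truth(self):
        trace, truth = make_trial(seed=11)
        score = score_trial(trace)
        assert not score.excluded
        assert score.srt_ms == pytest.approx(truth.srt_ms, abs=10)
        assert score.mgs_error == pytest.approx(truth.mgs_error, abs=0.25)
        assert score.fep_error == pytest.approx(truth.fep_error, abs=0.25)

    def test_missing_marker_named_in_error(self):
        trace, _ = make_trial(seed=2)
        trace.events.cue_ms = np.nan
        with pytest.raises(ValueError, match="cue_ms"):
            score_trial(trace)

    def test_scoring_is_deterministic(self):
        trace, _ = make_trial(seed=5)
        assert score_trial(trace) == score_trial(trace)

    def test_long_blink_in_response_window_excludes_trial(self):
        trace, _ = make_trial(seed=7)
        cue = trace.events.cue_ms
        sel = (trace.time_ms > cue + 100) & (trace.time_ms < cue + 300)
        trace.x[sel] = np.nan
        trace.y[sel] = np.nan
        score = score_trial(trace)
        assert score.excluded and score.reason == "no_saccade"

    def test_short_blink_is_interpolated(self):
        trace, truth = make_trial(seed=7)
        t0 = trace.events.target_onset_ms + 500
        sel = (trace.time_ms > t0) & (trace.time_ms < t0 + 30)
        trace.x[sel] = np.nan
        trace.y[sel] = np.nan
        score = score_trial(trace)
        assert not score.excluded


class TestScoreSession:
    def test_planted_violation_counts(self):
        traces = []
        plants = ["rt_long"] * 2 + ["rt_short"] + ["fixation_break"] * 2 + [None] * 25
        for i, p in enumerate(plants):
            tr, _ = make_trial(planted=p, seed=100 + i)
            tr.trial_id = i
            traces.append(tr)
        scores = score_session(traces)
        summary = exclusion_summary(scores)
        assert summary["included"] == 25
        assert summary["rt_long"] == 2
        assert summary["rt_short"] == 1
        assert summary["fixation_break"] == 2

    def test_all_clean_run_has_zero_exclusions(self):
        traces = []
        for i in range(10):
            tr, _ = make_trial(seed=200 + i)
            tr.trial_id = i
            traces.append(tr)
        scores = score_session(traces)
        assert exclusion_summary(scores)["included"] == 10

    def test_all_fixation_breaks_yield_empty_included_set(self):
        traces = []
        for i in range(5):
            tr, _ = make_trial(planted="fixation_break", seed=300 + i)
            tr.trial_id = i
            traces.append(tr)
        scores = score_session(traces)
        assert all(s.excluded for s in scores)
        frame = scores_to_frame(scores)
        assert frame["mgs_error"].isna().all()

    def test_duplicate_trial_ids_rejected(self):
        tr1, _ = make_trial(seed=1)
        tr2, _ = make_trial(seed=2)
        tr2.trial_id = tr1.trial_id
        with pytest.raises(ValueError, match="duplicate"):
            score_session([tr1, tr2])


class TestIO:
    def make_traces(self, n=3):
        traces = []
        for i in range(n):
            tr, _ = make_trial(seed=400 + i)
            tr.trial_id = i
            tr.subject = "s00"
            traces.append(tr)
        return traces

    def test_asc_round_trip_preserves_scoring(self, tmp_path):
        traces = self.make_traces()
        path = str(tmp_path / "run.asc")
        write_asc(traces, path)
        back = read_asc(path)
        assert len(back) == len(traces)
        for a, b in zip(traces, back):
            sa, sb = score_trial(a), score_trial(b)
            assert sa.excluded == sb.excluded
            assert sb.mgs_error == pytest.approx(sa.mgs_error, abs=1e-3)
            assert sb.srt_ms == pytest.approx(sa.srt_ms, abs=1.0)

    def test_csv_round_trip(self, tmp_path):
        traces = self.make_traces()
        sp, ep = str(tmp_path / "samples.csv"), str(tmp_path / "events.csv")
        write_gaze_csv(traces, sp, ep)
        back = read_gaze_csv(sp, ep)
        assert len(back) == len(traces)
        np.testing.assert_allclose(back[0].x, traces[0].x, atol=1e-6)
        assert back[0].events.cue_ms == traces[0].events.cue_ms
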