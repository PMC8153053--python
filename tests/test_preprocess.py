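import numpy as np
import pandas as pd
import pytest

from gazemem import preprocess as pp
from gazemem import synthetic as syn
from gazemem.geometry import GOGGLES_EXP1
from gazemem.types import GazeRecording


def make_recording(x, y, ar=None, fs=60.0):
    n = len(x)
    return GazeRecording(
        "s0",
        fs,
        pd.DataFrame(
            {
                "t_ms": np.arange(n) * 1000.0 / fs,
                "x_px": x,
                "y_px": y,
                "aspect_ratio": ar if ar is not None else np.full(n, 0.85),
                "trial_id": 0,
            }
        ),
        GOGGLES_EXP1,
    )


class TestCorrectDrift:
    def test_constant_signal_unchanged(self):
        rec = make_recording(np.full(500, 400.0), np.full(500, 300.0))
        out = pp.correct_drift(rec, 101)
        np.testing.assert_allclose(out.samples["x_px"], 400.0)
        np.testing.assert_allclose(out.samples["y_px"], 300.0)

    def test_even_window_rejected(self):
        rec = make_recording(np.zeros(10), np.zeros(10))
        with pytest.raises(ValueError, match="window_samples"):
            pp.correct_drift(rec, 100)

    def test_too_short_recording_rejected(self):
        rec = make_recording(np.zeros(1), np.zeros(1))
        with pytest.raises(ValueError, match="2 samples"):
            pp.correct_drift(rec)

    def test_default_window_spans_55_seconds_at_60hz(self):
        assert pp.DRIFT_WINDOW_SAMPLES / 60.0 == pytest.approx(55.0, abs=0.02)

    def test_linear_session_drift_removed(self):
        # adding a zero-median linear drift of 3 deg per session and
        # correcting must reproduce the corrected drift-free recording to
        # within 0.2 deg RMS away from the window edges
        cfg = syn.SimConfig(
            fixation_jitter_deg=0.2, drift_step_deg=0.0, blink_prob_per_trial=0.0
        )
        rng = np.random.default_rng(3)
        layouts = [syn.generate_aoi_layout(f"p{i}", 4, rng) for i in range(80)]
        rec, _ = syn.generate_gaze_recording(cfg, layouts, rng)
        n = len(rec.samples)
        jx, _ = cfg.geometry.deg_per_px()
        drifted = rec.samples.copy()
        drifted["x_px"] = drifted["x_px"] + np.linspace(-1.5, 1.5, n) / jx
        corr_d = pp.correct_drift(GazeRecording("s0", 60.0, drifted, cfg.geometry))
        corr_0 = pp.correct_drift(rec)
        core = slice(1650, n - 1650)
        diff = (
            corr_d.samples["x_px"].to_numpy()[core]
            - corr_0.samples["x_px"].to_numpy()[core]
        ) * jx
        # the time-varying drift component must be gone; a small constant
        # re-centering offset (median ambiguity) is allowed
        diff = diff - diff.mean()
        assert np.sqrt(np.mean(diff**2)) < 0.2

    def test_overall_median_position_preserved(self):
        rng = np.random.default_rng(0)
        x = 400 + np.cumsum(rng.normal(0, 2, 2000))
        rec = make_recording(x, np.full(2000, 300.0))
        out = pp.correct_drift(rec, 301)
        assert np.median(out.samples["x_px"]) == pytest.approx(np.median(x), abs=1.0)


class TestDetectFixations:
    def test_recovers_injected_fixations_and_centroids(self, clean_cfg, layout):
        rng = np.random.default_rng(0)
        rec, truth = syn.generate_gaze_recording(
            clean_cfg, [layout] * 5, rng, n_fixations_per_trial=4
        )
        events = pp.detect_fixations(rec)
        for tid in range(5):
            det = [e for e in events if e.trial_id == tid]
            true = truth.fixations[truth.fixations["trial_id"] == tid]
            assert len(det) == 4
            for e, (_, t) in zip(det, true.iterrows()):
                assert abs(e.centroid_deg[0] - t["x_deg"]) < 0.1
                assert abs(e.centroid_deg[1] - t["y_deg"]) < 0.1

    def test_sub_100ms_candidate_discarded(self, clean_cfg):
        # an 80 ms plateau flanked by saccades does not survive the
        # minimum-duration filter
        rng = np.random.default_rng(1)
        targets = [(0.0, 0.0), (8.0, 0.0), (0.0, 8.0)]
        samples, _, _ = syn.render_trial(clean_cfg, targets, [1100.0, 80.0, 1100.0], rng)
        rec = GazeRecording("s0", 60.0, samples, clean_cfg.geometry)
        events = pp.detect_fixations(rec)
        assert len(events) == 2

    def test_100ms_boundary_is_kept_not_discarded(self):
        # the duration rule is strictly "shorter than 100 ms": a candidate
        # run of exactly 6 samples at 60 Hz (100 ms) survives, 5 samples
        # (83 ms) does not
        kept = make_recording(np.full(6, 400.0), np.full(6, 300.0))
        assert len(pp.detect_fixations(kept)) == 1
        too_short = make_recording(np.full(5, 400.0), np.full(5, 300.0))
        assert pp.detect_fixations(too_short) == []

    def test_constant_position_yields_single_fixation(self):
        rec = make_recording(np.full(150, 400.0), np.full(150, 300.0))
        events = pp.detect_fixations(rec)
        assert len(events) == 1
        assert events[0].duration_ms == pytest.approx(150 * 1000 / 60)

    def test_short_trial_warns_and_returns_nothing(self):
        rec = make_recording(np.full(3, 400.0), np.full(3, 300.0))
        with pytest.warns(UserWarning, match="shorter than 5 samples"):
            assert pp.detect_fixations(rec) == []

    def test_events_ordered_and_nonoverlapping(self, noisy_cfg, layout):
        rng = np.random.default_rng(9)
        rec, _ = syn.generate_gaze_recording(noisy_cfg, [layout] * 10, rng)
        events = pp.detect_fixations(pp.correct_drift(rec))
        for tid in range(10):
            det = [e for e in events if e.trial_id == tid]
            for a, b in zip(det[:-1], det[1:]):
                assert b.onset_ms >= a.offset_ms - 1e-9

    def test_lowering_lambda_never_decreases_saccade_samples(self, noisy_cfg, layout):
        rng = np.random.default_rng(10)
        rec, _ = syn.generate_gaze_recording(noisy_cfg, [layout] * 4, rng)
        tr = rec.trial_samples(0)
        x, y = rec.geometry.px_to_deg(
            tr["x_px"].to_numpy(float), tr["y_px"].to_numpy(float)
        )
        vx, vy = pp.sample_velocities(np.asarray(x), np.asarray(y), rec.dt_ms / 1000)
        sx, sy = pp.robust_sd(vx), pp.robust_sd(vy)
        counts = []
        for lam in (12.0, 8.0, 6.0, 4.0, 2.0, 1.0):
            above = (vx / (lam * sx)) ** 2 + (vy / (lam * sy)) ** 2 > 1
            counts.append(int(above.sum()))
        assert counts == sorted(counts)

    def test_agrees_with_exhaustive_run_scanner_on_short_trials(self, noisy_cfg, layout):
        # brute-force oracle: same velocity + threshold definitions, but
        # event boundaries found by explicit run enumeration
        rng = np.random.default_rng(11)
        params = pp.VelocityParams()
        for rep in range(10):
            rec, _ = syn.generate_gaze_recording(noisy_cfg, [layout], rng)
            short = GazeRecording(
                "s0", 60.0, rec.samples.iloc[:50].copy(), rec.geometry
            )
            events = pp.detect_fixations(short, params)
            oracle = brute_force_fixations(short, params)
            assert [(e.onset_ms, e.offset_ms) for e in events] == oracle


def brute_force_fixations(rec, params):
    """Independent exhaustive scanner over all sample runs."""
    tr = rec.trial_samples(0)
    x, y = rec.geometry.px_to_deg(tr["x_px"].to_numpy(float), tr["y_px"].to_numpy(float))
    vx, vy = pp.sample_velocities(np.asarray(x), np.asarray(y), rec.dt_ms / 1000)
    valid = tr["aspect_ratio"].to_numpy(float) >= 0.5
    sx = pp.robust_sd(vx[valid])
    sy = pp.robust_sd(vy[valid])
    if sx <= 0 or sy <= 0:
        sx = max(sx, params.velocity_floor_deg_s / params.lambda_multiplier)
        sy = max(sy, params.velocity_floor_deg_s / params.lambda_multiplier)
    lam = params.lambda_multiplier
    above = [
        bool(((a / (lam * sx)) ** 2 + (b / (lam * sy)) ** 2 > 1) and v)
        for a, b, v in zip(vx, vy, valid)
    ]
    n = len(above)
    sac = [False] * n
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= params.min_saccade_samples:
                for k in range(i, j):
                    sac[k] = True
            i = j
        else:
            i += 1
    t = tr["t_ms"].to_numpy(float)
    out = []
    i = 0
    while i < n:
        if not sac[i]:
            j = i
            while j < n and not sac[j]:
                j += 1
            dur = (j - i) * rec.dt_ms
            if dur >= pp.MIN_FIXATION_MS and valid[i:j].any():
                out.append((t[i], t[i] + dur))
            i = j
        else:
            i += 1
    return out


class TestDetectBlinks:
    def test_100ms_dip_becomes_one_blink(self, clean_cfg):
        rng = np.random.default_rng(0)
        samples, _, _ = syn.render_trial(
            clean_cfg, [(0.0, 0.0), (5.0, 0.0)], [1000.0, 1400.0], rng, blink=(500.0, 100.0)
        )
        rec = GazeRecording("s0", 60.0, samples, clean_cfg.geometry)
        blinks = pp.detect_blinks(rec)
        assert len(blinks) == 1
        assert blinks[0].duration_ms == pytest.approx(100.0)

    def test_50ms_dip_below_minimum_ignored(self, clean_cfg):
        rng = np.random.default_rng(0)
        samples, _, _ = syn.render_trial(
            clean_cfg, [(0.0, 0.0), (5.0, 0.0)], [1000.0, 1400.0], rng, blink=(500.0, 50.0)
        )
        rec = GazeRecording("s0", 60.0, samples, clean_cfg.geometry)
        assert pp.detect_blinks(rec) == []

    def test_no_dip_gives_empty_list(self):
        rec = make_recording(np.full(150, 400.0), np.full(150, 300.0))
        assert pp.detect_blinks(rec) == []

    def test_blink_inside_fixation_does_not_split_it(self, clean_cfg):
        rng = np.random.default_rng(2)
        samples, _, _ = syn.render_trial(
            clean_cfg, [(0.0, 0.0), (6.0, 0.0)], [1500.0, 900.0], rng, blink=(600.0, 150.0)
        )
        rec = GazeRecording("s0", 60.0, samples, clean_cfg.geometry)
        assert len(pp.detect_fixations(rec)) == 2
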