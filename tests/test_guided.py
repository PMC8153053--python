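from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from gazemem import guided
from gazemem.geometry import MONITOR_EXP2
from gazemem.types import GazeRecording

from conftest import guided_layout


def picture_pool(seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    counts = [3 + i % 6 for i in range(54)]
    for i in range(54):
        rows.append(
            {
                "picture_id": f"g{i:03d}",
                "valence": ["negative", "neutral", "positive"][i % 3],
                "aois_pic": counts[i],
                "memorability": float(rng.uniform(0.1, 0.5)),
            }
        )
    return pd.DataFrame(rows)


class TestMatchPictureSets:
    def test_six_per_valence_per_set(self):
        sets = guided.match_picture_sets(picture_pool())
        counts = sets.groupby(["set", "valence"]).size()
        assert (counts == 6).all()

    def test_aoi_counts_balanced_across_sets(self):
        sets = guided.match_picture_sets(picture_pool())
        means = sets.groupby("set")["aois_pic"].mean()
        assert means.max() - means.min() <= 0.5

    def test_assignment_depends_only_on_seed(self):
        pool = picture_pool()
        a = guided.match_picture_sets(pool, seed=1)
        b = guided.match_picture_sets(pool, seed=1)
        pd.testing.assert_frame_equal(a, b)

    def test_wrong_counts_rejected(self):
        with pytest.raises(ValueError, match="54 pictures"):
            guided.match_picture_sets(picture_pool().iloc[:53])


class TestBuildScanPath:
    @pytest.mark.parametrize("k", range(3, 9))
    @pytest.mark.parametrize("cond", guided.CONDITIONS)
    def test_halt_counts_and_exact_conservation(self, k, cond):
        lay = guided_layout(k, seed=k)
        path = guided.build_scan_path(lay, cond, np.random.default_rng(0))
        n_expected = 2 * k if cond == "guided_fixation_x2" else k
        assert len(path.segments) == n_expected
        assert path.total_fixated_ms == Fraction(7000)  # exact, not approx
        durations = {s.halt_ms for s in path.segments}
        assert durations == {Fraction(7000, n_expected)}

    def test_boundary_halt_durations(self):
        p3 = guided.build_scan_path(
            guided_layout(3), "guided_fixation", np.random.default_rng(0)
        )
        assert float(p3.segments[0].halt_ms) == pytest.approx(2333.33, abs=0.01)
        p16 = guided.build_scan_path(
            guided_layout(8), "guided_fixation_x2", np.random.default_rng(0)
        )
        assert float(p16.segments[0].halt_ms) == pytest.approx(437.50)

    def test_first_halt_is_central_aoi(self):
        lay = guided_layout(5, seed=2)
        d = [np.hypot(*a.centroid_deg) for a in lay.interest]
        center = lay.interest[int(np.argmin(d))].centroid_deg
        for cond in guided.CONDITIONS:
            path = guided.build_scan_path(lay, cond, np.random.default_rng(1))
            assert path.segments[0].target_deg == center

    def test_guided_fixation_visits_each_aoi_once(self):
        lay = guided_layout(6, seed=3)
        path = guided.build_scan_path(lay, "guided_fixation", np.random.default_rng(2))
        visited = [s.target_deg for s in path.segments]
        assert sorted(visited) == sorted(a.centroid_deg for a in lay.interest)

    def test_x2_second_pass_repeats_first_order(self):
        lay = guided_layout(7, seed=4)
        path = guided.build_scan_path(
            lay, "guided_fixation_x2", np.random.default_rng(3)
        )
        first = [s.target_deg for s in path.segments[:7]]
        second = [s.target_deg for s in path.segments[7:]]
        assert first == second

    def test_no_interest_condition_mixes_targets(self):
        lay = guided_layout(7, seed=5)
        path = guided.build_scan_path(
            lay, "area_of_no_interest", np.random.default_rng(4)
        )
        kinds = [s.kind for s in path.segments]
        assert kinds.count("interest") == 1
        assert kinds.count("no_interest") == 6

    def test_presentation_time_exceeds_fixated_time(self):
        lay = guided_layout(4, seed=6)
        path = guided.build_scan_path(lay, "guided_fixation", np.random.default_rng(5))
        assert path.total_presentation_ms > 7000.0

    def test_missing_no_interest_centroids_rejected(self):
        from gazemem import synthetic as syn

        lay = syn.generate_aoi_layout("p", 5, np.random.default_rng(0), geometry=MONITOR_EXP2)
        with pytest.raises(ValueError, match="no-interest"):
            guided.build_scan_path(lay, "area_of_no_interest", np.random.default_rng(0))

    def test_serialization_roundtrip(self):
        from gazemem.types import ScanPath

        lay = guided_layout(5, seed=7)
        path = guided.build_scan_path(lay, "guided_fixation", np.random.default_rng(6))
        back = ScanPath.from_dict(path.to_dict())
        assert back.total_fixated_ms == Fraction(7000)
        assert [s.target_deg for s in back.segments] == [
            s.target_deg for s in path.segments
        ]


class TestScheduleTrials:
    def test_run_length_constraints_and_permutation(self):
        sets = guided.match_picture_sets(picture_pool())
        cond_by_set = dict(zip(range(3), guided.CONDITIONS))
        sched = guided.schedule_trials(sets, cond_by_set, np.random.default_rng(0))
        assert sorted(sched["picture_id"]) == sorted(sets["picture_id"])
        for col in ("valence", "set"):
            runs = (sched[col] != sched[col].shift()).cumsum()
            assert sched.groupby(runs)[col].size().max() <= 4

    def test_impossible_constraints_report_error(self):
        sets = guided.match_picture_sets(picture_pool())
        cond_by_set = dict(zip(range(3), guided.CONDITIONS))
        with pytest.raises(RuntimeError, match="runs <= 0"):
            guided.schedule_trials(
                sets, cond_by_set, np.random.default_rng(0), max_run=0, max_tries=10
            )


def compliant_recording(path, fs=120.0, delay_ms=0.0, geom=MONITOR_EXP2):
    """Gaze that follows the circle; an optional pure reaction delay holds
    the previous target until ``delay_ms`` after each halt onset, then
    jumps to the new target."""
    exp = guided.render_path(path, fs)
    if delay_ms > 0:
        onsets = guided.halt_onsets(path)
        t = exp["t_ms"].to_numpy()
        x = np.empty(len(t))
        y = np.empty(len(t))
        # gaze starts away from the first target so every halt, including
        # the first, shows the reaction delay
        prev = (onsets[0][1][0] + 10.0, onsets[0][1][1] + 10.0)
        for i, tt in enumerate(t):
            pos = prev
            for onset, tgt in onsets:
                if tt >= onset + delay_ms - 1e-9:
                    pos = tgt
            x[i], y[i] = pos
    else:
        x = exp["x_deg"].to_numpy()
        y = exp["y_deg"].to_numpy()
    px, py = geom.deg_to_px(x, y)
    samples = pd.DataFrame(
        {
            "t_ms": exp["t_ms"],
            "x_px": px,
            "y_px": py,
            "aspect_ratio": 0.85,
            "trial_id": 0,
        }
    )
    return GazeRecording("s0", fs, samples, geom)


class TestScoreCompliance:
    def test_self_generated_gaze_perfect_score(self):
        lay = guided_layout(5, seed=8)
        path = guided.build_scan_path(lay, "guided_fixation", np.random.default_rng(7))
        rec = compliant_recording(path)
        score = guided.score_compliance(rec, path)
        assert score.path_correlation == pytest.approx(1.0)
        assert score.mean_arrival_lag_ms == pytest.approx(0.0)
        assert score.n_halts_found == score.n_halts

    def test_reaction_delay_appears_as_lag(self):
        lay = guided_layout(5, seed=9)
        path = guided.build_scan_path(lay, "guided_fixation", np.random.default_rng(8))
        rec = compliant_recording(path, delay_ms=80.0)
        score = guided.score_compliance(rec, path)
        dt = 1000.0 / 120.0
        assert score.mean_arrival_lag_ms == pytest.approx(80.0, abs=dt + 1e-9)

    def test_random_walk_gaze_uncorrelated_on_average(self):
        lay = guided_layout(5, seed=10)
        path = guided.build_scan_path(lay, "guided_fixation", np.random.default_rng(9))
        rng = np.random.default_rng(10)
        rs = []
        for _ in range(30):
            n = len(guided.render_path(path, 120.0))
            steps = rng.normal(0, 0.3, (n, 2)).cumsum(axis=0)
            px, py = MONITOR_EXP2.deg_to_px(steps[:, 0], steps[:, 1])
            samples = pd.DataFrame(
                {
                    "t_ms": np.arange(n) * 1000.0 / 120.0,
                    "x_px": px,
                    "y_px": py,
                    "aspect_ratio": 0.85,
                    "trial_id": 0,
                }
            )
            rec = GazeRecording("s0", 120.0, samples, MONITOR_EXP2)
            rs.append(guided.score_compliance(rec, path).path_correlation)
        assert abs(np.mean(rs)) < 0.15

    def test_per_axis_mode_also_perfect_on_self_gaze(self):
        lay = guided_layout(4, seed=11)
        path = guided.build_scan_path(lay, "guided_fixation", np.random.default_rng(11))
        rec = compliant_recording(path)
        score = guided.score_compliance(rec, path, correlation_mode="per_axis")
        assert score.path_correlation == pytest.approx(1.0)

    def test_empty_trial_is_an_error(self):
        lay = guided_layout(4, seed=12)
        path = guided.build_scan_path(lay, "guided_fixation", np.random.default_rng(12))
        rec = compliant_recording(path)
        with pytest.raises(ValueError, match="no samples"):
            guided.score_compliance(rec, path, trial_id=99)


def recall_table(n_subjects=64, seed=0, effects=None):
    from gazemem import synthetic as syn

    cfg = syn.SimConfig()
    if effects is not None:
        cfg.condition_effects = effects
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for cond in guided.CONDITIONS:
            eta = cfg.recall_intercept + cfg.condition_effects[cond] + rng.normal(0, 0.3)
            p = 1 / (1 + np.exp(-eta))
            rows.append(
                {
                    "subject_id": f"s{s:03d}",
                    "condition": cond,
                    "recall_count": rng.binomial(18, p),
                    "sex": s % 2,
                    "age": float(np.round(rng.normal(23.3, 3.9), 1)),
                }
            )
    return pd.DataFrame(rows)


class TestFitConditionEffect:
    def test_condition_effect_detected_with_expected_signs(self):
        res = guided.fit_condition_effect(recall_table(seed=1))
        assert res["condition_p"] < 0.01
        ph = res["posthoc"].set_index("contrast")
        assert ph.loc["area_of_no_interest_vs_guided_fixation", "percent_change"] < 0
        assert ph.loc["guided_fixation_x2_vs_guided_fixation", "percent_change"] > 0
        assert (ph["p_fdr"] >= ph["p"] - 1e-12).all()

    def test_percent_change_matches_headline_rounding(self):
        assert round(guided.percent_change(4.19, 4.97)) == 19
        assert round(guided.percent_change(4.19, 3.25)) == -22

    def test_null_conditions_give_large_p(self):
        effects = {c: 0.0 for c in guided.CONDITIONS}
        ps = [
            guided.fit_condition_effect(recall_table(seed=100 + i, effects=effects))[
                "condition_p"
            ]
            for i in range(10)
        ]
        # under the null, p-values spread over (0, 1) instead of piling at 0
        assert min(ps) > 1e-4
        assert np.mean([p > 0.2 for p in ps]) >= 0.5

    def test_subject_missing_a_condition_excluded(self):
        t = recall_table(seed=2)
        t = t.drop(t[(t["subject_id"] == "s000")].index[:1])
        res = guided.fit_condition_effect(t)
        assert res["dropped_subjects"] == ["s000"]
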