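"""Template matching: windows, correlation, grab detection, scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import reachmetrics as rm
from reachmetrics.stereotypy import HALF_WIN, TEMPLATE_LEN

from conftest import brute_force_sliding_correlation


def flat_track(digit_matrix, **kw):
    """Wrap an (n, 10) digit matrix into a PoseTrack (wrist/pellet static)."""
    n = digit_matrix.shape[0]
    x = np.zeros((n, 7))
    y = np.zeros((n, 7))
    x[:, :5] = digit_matrix[:, 0::2]
    y[:, :5] = digit_matrix[:, 1::2]
    x[:, 5:] = 500.0
    y[:, 5:] = 500.0
    return rm.PoseTrack(x=x, y=y, likelihood=np.ones((n, 7)), **kw)


class TestWindowsAndTemplates:
    def test_centered_window_bounds(self):
        track = flat_track(np.arange(400 * 10, dtype=float).reshape(400, 10))
        win = rm.extract_grab_window(track, 100)
        np.testing.assert_array_equal(
            win, track.digit_matrix()[75:125]
        )

    @pytest.mark.parametrize("center", [10, 24, 380, 399])
    def test_window_overrun_rejected(self, center):
        track = flat_track(np.zeros((400, 10)))
        with pytest.raises(ValueError, match="out of bounds"):
            rm.extract_grab_window(track, center)

    def test_template_mean_identities(self, base_waveform):
        rng = np.random.default_rng(0)
        A = base_waveform
        B = base_waveform + rng.normal(0, 5, base_waveform.shape)
        pad = np.tile(A[:1], (60, 1))
        tr_a = flat_track(np.vstack([pad, A, pad]))
        tr_b = flat_track(np.vstack([pad, B, pad]))
        center = 60 + HALF_WIN
        same = rm.build_template([tr_a, tr_a, tr_a], [center] * 3)
        np.testing.assert_allclose(same.values, A)
        mixed = rm.build_template([tr_a, tr_a, tr_b], [center] * 3)
        np.testing.assert_allclose(mixed.values, (2 * A + B) / 3)

    def test_template_from_noiseless_grabs_equals_base(self, noiseless_tracks):
        cfg, tracks, truth = noiseless_tracks
        tpl = rm.build_template(tracks, [g[0] for g in truth])
        # mean of three bit-identical windows is exact up to one rounding step
        np.testing.assert_allclose(tpl.values, cfg.grab_waveform, rtol=1e-14)

    def test_fewer_than_three_grabs_rejected(self, noiseless_tracks):
        _, tracks, truth = noiseless_tracks
        with pytest.raises(ValueError, match="3 grabs"):
            rm.build_template(tracks[:2], [truth[0][0], truth[1][0]])


class TestSlidingCorrelation:
    def test_matches_brute_force_oracle(self, base_waveform):
        rng = np.random.default_rng(42)
        X = rng.normal(500, 40, (400, 10))
        track = flat_track(X)
        tpl = rm.GrabTemplate(values=base_waveform)
        fast = rm.sliding_correlation(track, tpl)
        slow = brute_force_sliding_correlation(track.digit_matrix(), tpl.values)
        np.testing.assert_array_equal(np.isnan(fast), np.isnan(slow))
        assert np.nanmax(np.abs(fast - slow)) < 1e-10

    def test_peak_of_one_at_embedding(self, base_waveform):
        pad = np.tile(base_waveform[:1], (100, 1))
        X = np.vstack([pad, base_waveform, pad])
        corr = rm.sliding_correlation(
            flat_track(X), rm.GrabTemplate(values=base_waveform)
        )
        center = 100 + HALF_WIN
        assert corr[center] == pytest.approx(1.0, abs=1e-12)
        assert np.nanargmax(corr) == center

    def test_negated_template_scores_minus_one(self, base_waveform):
        centered = base_waveform - base_waveform.mean(axis=0)
        pad = np.tile(centered[:1], (80, 1))
        X = np.vstack([pad, -centered, pad]) + 700.0
        corr = rm.sliding_correlation(
            flat_track(X), rm.GrabTemplate(values=centered + 700.0)
        )
        assert corr[80 + HALF_WIN] == pytest.approx(-1.0, abs=1e-12)

    def test_edges_are_nan_not_zero(self, base_waveform):
        track = flat_track(np.random.default_rng(1).normal(0, 1, (200, 10)))
        corr = rm.sliding_correlation(track, rm.GrabTemplate(values=base_waveform))
        assert np.all(np.isnan(corr[:HALF_WIN]))
        assert np.all(np.isnan(corr[-(HALF_WIN - 1):]))
        assert np.all(np.isfinite(corr[HALF_WIN : -(HALF_WIN - 1)]))

    def test_zero_variance_coordinate_contributes_zero(self, base_waveform):
        X = np.random.default_rng(2).normal(0, 1, (120, 10))
        X[:, 3] = 5.0  # flat coordinate
        corr = rm.sliding_correlation(
            flat_track(X), rm.GrabTemplate(values=base_waveform)
        )
        slow = brute_force_sliding_correlation(X, base_waveform)
        assert np.nanmax(np.abs(corr - slow)) < 1e-10

    def test_short_trial_rejected(self, base_waveform):
        with pytest.raises(ValueError, match="shorter than template"):
            rm.sliding_correlation(
                flat_track(np.zeros((30, 10))), rm.GrabTemplate(values=base_waveform)
            )


class TestDetectGrabs:
    def test_two_embedded_grabs_recovered(self, base_waveform):
        pad = np.tile(base_waveform[:1], (75, 1))
        X = np.vstack([pad, base_waveform, pad, base_waveform, pad])
        corr = rm.sliding_correlation(
            flat_track(X), rm.GrabTemplate(values=base_waveform)
        )
        events = rm.detect_grabs(corr, min_separation=50, min_score=0.3)
        centers = [75 + HALF_WIN, 75 + TEMPLATE_LEN + 75 + HALF_WIN]
        assert len(events) == 2
        for ev, c in zip(events, centers):
            assert abs(ev.frame - c) <= 1
        assert [e.is_final for e in events] == [False, True]

    def test_monotone_series_yields_at_most_one_peak(self):
        corr = np.linspace(-0.5, 0.9, 300)
        assert len(rm.detect_grabs(corr)) <= 1

    def test_all_below_threshold_empty(self):
        rng = np.random.default_rng(3)
        corr = rng.uniform(-0.2, 0.25, 400)
        assert rm.detect_grabs(corr, min_score=0.3) == []

    def test_short_series_empty(self):
        assert rm.detect_grabs(np.array([0.9])) == []

    @given(seed=st.integers(0, 1000), sep=st.sampled_from([30, 50, 80]))
    @settings(max_examples=30, deadline=None)
    def test_count_bound_and_separation(self, seed, sep):
        corr = np.random.default_rng(seed).uniform(-1, 1, 400)
        events = rm.detect_grabs(corr, min_separation=sep, min_score=0.0)
        assert len(events) <= 400 // sep + 1
        frames = [e.frame for e in events]
        assert all(b - a >= sep for a, b in zip(frames, frames[1:]))
        assert sum(e.is_final for e in events) == (1 if events else 0)


class TestStereotypyScore:
    def test_exact_final_grab_scores_one(self, noiseless_tracks):
        cfg, tracks, _ = noiseless_tracks
        tpl = rm.GrabTemplate(values=cfg.grab_waveform)
        for tr in tracks:
            rec = rm.stereotypy_score(tr, tpl)
            assert rec.score == pytest.approx(1.0, abs=1e-12)

    def test_no_grab_yields_missing_score(self, base_waveform):
        track = flat_track(np.random.default_rng(4).normal(0, 1, (200, 10)))
        rec = rm.stereotypy_score(
            track, rm.GrabTemplate(values=base_waveform), min_score=0.99
        )
        assert rec.score is None and rec.frame is None

    def test_translation_and_scale_invariance(self, base_waveform):
        cfg = rm.TrajectorySimConfig(n_trials=1, stereotypy_level=0.5, seed=6)
        (track,), _ = rm.gen_pose_trials(cfg)
        tpl = rm.GrabTemplate(values=base_waveform)
        ref = rm.stereotypy_score(track, tpl).score
        moved = rm.PoseTrack(
            x=track.x * 3.0 + 120.0, y=track.y * 3.0 - 40.0,
            likelihood=track.likelihood, trial_id=track.trial_id,
        )
        moved_values = np.empty((50, 10))
        moved_values[:, 0::2] = base_waveform[:, 0::2] * 3.0 + 120.0
        moved_values[:, 1::2] = base_waveform[:, 1::2] * 3.0 - 40.0
        moved_tpl = rm.GrabTemplate(values=moved_values)
        assert rm.stereotypy_score(moved, moved_tpl).score == pytest.approx(
            ref, abs=1e-9
        )

    def test_mean_score_increases_with_stereotypy_level(self, base_waveform):
        tpl = rm.GrabTemplate(values=base_waveform)
        means = []
        for lvl in (0.2, 0.8):
            cfg = rm.TrajectorySimConfig(n_trials=30, stereotypy_level=lvl, seed=13)
            tracks, _ = rm.gen_pose_trials(cfg)
            scores = [rm.stereotypy_score(t, tpl).score for t in tracks]
            means.append(np.mean([s for s in scores if s is not None]))
        assert means[1] > means[0]


class TestSessionPipeline:
    def test_session_template_and_scores_on_noiseless_cohort(self):
        cfg = rm.TrajectorySimConfig(
            n_trials=8, stereotypy_level=1.0, baseline_noise_sd=0.0, seed=17
        )
        tracks, _ = rm.gen_pose_trials(cfg)
        tpl = rm.build_session_template(tracks)
        np.testing.assert_allclose(tpl.values, cfg.grab_waveform, atol=1e-9)
        df = rm.score_session(tracks, tpl)
        assert np.allclose(df["score"], 1.0)

    def test_template_archive_round_trip(self, tmp_path, base_waveform):
        tpl = rm.GrabTemplate(
            values=base_waveform, animal_id="rat03", day=4,
            source_trials=("a", "b", "c"),
        )
        path = tmp_path / "templates.h5"
        from reachmetrics.stereotypy import load_templates, save_templates

        save_templates([tpl], path)
        (back,) = load_templates(path)
        np.testing.assert_array_equal(back.values, tpl.values)
        assert back.animal_id == "rat03" and back.day == 4
        assert back.source_trials == ("a", "b", "c")
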