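"""Pose-track filtering, limb detection, alignment and kinematics."""

import numpy as np
import pytest

from pawkit import PawkitError
from pawkit.core import ANALYSIS_PARTS, PoseTrack
from pawkit.pose import (
    baseline_pose,
    detect_stimulated_limb,
    displacement_series,
    egocentric_align,
    filter_labels,
    head_yaw_series,
    movement_onset,
    paw_nose_metrics,
    qc_pose_trial,
    summarize_kinematics,
)
from pawkit.synthetic import (
    CohortSpec,
    gen_pose_cohort,
    gen_pose_trial,
    gen_wholebody_trial,
    inject_glitches,
    static_pose_track,
    with_overrides,
)


def static_track(n_frames=60, onset=30, parts=None, fps=400.0, side="left", **kw):
    parts = list(parts or ANALYSIS_PARTS)
    from pawkit.synthetic import DEFAULT_POSE

    x = np.tile([DEFAULT_POSE[p][0] for p in parts], (n_frames, 1))
    y = np.tile([DEFAULT_POSE[p][1] for p in parts], (n_frames, 1))
    lik = np.full_like(x, 0.99)
    return PoseTrack(x=x, y=y, likelihood=lik, parts=parts, fps=fps,
                     onset_frame=onset, stimulated_side=side, **kw)


class TestFilterLabels:
    def test_low_likelihood_point_removed(self):
        tr = static_track()
        tr.likelihood[5, 0] = 0.94
        out = filter_labels(tr)
        assert np.isnan(out.x[5, 0]) and np.isfinite(out.x[4, 0])

    def test_transient_jump_removed_sustained_kept(self):
        tr = static_track()
        j = tr.part_index("nose")
        tr.x[10, j] += 12.0  # one-frame excursion, returns at 11
        tr.x[20:, j] += 12.0  # sustained 12 px jump
        out = filter_labels(tr)
        assert np.isnan(out.x[10, j])
        assert np.isfinite(out.x[20:, j]).all()
        assert 10 in out.meta["jump_flagged_frames"]

    def test_stimulation_frames_removed_for_all_parts(self):
        tr = static_track(stimulation_frames=(30, 31, 32, 33, 34))
        out = filter_labels(tr)
        assert np.isnan(out.x[30:35]).all()
        assert np.isfinite(out.x[35]).all()

    def test_idempotent(self):
        tr = static_track()
        tr.likelihood[5, 0] = 0.5
        tr.x[12, 1] += 15.0
        once = filter_labels(tr)
        twice = filter_labels(once)
        assert np.array_equal(np.isnan(once.x), np.isnan(twice.x))

    def test_programmed_glitch_schedule_recovered(self):
        spec = with_overrides(CohortSpec(), jitter_sd_px=0.05)
        rng = np.random.default_rng(0)
        tr, _ = gen_pose_trial(spec, rng, stimulated_side="left", respond=False)
        schedule = {"nose": [10, 25, 40], "tail_base": [15]}
        glitched = inject_glitches(tr, schedule, magnitude_px=12.0)
        out = filter_labels(glitched)
        for part, frames in schedule.items():
            j = out.part_index(part)
            for f in frames:
                assert np.isnan(out.x[f, j])
        assert set(out.meta["jump_flagged_frames"]) == {10, 15, 25, 40}

    def test_programmed_dropout_fraction_removed(self):
        spec = with_overrides(CohortSpec(), dropout_frac=0.2)
        rng = np.random.default_rng(1)
        tr, _ = gen_pose_trial(spec, rng, stimulated_side="left", respond=False)
        out = filter_labels(tr, stim_frames=())
        frac = np.isnan(out.x).mean()
        assert frac == pytest.approx(0.2, abs=0.03)


class TestQcPoseTrial:
    def test_missing_fraction_threshold(self):
        tr = static_track(n_frames=100)
        out = filter_labels(tr)
        out.x[:11, :] = np.nan  # 11% missing on all parts
        ok, reasons = qc_pose_trial(out)
        assert not ok and "too-many-missing-labels" in reasons

    def test_clean_trial_passes(self):
        ok, reasons = qc_pose_trial(filter_labels(static_track()))
        assert ok and reasons == ()

    def test_cohort_trial_with_heavy_dropout_fails(self):
        spec = with_overrides(CohortSpec(), dropout_frac=0.15)
        rng = np.random.default_rng(2)
        tr, _ = gen_pose_trial(spec, rng, stimulated_side="right")
        ok, _ = qc_pose_trial(filter_labels(tr))
        assert not ok

    def test_manual_flag_pathway(self):
        out = filter_labels(static_track())
        ok, reasons = qc_pose_trial(out, manual_bad_frames=tuple(range(11)))
        assert not ok and "too-many-mislabeled-frames" in reasons


class TestDetectStimulatedLimb:
    def test_saturation_disc_side_recovered(self, rng):
        spec = CohortSpec()
        hits = 0
        for _ in range(20):
            stack, gt = gen_wholebody_trial(spec, rng, move=True)
            track = static_pose_track(gt, stack.n_frames, stack.fps,
                                      stack.onset_frame)
            hits += detect_stimulated_limb(stack, track) == gt.stimulated_side
        assert hits == 20

    def test_no_saturation_returns_unknown(self, rng):
        spec = CohortSpec()
        stack, gt = gen_wholebody_trial(spec, rng, move=False,
                                        stimulus_disc=False)
        track = static_pose_track(gt, stack.n_frames, stack.fps,
                                  stack.onset_frame)
        assert detect_stimulated_limb(stack, track) == "unknown"


class TestMovementOnset:
    def test_static_track_has_no_onset(self):
        assert movement_onset(static_track(), "nose") is None

    def test_step_and_sustained_drift_latency_arithmetic(self):
        tr = static_track(n_frames=80, onset=30)
        j = tr.part_index("nose")
        f0 = 42
        for i, f in enumerate(range(f0, 80)):
            tr.x[f, j] += 1.0 + 0.6 * i  # 1 px step then 0.6 px/frame
        lat = movement_onset(tr, "nose")
        assert lat == pytest.approx((f0 - 30) * 2.5)  # 30 ms at 400 fps

    def test_brief_twitch_rejected(self):
        tr = static_track(n_frames=80, onset=30)
        j = tr.part_index("nose")
        tr.x[40:43, j] += 5.0  # moves then stops
        assert movement_onset(tr, "nose") is None

    def test_cohort_onsets_recovered_within_one_frame(self):
        spec = with_overrides(CohortSpec(), n_mice=4, trials_per_mouse=5)
        tracks, gts = gen_pose_cohort(spec, 7)
        ok = 0
        for tk, gt in zip(tracks, gts):
            part = f"{gt.stimulated_side}_hind_digits"
            lat = movement_onset(filter_labels(tk), part)
            ok += lat is not None and abs(lat - gt.part_onsets_ms[part]) <= 2.5
        assert ok >= 0.95 * len(tracks)


class TestEgocentricAlign:
    def test_tail_base_at_origin_and_paw_on_right(self):
        for side in ("left", "right"):
            spec = CohortSpec()
            rng = np.random.default_rng(3)
            tr, _ = gen_pose_trial(spec, rng, stimulated_side=side)
            al = egocentric_align(filter_labels(tr))
            assert al.baseline_pose["tail_base"] == pytest.approx((0.0, 0.0), abs=1e-9)
            assert al.baseline_pose["stim_hind_digits"][0] >= 0

    def test_alignment_is_isometry(self):
        rng = np.random.default_rng(4)
        tr, _ = gen_pose_trial(CohortSpec(), rng, stimulated_side="left")
        filtered = filter_labels(tr)
        al = egocentric_align(filtered)
        # pairwise distances at an arbitrary frame are preserved
        f = 100
        raw = np.column_stack([filtered.x[f], filtered.y[f]])
        ali = np.column_stack([al.x[f], al.y[f]])
        # map aligned part order back to raw part order
        order = [filtered.parts.index(
            {"nose": "nose", "tail_base": "tail_base",
             "stim_hind_digits": "left_hind_digits",
             "stim_hind_heel": "left_hind_heel",
             "contra_hind_digits": "right_hind_digits",
             "contra_hind_heel": "right_hind_heel"}[p]) for p in al.parts]
        raw = raw[order]
        d_raw = np.linalg.norm(raw[:, None] - raw[None, :], axis=-1)
        d_ali = np.linalg.norm(ali[:, None] - ali[None, :], axis=-1)
        assert np.allclose(d_raw, d_ali, equal_nan=True)

    def test_unknown_side_rejected(self):
        tr = static_track(side="unknown")
        with pytest.raises(PawkitError):
            egocentric_align(tr)


class TestDisplacementAndDistance:
    def test_static_part_all_zero(self):
        series, maxima = displacement_series(static_track())
        assert np.allclose(series["nose"], 0.0, atol=1e-9)
        assert maxima["nose"] == pytest.approx(0.0, abs=1e-9)

    def test_three_four_five_displacement(self):
        tr = static_track(n_frames=60, onset=30)
        j = tr.part_index("nose")
        tr.x[40:, j] += 3.0
        tr.y[40:, j] += 4.0
        _, maxima = displacement_series(tr)
        assert maxima["nose"] == pytest.approx(5.0)

    def test_maxima_match_bruteforce_scan(self):
        rng = np.random.default_rng(5)
        tr, _ = gen_pose_trial(CohortSpec(), rng, stimulated_side="right")
        filtered = filter_labels(tr)
        series, maxima = displacement_series(filtered, window_ms=300.0)
        win_stop = filtered.onset_frame + int(round(300.0 * filtered.fps / 1000.0)) + 1
        for p, m in maxima.items():
            assert m == pytest.approx(
                np.nanmax(series[p][filtered.onset_frame:win_stop]))

    def test_paw_nose_static_distance(self):
        tr = static_track(side="left")
        dmin, dmax, d = paw_nose_metrics(tr)
        expected = np.hypot(48 - 30, 70 - 20)
        assert dmin == pytest.approx(expected) and dmax == pytest.approx(expected)

    def test_translation_invariance(self):
        rng = np.random.default_rng(6)
        tr, _ = gen_pose_trial(CohortSpec(), rng, stimulated_side="left")
        filtered = filter_labels(tr)
        shifted = filtered.copy()
        shifted.x += 17.0
        shifted.y -= 9.0
        a = summarize_kinematics(filtered)
        b = summarize_kinematics(shifted)
        for p in a.max_displacement_px:
            assert a.max_displacement_px[p] == pytest.approx(
                b.max_displacement_px[p], abs=1e-9)
        assert a.paw_nose_min_px == pytest.approx(b.paw_nose_min_px, abs=1e-9)
        assert a.mean_yaw_deg == pytest.approx(b.mean_yaw_deg, abs=1e-9)


class TestHeadYaw:
    def test_motion_along_body_axis_gives_zero_yaw(self):
        tr = static_track(n_frames=80, onset=30)
        j = tr.part_index("nose")
        tr.y[40:, j] -= 10.0  # nose moves straight ahead (up the image)
        yaw, mean_yaw = head_yaw_series(tr)
        assert mean_yaw == pytest.approx(0.0, abs=1e-9)

    def test_quarter_turn_reads_ninety_degrees(self):
        tr = static_track(n_frames=80, onset=30, side="right")
        jn, jt = tr.part_index("nose"), tr.part_index("tail_base")
        # rotate the nose 90 deg about the tail base, toward image right
        radius = tr.y[0, jt] - tr.y[0, jn]
        tr.x[40:, jn] = tr.x[0, jt] + radius
        tr.y[40:, jn] = tr.y[0, jt]
        yaw, _ = head_yaw_series(tr)
        assert yaw[50] == pytest.approx(90.0)

    def test_cohort_yaw_recovered(self):
        spec = with_overrides(CohortSpec(), n_mice=6, trials_per_mouse=6)
        tracks, gts = gen_pose_cohort(spec, 11)
        recovered = []
        for tk, gt in zip(tracks, gts):
            _, my = head_yaw_series(filter_labels(tk))
            recovered.append(my)
        assert np.mean(recovered) == pytest.approx(20.0, abs=2.0)

    def test_baseline_requires_labels(self):
        tr = static_track()
        tr.x[:, tr.part_index("nose")] = np.nan
        with pytest.raises(PawkitError):
            head_yaw_series(tr)


class TestBaselinePose:
    def test_mean_of_ten_preonset_frames(self):
        tr = static_track(n_frames=60, onset=30)
        j = tr.part_index("nose")
        tr.x[20:30, j] = np.arange(10, 20, dtype=float)
        pose = baseline_pose(tr)
        assert pose["nose"][0] == pytest.approx(14.5)

    def test_insufficient_preonset_frames(self):
        tr = static_track(n_frames=20, onset=5)
        with pytest.raises(PawkitError):
            baseline_pose(tr)
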