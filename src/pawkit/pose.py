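"""Post-processing of markerless body-part tracks and kinematics.

The toolkit consumes DeepLabCut-style tracks (x, y, likelihood per part per
frame) and provides the downstream steps: confidence/jump filtering, trial
quality control, automated detection of the stimulated limb from laser
saturation, per-part movement-onset latencies, egocentric alignment (tail
base at the origin, stimulated paw on the right), displacement and
paw-nose distance series, and head-yaw trajectories.

Sides are named as viewed in the image; the image origin is top-left with y
increasing downward. Removed points are NaN and are never interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import circmean

from .core import ANALYSIS_PARTS, FrameStack, PoseTrack
from .errors import PawkitError, ValidationError

#: Feature order after alignment: six parts x (x, y) = 12 features.
ALIGNED_PARTS = (
    "nose",
    "stim_hind_digits",
    "stim_hind_heel",
    "contra_hind_digits",
    "contra_hind_heel",
    "tail_base",
)


@dataclass
class AlignedPose:
    """Egocentric coordinates for the six analysis parts.

    ``x``/``y`` are ``(n_frames, 6)`` arrays in the order
    :data:`ALIGNED_PARTS`; the baseline tail base sits at (0, 0) and the
    stimulated hind paw has non-negative baseline x.
    """

    x: np.ndarray
    y: np.ndarray
    parts: tuple[str, ...]
    fps: float
    onset_frame: int
    reflected: bool
    baseline_pose: dict[str, tuple[float, float]]

    def features(self, frame: int) -> np.ndarray:
        """12-vector (x1, y1, ..., x6, y6) at one frame."""
        return np.column_stack([self.x[frame], self.y[frame]]).ravel()

    def feature_matrix(self) -> np.ndarray:
        """``(n_frames, 12)`` feature time course."""
        return np.stack([self.features(f) for f in range(self.x.shape[0])])


@dataclass
class KinematicsSummary:
    """Per-trial kinematic read-outs within the analysis window."""

    onset_ms: dict[str, float | None]
    max_displacement_px: dict[str, float | None]
    paw_nose_min_px: float | None
    paw_nose_max_px: float | None
    mean_yaw_deg: float | None

    def __post_init__(self) -> None:
        if (
            self.paw_nose_min_px is not None
            and self.paw_nose_max_px is not None
            and self.paw_nose_min_px > self.paw_nose_max_px + 1e-9
        ):
            raise ValidationError("min paw-nose distance exceeds max")


def filter_labels(
    track: PoseTrack,
    p_cutoff: float = 0.95,
    jump_px: float = 10.0,
    stim_frames: tuple[int, ...] | None = None,
) -> PoseTrack:
    """Remove unreliable points from a track.

    A point is removed when (1) its likelihood is below ``p_cutoff``;
    (2) it jumps at least ``jump_px`` pixels from the previous retained point
    *and* the next frame does not return to within ``jump_px`` of the
    pre-jump position (a sustained jump is real movement and is kept); or
    (3) it falls on a stimulation frame (laser light contaminates every
    label there). Removal is by NaN; nothing is interpolated.

    The returned track's ``meta['jump_flagged_frames']`` lists the frames
    removed by the jump rule, which feeds trial QC.
    """
    out = track.copy()
    if stim_frames is None:
        stim_frames = tuple(track.stimulation_frames)
    low = out.likelihood < p_cutoff
    out.x[low] = np.nan
    out.y[low] = np.nan
    flagged: set[int] = set()
    for j in range(out.n_parts):
        xs, ys = out.x[:, j], out.y[:, j]
        prev: tuple[float, float] | None = None
        for f in range(out.n_frames):
            if np.isnan(xs[f]):
                continue
            if prev is not None:
                d = float(np.hypot(xs[f] - prev[0], ys[f] - prev[1]))
                if d >= jump_px:
                    nxt = f + 1
                    returned = (
                        nxt < out.n_frames
                        and not np.isnan(xs[nxt])
                        and np.hypot(xs[nxt] - prev[0], ys[nxt] - prev[1]) < jump_px
                    )
                    if returned:
                        xs[f] = np.nan
                        ys[f] = np.nan
                        flagged.add(f)
                        continue  # prev stays the pre-jump point
            prev = (float(xs[f]), float(ys[f]))
    if stim_frames:
        sf = [f for f in stim_frames if 0 <= f < out.n_frames]
        out.x[sf, :] = np.nan
        out.y[sf, :] = np.nan
    out.meta["jump_flagged_frames"] = tuple(sorted(flagged))
    out.meta["filtered"] = True
    return out


def qc_pose_trial(
    track: PoseTrack,
    max_missing_frac: float = 0.10,
    max_bad_frames: int = 10,
    parts: tuple[str, ...] | None = None,
    manual_bad_frames: tuple[int, ...] = (),
) -> tuple[bool, tuple[str, ...]]:
    """Trial-level pose quality control on a filtered track.

    Fails when the missing-label fraction over the analysis parts exceeds
    ``max_missing_frac`` or when more than ``max_bad_frames`` frames were
    mislabeled. Mislabeled frames are those flagged by the jump rule during
    filtering plus any supplied ``manual_bad_frames`` (the manual-inspection
    pathway). Stimulation frames are excluded from the missing count since
    their removal is by design.
    """
    if parts is None:
        parts = tuple(p for p in ANALYSIS_PARTS if p in track.parts) or tuple(track.parts)
    cols = [track.part_index(p) for p in parts]
    keep = np.ones(track.n_frames, dtype=bool)
    for f in track.stimulation_frames:
        if 0 <= f < track.n_frames:
            keep[f] = False
    sub = track.x[np.ix_(keep, cols)]
    missing_frac = float(np.isnan(sub).mean()) if sub.size else 0.0
    bad = set(track.meta.get("jump_flagged_frames", ())) | set(manual_bad_frames)
    reasons: list[str] = []
    if missing_frac > max_missing_frac:
        reasons.append("too-many-missing-labels")
    if len(bad) > max_bad_frames:
        reasons.append("too-many-mislabeled-frames")
    return (len(reasons) == 0, tuple(reasons))


def _saturation_count(
    frame: np.ndarray, center: tuple[float, float], window_px: int, saturation: int
) -> int:
    h, w = frame.shape
    half = window_px // 2
    cx, cy = int(round(center[0])), int(round(center[1]))
    x0, x1 = max(cx - half, 0), min(cx + half, w)
    y0, y1 = max(cy - half, 0), min(cy + half, h)
    if x0 >= x1 or y0 >= y1:
        return 0
    return int((frame[y0:y1, x0:x1] >= saturation).sum())


def detect_stimulated_limb(
    stack: FrameStack,
    track: PoseTrack,
    left_part: str = "left_hind_digits",
    right_part: str = "right_hind_digits",
    window_px: int = 60,
    t_pre_ms: float = 7.5,
    t_post_ms: float = 5.0,
    saturation: int = 255,
) -> str:
    """Which hind paw received the laser, from pixel saturation.

    Compares the number of saturated pixels inside a ``window_px`` square
    window around each hind-paw label between a frame ``t_pre_ms`` before
    and ``t_post_ms`` after stimulus onset (rounded to the nearest frames).
    Returns ``"left"`` / ``"right"`` (as viewed in the image) or
    ``"unknown"`` when neither window gains saturation.
    """
    pre_f = stack.onset_frame - int(round(t_pre_ms * stack.fps / 1000.0))
    post_f = stack.onset_frame + int(round(t_post_ms * stack.fps / 1000.0))
    pre_f = max(pre_f, 0)
    post_f = min(post_f, stack.n_frames - 1)
    gains = {}
    for side, part in (("left", left_part), ("right", right_part)):
        xy = track.xy(part)
        # use the label position just before the stimulus; fall back to the
        # nearest finite pre-onset position
        pos = None
        for f in range(min(pre_f, track.n_frames - 1), -1, -1):
            if np.isfinite(xy[f]).all():
                pos = (float(xy[f, 0]), float(xy[f, 1]))
                break
        if pos is None:
            gains[side] = 0
            continue
        pre = _saturation_count(stack.frames[pre_f], pos, window_px, saturation)
        post = _saturation_count(stack.frames[post_f], pos, window_px, saturation)
        gains[side] = post - pre
    if gains["left"] == gains["right"]:
        return "unknown"
    return "left" if gains["left"] > gains["right"] else "right"


def baseline_pose(
    track: PoseTrack, n_frames: int = 10, end_frame: int | None = None
) -> dict[str, tuple[float, float]]:
    """Average (x, y) per part over ``n_frames`` consecutive pre-onset frames.

    Uses the ``n_frames`` frames immediately before the stimulus (or before
    ``end_frame``); NaN points are ignored in the average.
    """
    end = track.onset_frame if end_frame is None else end_frame
    start = end - n_frames
    if start < 0:
        raise PawkitError(
            f"need {n_frames} pre-onset frames for the baseline, have {end}"
        )
    pose = {}
    for p in track.parts:
        xy = track.xy(p)[start:end]
        with np.errstate(invalid="ignore"):
            pose[p] = (float(np.nanmean(xy[:, 0])), float(np.nanmean(xy[:, 1])))
    return pose


def movement_onset(
    track: PoseTrack,
    part: str,
    baseline_frames: int = 10,
    min_disp_px: float = 0.5,
    min_rate_px_per_frame: float = 0.5,
    persist_frames: int = 10,
) -> float | None:
    """Movement-onset latency (ms) of one body part, or None.

    Onset is the first post-stimulus frame whose Euclidean displacement from
    the baseline position (mean of ``baseline_frames`` consecutive pre-onset
    frames) reaches ``min_disp_px`` *and* that keeps moving at
    ``min_rate_px_per_frame`` (frame-to-frame) for the subsequent
    ``persist_frames`` frames. Frames with missing data cannot qualify.
    """
    base = baseline_pose(track, n_frames=baseline_frames)[part]
    if not np.isfinite(base).all():
        raise PawkitError(f"baseline position of {part!r} is undefined")
    xy = track.xy(part)
    disp = np.hypot(xy[:, 0] - base[0], xy[:, 1] - base[1])
    step = np.hypot(np.diff(xy[:, 0]), np.diff(xy[:, 1]))  # step[f] = f -> f+1
    for f in range(track.onset_frame, track.n_frames):
        if not np.isfinite(disp[f]) or disp[f] < min_disp_px:
            continue
        last = f + persist_frames
        if last > track.n_frames - 1:
            break
        seg = step[f:last]
        if np.isfinite(seg).all() and (seg >= min_rate_px_per_frame).all():
            return float((f - track.onset_frame) * 1000.0 / track.fps)
    return None


def egocentric_align(
    track: PoseTrack,
    base_pose: dict[str, tuple[float, float]] | None = None,
    stimulated_side: str | None = None,
    parts_map: dict[str, str] | None = None,
) -> AlignedPose:
    """Egocentric alignment: baseline tail base at (0, 0), stimulated paw right.

    Coordinates are translated so the baseline tail-base position is the
    origin, and reflected in x when the stimulated hind paw's baseline x is
    negative, so the stimulated paw always lies on the right. Left/right part
    names are relabeled to stimulated/contralateral
    (:data:`ALIGNED_PARTS`). Alignment is translation + optional reflection
    only — an isometry, so all inter-part distances are preserved.
    """
    if stimulated_side is None:
        stimulated_side = track.stimulated_side
    if stimulated_side not in ("left", "right"):
        raise PawkitError("stimulated side must be known for egocentric alignment")
    if base_pose is None:
        base_pose = baseline_pose(track)
    tb = base_pose.get("tail_base")
    if tb is None or not np.isfinite(tb).all():
        raise PawkitError("tail base missing at baseline; cannot align")
    stim, contra = (("left", "right") if stimulated_side == "left"
                    else ("right", "left"))
    if parts_map is None:
        parts_map = {
            "nose": "nose",
            "stim_hind_digits": f"{stim}_hind_digits",
            "stim_hind_heel": f"{stim}_hind_heel",
            "contra_hind_digits": f"{contra}_hind_digits",
            "contra_hind_heel": f"{contra}_hind_heel",
            "tail_base": "tail_base",
        }
    cols = [track.part_index(parts_map[p]) for p in ALIGNED_PARTS]
    x = track.x[:, cols] - tb[0]
    y = track.y[:, cols] - tb[1]
    stim_base_x = base_pose[parts_map["stim_hind_digits"]][0] - tb[0]
    reflected = stim_base_x < 0
    if reflected:
        x = -x
    aligned_base = {}
    for p in ALIGNED_PARTS:
        bx, by = base_pose[parts_map[p]]
        ax = bx - tb[0]
        aligned_base[p] = (-ax if reflected else ax, by - tb[1])
    return AlignedPose(
        x=x, y=y, parts=ALIGNED_PARTS, fps=track.fps,
        onset_frame=track.onset_frame, reflected=bool(reflected),
        baseline_pose=aligned_base,
    )


def _window_slice(track_fps: float, onset_frame: int, n_frames: int,
                  window_ms: float) -> slice:
    stop = onset_frame + int(round(window_ms * track_fps / 1000.0)) + 1
    return slice(onset_frame, min(stop, n_frames))


def displacement_series(
    track: PoseTrack,
    window_ms: float = 300.0,
    parts: tuple[str, ...] | None = None,
    base_pose: dict[str, tuple[float, float]] | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, float | None]]:
    """Distance from baseline per frame per part, and maxima in the window."""
    if parts is None:
        parts = tuple(p for p in ANALYSIS_PARTS if p in track.parts) or tuple(track.parts)
    if base_pose is None:
        base_pose = baseline_pose(track)
    win = _window_slice(track.fps, track.onset_frame, track.n_frames, window_ms)
    series: dict[str, np.ndarray] = {}
    maxima: dict[str, float | None] = {}
    for p in parts:
        bx, by = base_pose[p]
        xy = track.xy(p)
        d = np.hypot(xy[:, 0] - bx, xy[:, 1] - by)
        series[p] = d
        dw = d[win]
        maxima[p] = float(np.nanmax(dw)) if np.isfinite(dw).any() else None
    return series, maxima


def paw_nose_metrics(
    track: PoseTrack,
    window_ms: float = 300.0,
    paw_part: str | None = None,
    nose_part: str = "nose",
) -> tuple[float | None, float | None, np.ndarray]:
    """Min and max stimulated-paw-to-nose distance in the window, plus series."""
    if paw_part is None:
        if track.stimulated_side not in ("left", "right"):
            raise PawkitError("stimulated side unknown; pass paw_part explicitly")
        paw_part = f"{track.stimulated_side}_hind_digits"
    paw = track.xy(paw_part)
    nose = track.xy(nose_part)
    d = np.hypot(paw[:, 0] - nose[:, 0], paw[:, 1] - nose[:, 1])
    win = _window_slice(track.fps, track.onset_frame, track.n_frames, window_ms)
    dw = d[win]
    if not np.isfinite(dw).any():
        return None, None, d
    return float(np.nanmin(dw)), float(np.nanmax(dw)), d


def _wrap_deg(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles to (-180, 180]."""
    return -((-np.asarray(a) + 180.0) % 360.0 - 180.0)


def head_yaw_series(
    track: PoseTrack,
    window_ms: float = 300.0,
    nose_part: str = "nose",
    origin_part: str = "tail_base",
    baseline_frames: int = 10,
) -> tuple[np.ndarray, float | None]:
    """Head yaw (deg) relative to the baseline body axis, and its circular mean.

    Yaw is the angle of the tail-base-to-nose vector minus its baseline
    circular mean, wrapped to (-180, 180]; the sign is positive when the nose
    rotates toward the stimulated side (as viewed in the image). Frames where
    either label is missing, or where the vector has zero length, are NaN.
    The mean over the post-stimulus window is circular.
    """
    nose = track.xy(nose_part)
    origin = track.xy(origin_part)
    dx = nose[:, 0] - origin[:, 0]
    dy = origin[:, 1] - nose[:, 1]  # flip to y-up for a math-convention angle
    ang = np.degrees(np.arctan2(dy, dx))
    zero = np.hypot(dx, dy) == 0
    ang[zero] = np.nan
    end = track.onset_frame
    start = end - baseline_frames
    if start < 0:
        raise PawkitError("insufficient pre-onset frames for baseline yaw")
    base_seg = ang[start:end]
    base_seg = base_seg[np.isfinite(base_seg)]
    if base_seg.size == 0:
        raise PawkitError("baseline yaw undefined (labels missing)")
    base_ang = float(circmean(base_seg, high=180.0, low=-180.0))
    raw = _wrap_deg(ang - base_ang)
    # orient: positive = toward the stimulated side. With y-up angles, the
    # stimulated side sits toward angle 0 (right) or 180 (left); rotating the
    # nose toward it decreases |angle - side_angle|. For a nose above the
    # body axis (sin(base) > 0) rotation toward the right side is clockwise,
    # i.e. a negative raw yaw, so flip the sign; mirror for the left side.
    side = track.stimulated_side
    s = 1.0
    if side in ("left", "right"):
        sin_b = np.sin(np.radians(base_ang))
        toward_right = -1.0 if sin_b > 0 else 1.0
        s = toward_right if side == "right" else -toward_right
    yaw = s * raw
    win = _window_slice(track.fps, track.onset_frame, track.n_frames, window_ms)
    yw = yaw[win]
    yw = yw[np.isfinite(yw)]
    mean_yaw = (
        float(_wrap_deg(circmean(yw, high=180.0, low=-180.0))) if yw.size else None
    )
    return yaw, mean_yaw


def summarize_kinematics(
    track: PoseTrack,
    window_ms: float = 300.0,
    parts: tuple[str, ...] | None = None,
) -> KinematicsSummary:
    """Bundle per-part onsets, displacement maxima, paw-nose range and yaw."""
    if parts is None:
        parts = tuple(p for p in ANALYSIS_PARTS if p in track.parts) or tuple(track.parts)
    onsets = {p: movement_onset(track, p) for p in parts}
    _, maxima = displacement_series(track, window_ms, parts)
    try:
        dmin, dmax, _ = paw_nose_metrics(track, window_ms)
    except (PawkitError, KeyError):
        dmin = dmax = None
    try:
        _, mean_yaw = head_yaw_series(track, window_ms)
    except (PawkitError, KeyError):
        mean_yaw = None
    return KinematicsSummary(
        onset_ms=onsets,
        max_displacement_px=maxima,
        paw_nose_min_px=dmin,
        paw_nose_max_px=dmax,
        mean_yaw_deg=mean_yaw,
    )
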