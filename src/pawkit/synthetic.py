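"""Synthetic trials with known ground truth.

Every analysis stage in the toolkit has a matching generator here so the
whole pipeline can be exercised in a closed loop: FTIR-style ROI traces with
programmed withdrawal latencies, rise times and extents; whole-body frame
stacks with a textured blob that starts translating at a programmed onset
(plus an optional saturated stimulus disc at one hind paw); hierarchically
structured (mouse -> trial) pose cohorts with programmed per-part onsets,
displacement directions and head-yaw effects; and pulse-train response
outcomes following the probability sum rule.

Ground-truth conventions:

* a trial's ``true_latency_ms`` is the time at which the noise-free trace
  crosses the detectability level (baseline mean - 5 x programmed noise SD),
  so the closed loop with the sd5 detector is exact up to noise and frame
  quantisation;
* all generators are deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import ANALYSIS_PARTS, FrameStack, PoseTrack, ROITrace
from .errors import ValidationError


@dataclass
class TrialGroundTruth:
    """Programmed truth for one synthetic trial."""

    responded: bool
    true_latency_ms: float | None = None
    true_rise_time_ms: float | None = None
    true_extent: float | None = None
    part_onsets_ms: dict[str, float] = field(default_factory=dict)
    stimulated_side: str = "unknown"
    true_head_yaw_deg: float | None = None
    mouse_id: str = "m0"
    trial_id: str = "t0"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.responded and (
            self.true_latency_ms is not None or self.true_extent is not None
        ):
            raise ValidationError("non-responding trials carry no latency/extent")
        if self.true_extent is not None and not (0 <= self.true_extent <= 1):
            raise ValidationError("extent must lie in [0, 1]")


@dataclass
class CohortSpec:
    """Study conditions for synthetic cohorts.

    Defaults mirror the published recording conditions: 1000 fps local view
    and 400 fps whole-body view, 500 ms baseline in 1.5 s trials, 8-bit
    baseline around 100 with noise SD 2, withdrawal latencies near 30 ms
    with 2 ms mouse-level and 5 ms trial-level spread, ~4 ms 20-80% rise
    times, 90% signal extent, and a 29 ms stimulated-paw movement onset.
    """

    n_mice: int = 8
    trials_per_mouse: int = 8
    # hierarchy
    mouse_latency_sd_ms: float = 2.0
    mouse_magnitude_sd: float = 0.0
    # response model
    response_p: float = 0.8          # per-pulse response probability
    n_pulses: int = 1
    isi_ms: float = 100.0
    # trial-level latency distribution
    latency_loc_ms: float = 30.0
    latency_scale_ms: float = 5.0
    # FTIR trace shape
    baseline_mean: float = 100.0
    noise_sd: float = 2.0
    extent: float = 0.9
    rise_2080_ms: float = 4.0
    waveform: str = "logistic"       # or "linear"
    # timing / cameras
    fps_local: float = 1000.0
    fps_wholebody: float = 400.0
    duration_ms: float = 1500.0
    onset_ms: float = 500.0
    # whole-body stack
    frame_size: tuple[int, int] = (96, 96)
    wholebody_noise_sd: float = 1.5
    blob_speed_px: float = 2.0
    # pose cohort
    paw_onset_ms: float = 29.0
    paw_onset_trial_sd_ms: float = 1.0
    jitter_sd_px: float = 0.1
    dropout_frac: float = 0.0
    head_yaw_deg: float = 20.0
    # across-trial variability (initial pose and movement realisation)
    trial_translation_sd_px: float = 4.0
    trial_pose_sd_px: float = 2.0
    direction_jitter_deg: float = 25.0
    trial_magnitude_sd: float = 0.2
    head_yaw_trial_sd_deg: float = 5.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.response_p <= 1.0):
            raise ValidationError("response_p must lie in [0, 1]")
        if self.n_mice < 1 or self.trials_per_mouse < 1:
            raise ValidationError("need at least one mouse and one trial per mouse")
        if not (0.0 <= self.extent <= 1.0):
            raise ValidationError("extent must lie in [0, 1]")
        if self.waveform not in ("logistic", "linear"):
            raise ValidationError(f"unknown waveform {self.waveform!r}")
        if not (0.0 <= self.dropout_frac < 1.0):
            raise ValidationError("dropout_frac must lie in [0, 1)")


# ---------------------------------------------------------------------------
# FTIR traces
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


_LOGISTIC_A = 4.0  # steepness of the truncated-logistic fall over [0, 1]


def _logistic_frac(u: np.ndarray) -> np.ndarray:
    """Normalized truncated-logistic fall fraction g(u) on [0, 1]."""
    a = _LOGISTIC_A
    lo, hi = _sigmoid(-a), _sigmoid(a)
    u = np.clip(u, 0.0, 1.0)
    return (_sigmoid(a * (2.0 * u - 1.0)) - lo) / (hi - lo)


def _logistic_frac_inv(q: float) -> float:
    """Inverse of :func:`_logistic_frac` for q in (0, 1)."""
    a = _LOGISTIC_A
    lo, hi = _sigmoid(-a), _sigmoid(a)
    c = q * (hi - lo) + lo
    x = np.log(c / (1.0 - c))
    return float((x / a + 1.0) / 2.0)


def _fall_profile(
    t_ms: np.ndarray, latency_ms: float, depth: float, rise_2080_ms: float,
    detect_drop: float, waveform: str,
) -> np.ndarray:
    """Signal drop (0..depth) vs time, crossing ``detect_drop`` at latency."""
    q = min(max(detect_drop / depth, 0.0), 0.5) if depth > 0 else 0.0
    if waveform == "linear":
        total = rise_2080_ms / 0.6
        t0 = latency_ms - q * total
        u = (t_ms - t0) / total
        return depth * np.clip(u, 0.0, 1.0)
    span = _logistic_frac_inv(0.8) - _logistic_frac_inv(0.2)
    total = rise_2080_ms / span
    u_star = _logistic_frac_inv(q) if q > 0 else 0.0
    t0 = latency_ms - u_star * total
    return depth * _logistic_frac((t_ms - t0) / total)


def gen_ftir_trial(
    spec: CohortSpec,
    seed: int | np.random.Generator,
    responded: bool | None = None,
    latency_ms: float | None = None,
    render_stack: bool = False,
    mouse_id: str = "m0",
    trial_id: str = "t0",
    mouse_latency_shift_ms: float = 0.0,
) -> tuple[ROITrace, FrameStack | None, TrialGroundTruth]:
    """One synthetic FTIR trial: noisy baseline plus an optional programmed fall.

    The noise-free responding trace equals ``baseline_mean`` until shortly
    before ``true_latency_ms``, where a logistic (or linear) fall of final
    depth ``extent * baseline_mean`` and programmed 20-80% time begins; the
    fall is placed so it crosses ``baseline_mean - 5 * noise_sd`` exactly at
    the true latency. Gaussian noise of SD ``noise_sd`` is added and the
    trace clipped to [0, 255].
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(spec.duration_ms * spec.fps_local / 1000.0))
    onset = int(round(spec.onset_ms * spec.fps_local / 1000.0))
    t_ms = (np.arange(n) - onset) * 1000.0 / spec.fps_local
    if responded is None:
        responded = bool(rng.random() < (1.0 - (1.0 - spec.response_p) ** spec.n_pulses))
    clean = np.full(n, spec.baseline_mean)
    gt_latency = gt_extent = gt_rise = None
    if responded:
        if latency_ms is None:
            latency_ms = float(
                max(spec.latency_loc_ms + mouse_latency_shift_ms
                    + rng.normal(0.0, spec.latency_scale_ms), 12.0)
            )
        # events live on the frame grid: snap the programmed crossing time
        # to the nearest frame so frame-grain detection is well-posed
        latency_ms = round(latency_ms * spec.fps_local / 1000.0) * 1000.0 / spec.fps_local
        depth = spec.extent * spec.baseline_mean
        drop = _fall_profile(
            t_ms, latency_ms, depth, spec.rise_2080_ms,
            detect_drop=5.0 * spec.noise_sd, waveform=spec.waveform,
        )
        clean = clean - drop
        gt_latency, gt_extent, gt_rise = latency_ms, spec.extent, spec.rise_2080_ms
    noisy = np.clip(clean + rng.normal(0.0, spec.noise_sd, size=n), 0.0, 255.0)
    trace = ROITrace(intensity=noisy, fps=spec.fps_local, onset_frame=onset,
                     mouse_id=mouse_id, trial_id=trial_id)
    stack = None
    if render_stack:
        h = w = 32
        yy, xx = np.mgrid[0:h, 0:w]
        disc = (np.hypot(yy - h / 2, xx - w / 2) <= 10).astype(float)
        frames = disc[None] * noisy[:, None, None]
        frames = np.clip(frames + rng.normal(0, spec.noise_sd, frames.shape), 0, 255)
        stack = FrameStack(frames=frames.astype(np.uint8), fps=spec.fps_local,
                           onset_frame=onset)
    gt = TrialGroundTruth(
        responded=responded, true_latency_ms=gt_latency,
        true_rise_time_ms=gt_rise, true_extent=gt_extent,
        mouse_id=mouse_id, trial_id=trial_id,
    )
    return trace, stack, gt


def gen_ftir_cohort(
    spec: CohortSpec, seed: int
) -> tuple[list[ROITrace], list[TrialGroundTruth]]:
    """A mouse -> trial nested cohort of FTIR traces.

    Mouse effects are additive Gaussian shifts (SD ``mouse_latency_sd_ms``)
    on the trial latency location.
    """
    rng = np.random.default_rng(seed)
    traces, gts = [], []
    for m in range(spec.n_mice):
        shift = rng.normal(0.0, spec.mouse_latency_sd_ms)
        for t in range(spec.trials_per_mouse):
            trace, _, gt = gen_ftir_trial(
                spec, rng, mouse_id=f"m{m}", trial_id=f"t{t}",
                mouse_latency_shift_ms=shift,
            )
            traces.append(trace)
            gts.append(gt)
    return traces, gts


# ---------------------------------------------------------------------------
# Whole-body frame stacks
# ---------------------------------------------------------------------------

#: Default body-part layout (viewer coordinates, y down) within the default
#: 96 x 96 whole-body frame.
DEFAULT_POSE: dict[str, tuple[float, float]] = {
    "nose": (48.0, 20.0),
    "left_hind_digits": (30.0, 70.0),
    "left_hind_heel": (33.0, 76.0),
    "right_hind_digits": (66.0, 70.0),
    "right_hind_heel": (63.0, 76.0),
    "tail_base": (48.0, 80.0),
}


def gen_wholebody_trial(
    spec: CohortSpec,
    seed: int | np.random.Generator,
    move: bool | None = None,
    motion_onset_frame: int | None = None,
    stimulated_side: str | None = None,
    stimulus_disc: bool = True,
    n_frames: int = 100,
    onset_frame: int = 40,
) -> tuple[FrameStack, TrialGroundTruth]:
    """One whole-body trial: textured blob that translates at a known frame.

    The scene is a static random texture plus per-frame Gaussian sensor
    noise; a high-contrast textured disc (the "body") starts translating at
    ``blob_speed_px`` px/frame from ``motion_onset_frame`` (default: the
    stimulus-onset frame). During the stimulus frames a saturated disc is
    drawn at the stimulated hind paw position so limb detection can be
    exercised.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    h, w = spec.frame_size
    if move is None:
        move = bool(rng.random() < (1.0 - (1.0 - spec.response_p) ** spec.n_pulses))
    if motion_onset_frame is None:
        motion_onset_frame = onset_frame
    if stimulated_side is None:
        stimulated_side = "left" if rng.random() < 0.5 else "right"
    background = rng.integers(40, 80, size=(h, w)).astype(float)
    texture = rng.integers(0, 256, size=(h, w)).astype(float)
    yy, xx = np.mgrid[0:h, 0:w]
    r_blob = 12.0
    cx0, cy0 = w / 2.0, h / 2.0
    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    paw = DEFAULT_POSE[f"{stimulated_side}_hind_digits"]
    # a 10 ms pulse spans 4 frames at 400 fps
    stim_frames = tuple(range(onset_frame, onset_frame + 4))
    for f in range(n_frames):
        shift = spec.blob_speed_px * max(f - motion_onset_frame + 1, 0) if move else 0.0
        cx = cx0 + shift
        mask = np.hypot(yy - cy0, xx - cx) <= r_blob
        img = background.copy()
        # texture sampled in blob-attached coordinates so the pattern moves
        src_x = np.clip((xx - shift).astype(int), 0, w - 1)
        img[mask] = texture[yy[mask], src_x[mask]]
        if spec.wholebody_noise_sd > 0:
            img = img + rng.normal(0.0, spec.wholebody_noise_sd, size=(h, w))
        if stimulus_disc and f in stim_frames:
            disc = np.hypot(yy - paw[1], xx - paw[0]) <= 8
            img[disc] = 255.0
        frames[f] = np.clip(img, 0, 255).astype(np.uint8)
    gt = TrialGroundTruth(
        responded=move,
        true_latency_ms=(
            (motion_onset_frame - onset_frame) * 1000.0 / spec.fps_wholebody
            if move else None
        ),
        stimulated_side=stimulated_side,
        extra={
            "motion_onset_frame": motion_onset_frame if move else None,
            "pose": dict(DEFAULT_POSE),
            "stimulation_frames": stim_frames,
        },
    )
    stack = FrameStack(frames=frames, fps=spec.fps_wholebody, onset_frame=onset_frame)
    return stack, gt


def static_pose_track(
    gt: TrialGroundTruth, n_frames: int, fps: float, onset_frame: int
) -> PoseTrack:
    """A static PoseTrack at the ground-truth part layout (for limb detection)."""
    pose = gt.extra.get("pose", DEFAULT_POSE)
    parts = list(ANALYSIS_PARTS)
    x = np.tile([pose[p][0] for p in parts], (n_frames, 1))
    y = np.tile([pose[p][1] for p in parts], (n_frames, 1))
    lik = np.full_like(x, 0.99)
    return PoseTrack(
        x=x, y=y, likelihood=lik, parts=parts, fps=fps, onset_frame=onset_frame,
        stimulation_frames=tuple(gt.extra.get("stimulation_frames", ())),
        stimulated_side=gt.stimulated_side,
    )


# ---------------------------------------------------------------------------
# Pose cohorts
# ---------------------------------------------------------------------------

#: Post-onset movement direction per part (unit-ish vectors, viewer coords).
_MOVE_DIRECTIONS = {
    "left_hind_digits": (-1.0, 0.3),
    "left_hind_heel": (-1.0, 0.3),
    "right_hind_digits": (1.0, 0.3),
    "right_hind_heel": (1.0, 0.3),
}

_PART_ONSET_OFFSETS_MS = {"contra": 3.0}

#: Nose movement begins just after the laser-contaminated frames (the five
#: stimulation frames span 12.5 ms at 400 fps) so its onset is measurable.
_NOSE_ONSET_MS = 12.5


def gen_pose_trial(
    spec: CohortSpec,
    rng: np.random.Generator,
    stimulated_side: str,
    mouse_onset_shift_ms: float = 0.0,
    mouse_magnitude_scale: float = 1.0,
    respond: bool = True,
    n_frames: int = 220,
    onset_frame: int = 60,
    mouse_id: str = "m0",
    trial_id: str = "t0",
) -> tuple[PoseTrack, TrialGroundTruth]:
    """One pose trial with programmed per-part onsets and head yaw."""
    parts = list(ANALYSIS_PARTS)
    fps = spec.fps_wholebody
    # initial pose varies across trials: a common translation of the whole
    # body plus small per-part conformational shifts
    shift_xy = rng.normal(0.0, spec.trial_translation_sd_px, size=2)
    base = {
        p: (
            DEFAULT_POSE[p][0] + shift_xy[0] + rng.normal(0.0, spec.trial_pose_sd_px),
            DEFAULT_POSE[p][1] + shift_xy[1] + rng.normal(0.0, spec.trial_pose_sd_px),
        )
        for p in parts
    }
    x = np.tile([base[p][0] for p in parts], (n_frames, 1)).astype(float)
    y = np.tile([base[p][1] for p in parts], (n_frames, 1)).astype(float)
    part_onsets: dict[str, float] = {}
    yaw_deg = None
    if respond:
        stim_prefix = stimulated_side
        contra_prefix = "right" if stimulated_side == "left" else "left"
        paw_on = max(
            spec.paw_onset_ms + mouse_onset_shift_ms
            + rng.normal(0.0, spec.paw_onset_trial_sd_ms),
            2.0,
        )
        onset_by_part = {
            f"{stim_prefix}_hind_digits": paw_on,
            f"{stim_prefix}_hind_heel": paw_on,
            f"{contra_prefix}_hind_digits": paw_on + _PART_ONSET_OFFSETS_MS["contra"],
            f"{contra_prefix}_hind_heel": paw_on + _PART_ONSET_OFFSETS_MS["contra"],
            "nose": _NOSE_ONSET_MS,
        }
        # ~1 m/s paw speed at 0.32 mm/px and 400 fps; stays well above the
        # 0.5 px/frame persistence floor across magnitude draws
        speed = (2.5 * mouse_magnitude_scale
                 * float(np.exp(rng.normal(0.0, spec.trial_magnitude_sd))))
        move_frames = 40
        for p, on_ms in onset_by_part.items():
            part_onsets[p] = float(on_ms)
            j = parts.index(p)
            f0 = onset_frame + int(round(on_ms * fps / 1000.0))
            if p == "nose":
                continue  # nose follows the yaw rotation below
            dx, dy = _MOVE_DIRECTIONS[p]
            # per-trial realisation of the movement direction
            rot = np.radians(rng.normal(0.0, spec.direction_jitter_deg))
            c, s = np.cos(rot), np.sin(rot)
            dx, dy = dx * c - dy * s, dx * s + dy * c
            norm = float(np.hypot(dx, dy))
            for f in range(f0, n_frames):
                steps = min(f - f0 + 1, move_frames)
                x[f, j] += speed * steps * dx / norm
                y[f, j] += speed * steps * dy / norm
        # head yaw: nose rotates about the tail base toward the stimulated
        # side with a fast ramp (so the 300 ms window mean sits near the
        # plateau), then drifts radially outward so the persistence-based
        # onset detector keeps seeing motion without changing the angle
        yaw_deg = float(
            (spec.head_yaw_deg + rng.normal(0.0, spec.head_yaw_trial_sd_deg))
            * mouse_magnitude_scale
        )
        jn = parts.index("nose")
        jt = parts.index("tail_base")
        dx0 = base["nose"][0] - base["tail_base"][0]
        dy0 = base["tail_base"][1] - base["nose"][1]  # y-up
        radius = float(np.hypot(dx0, dy0))
        phi0 = float(np.arctan2(dy0, dx0))  # baseline y-up angle of tail->nose
        f0 = onset_frame + int(round(onset_by_part["nose"] * fps / 1000.0))
        ramp_frames = max(int(round(7.5 * fps / 1000.0)), 1)
        drift_frames = 40
        sign = 1.0 if stimulated_side == "right" else -1.0
        for f in range(f0, n_frames):
            frac = min((f - f0 + 1) / ramp_frames, 1.0)
            theta = np.radians(yaw_deg * frac)
            phi = phi0 - sign * theta
            drift = 1.0 * min(max(f - f0 + 1 - ramp_frames, 0), drift_frames)
            r = radius + drift
            x[f, jn] = x[f, jt] + r * np.cos(phi)
            y[f, jn] = y[f, jt] - r * np.sin(phi)
    x += rng.normal(0.0, spec.jitter_sd_px, size=x.shape)
    y += rng.normal(0.0, spec.jitter_sd_px, size=y.shape)
    lik = np.full(x.shape, 0.99)
    if spec.dropout_frac > 0:
        drop = rng.random(x.shape) < spec.dropout_frac
        lik[drop] = rng.uniform(0.0, 0.94, size=int(drop.sum()))
    stim_frames = tuple(range(onset_frame, onset_frame + 5))
    track = PoseTrack(
        x=x, y=y, likelihood=lik, parts=parts, fps=fps, onset_frame=onset_frame,
        stimulation_frames=stim_frames, stimulated_side=stimulated_side,
        mm_per_px=0.32,
    )
    gt = TrialGroundTruth(
        responded=respond,
        true_latency_ms=part_onsets.get(f"{stimulated_side}_hind_digits"),
        part_onsets_ms=part_onsets,
        stimulated_side=stimulated_side,
        true_head_yaw_deg=yaw_deg if respond else None,
        mouse_id=mouse_id, trial_id=trial_id,
        extra={"dropout_frac": spec.dropout_frac},
    )
    return track, gt


def gen_pose_cohort(
    spec: CohortSpec, seed: int, respond_all: bool = True
) -> tuple[list[PoseTrack], list[TrialGroundTruth]]:
    """A nested cohort of pose trials with mouse-level random effects."""
    rng = np.random.default_rng(seed)
    tracks, gts = [], []
    for m in range(spec.n_mice):
        shift = rng.normal(0.0, spec.mouse_latency_sd_ms)
        scale = float(np.exp(rng.normal(0.0, spec.mouse_magnitude_sd)))
        for t in range(spec.trials_per_mouse):
            side = "left" if rng.random() < 0.5 else "right"
            respond = True if respond_all else bool(rng.random() < spec.response_p)
            track, gt = gen_pose_trial(
                spec, rng, stimulated_side=side, mouse_onset_shift_ms=shift,
                mouse_magnitude_scale=scale, respond=respond,
                mouse_id=f"m{m}", trial_id=f"t{t}",
            )
            tracks.append(track)
            gts.append(gt)
    return tracks, gts


def inject_glitches(
    track: PoseTrack, schedule: dict[str, list[int]], magnitude_px: float = 12.0
) -> PoseTrack:
    """Displace single frames by ``magnitude_px`` (the next frame returns).

    Emulates tracker glitches for testing the jump-removal rule; the
    returned track's ``meta['glitch_schedule']`` records the injection.
    """
    out = track.copy()
    for part, frames in schedule.items():
        j = out.part_index(part)
        for f in frames:
            out.x[f, j] += magnitude_px
    out.meta["glitch_schedule"] = {p: list(fs) for p, fs in schedule.items()}
    return out


# ---------------------------------------------------------------------------
# Pulse trains
# ---------------------------------------------------------------------------

def _truncated_normal(
    rng: np.random.Generator, loc: float, scale: float, low: float, high: float,
    size: int,
) -> np.ndarray:
    """Rejection-sampled normal restricted to [low, high]."""
    out = np.empty(size)
    todo = np.arange(size)
    while todo.size:
        draw = rng.normal(loc, scale, size=todo.size)
        ok = (draw >= low) & (draw <= high)
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def gen_pulse_train_outcomes(
    p: float,
    n_pulses: int,
    isi_ms: float,
    latency_loc_ms: float = 60.0,
    latency_scale_ms: float = 15.0,
    latency_max_ms: float = 95.0,
    n_trials: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulated trial outcomes for a train of optogenetic pulses.

    Each pulse independently triggers a response with probability ``p``; a
    trial's latency is the onset time of its first triggering pulse plus a
    per-pulse reaction time drawn from a truncated normal. The reaction-time
    support is capped at ``latency_max_ms`` (below any inter-stimulus
    interval of interest) so every response is attributable to a unique
    pulse — which is what makes pulse-matched latency distributions
    superimpose across frequencies by construction.
    """
    if not (0.0 <= p <= 1.0):
        raise ValidationError("p must lie in [0, 1]")
    if n_pulses < 1:
        raise ValidationError("n_pulses must be >= 1")
    rng = np.random.default_rng(seed)
    triggers = rng.random((n_trials, n_pulses)) < p
    responded = triggers.any(axis=1)
    first = np.where(responded, triggers.argmax(axis=1), -1)
    latency = np.full(n_trials, np.nan)
    n_resp = int(responded.sum())
    if n_resp:
        rt = _truncated_normal(rng, latency_loc_ms, latency_scale_ms,
                               0.0, latency_max_ms, n_resp)
        latency[responded] = first[responded] * isi_ms + rt
    return pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "responded": responded,
            "first_pulse": first,
            "latency_ms": latency,
        }
    )


def gen_nested_values(
    n_mice: int = 8,
    trials_per_mouse: int = 8,
    center: float = 30.0,
    mouse_sd: float = 2.0,
    trial_sd: float = 5.0,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Gaussian mouse -> trial nested values for bootstrap recovery tests."""
    rng = np.random.default_rng(seed)
    return {
        f"m{m}": center + rng.normal(0.0, mouse_sd)
        + rng.normal(0.0, trial_sd, size=trials_per_mouse)
        for m in range(n_mice)
    }


def with_overrides(spec: CohortSpec, **kwargs) -> CohortSpec:
    """A copy of ``spec`` with fields replaced (convenience for tests/CLI)."""
    return replace(spec, **kwargs)
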