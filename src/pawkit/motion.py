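"""Binarized motion energy and global-response timing.

Whole-body movement is quantified without tracking: for every pair of
consecutive frames, each pixel is assigned 1 if its absolute 8-bit change
exceeds a noise threshold (5 at 40 fps, 7 at 400 fps) and 0 otherwise, and
the binary values are summed per frame pair. The resulting "binarized motion
energy" trace, normalized to its pre-stimulus baseline, yields a peak
magnitude and — by threshold crossing at a multiple of the baseline SD — the
onset, termination and duration of the first movement bout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import FrameStack
from .errors import ConfigError, ValidationError


@dataclass
class MotionEnergyTrace:
    """Summed binary pixel changes per retained frame pair.

    ``frame_index`` holds, for each pair, the index of the later frame in the
    original stack; laser-affected frames are dropped before pairing, so
    pairs may span a gap.
    """

    counts: np.ndarray
    frame_index: np.ndarray
    fps: float
    onset_frame: int
    delta_threshold: float
    total_pixels: int
    excluded_frames: tuple[int, ...] = ()

    @property
    def n_pairs(self) -> int:
        return self.counts.size

    def time_ms(self) -> np.ndarray:
        """Time of each pair (later frame) in ms relative to stimulus onset."""
        return (self.frame_index - self.onset_frame) * 1000.0 / self.fps


@dataclass
class NormalizedMotion:
    """Baseline-subtracted (optionally pixel-normalized) motion energy."""

    values: np.ndarray
    time_ms: np.ndarray
    baseline_mean: float
    baseline_mask: np.ndarray
    per_pixel: bool


@dataclass
class GlobalResponse:
    """Whole-body response summary from normalized motion energy."""

    peak: float
    peak_ok: bool
    onset_ms: float | None
    bout_end_ms: float | None
    duration_ms: float | None
    peak_k: float
    onset_k: float
    baseline_sd: float

    def __post_init__(self) -> None:
        if (
            self.onset_ms is not None
            and self.bout_end_ms is not None
            and self.bout_end_ms < self.onset_ms
        ):
            raise ValidationError("bout end precedes onset")


def binarized_motion_energy(
    stack: FrameStack,
    delta_threshold: float = 5.0,
    excluded_frames: tuple[int, ...] | list[int] = (),
) -> MotionEnergyTrace:
    """Count pixels changing by more than ``delta_threshold`` per frame pair.

    A change of exactly the threshold counts as no change (strict ``>``).
    ``excluded_frames`` (e.g. frames bleached by the stimulation laser) are
    removed before pairing, so the trace skips over them.
    """
    if delta_threshold < 0:
        raise ConfigError("delta_threshold must be >= 0")
    keep = np.setdiff1d(np.arange(stack.n_frames), np.asarray(excluded_frames, int))
    if keep.size < 2:
        raise ValidationError("need at least 2 retained frames")
    frames = stack.frames[keep].astype(np.int16)
    deltas = np.abs(np.diff(frames, axis=0))
    counts = (deltas > delta_threshold).sum(axis=(1, 2))
    return MotionEnergyTrace(
        counts=counts.astype(np.int64),
        frame_index=keep[1:],
        fps=stack.fps,
        onset_frame=stack.onset_frame,
        delta_threshold=float(delta_threshold),
        total_pixels=int(stack.frames.shape[1] * stack.frames.shape[2]),
        excluded_frames=tuple(int(f) for f in excluded_frames),
    )


def normalize_motion(
    trace: MotionEnergyTrace,
    baseline_window: tuple[int, int] | None = None,
    per_pixel: bool = False,
) -> NormalizedMotion:
    """Subtract the baseline-mean motion energy from each frame pair.

    Positive values mean more motion than baseline (so the peak is a
    maximum). With ``per_pixel=True`` counts are first divided by the number
    of pixels per frame — the convention of the high-frame-rate analysis.
    ``baseline_window`` is a frame range; the default is all pre-onset pairs.
    """
    if baseline_window is None:
        baseline_window = (0, trace.onset_frame)
    start, stop = baseline_window
    mask = (trace.frame_index >= start) & (trace.frame_index < stop)
    if not mask.any():
        raise ValidationError("baseline window contains no frame pairs")
    values = trace.counts.astype(float)
    if per_pixel:
        values = values / trace.total_pixels
    base = float(values[mask].mean())
    return NormalizedMotion(
        values=values - base,
        time_ms=trace.time_ms(),
        baseline_mean=base,
        baseline_mask=mask,
        per_pixel=per_pixel,
    )


def detect_global_response(
    norm: NormalizedMotion,
    peak_k: float = 5.0,
    onset_k: float = 10.0,
    peak_window_ms: float | None = None,
) -> GlobalResponse:
    """Peak magnitude and first-bout timing from normalized motion energy.

    The peak (optionally restricted to the first ``peak_window_ms`` after
    onset, the time-locking window used for nociceptor trials) must reach
    ``peak_k`` baseline SDs for the trial to be retained. Movement onset is
    the first post-stimulus crossing above ``onset_k`` baseline SDs and the
    bout ends at the first return below that level.
    """
    sd = float(norm.values[norm.baseline_mask].std())
    post = norm.time_ms >= 0
    if not post.any():
        raise ValidationError("no post-stimulus frame pairs")
    if sd == 0:
        warnings.warn(
            "degenerate baseline (SD = 0); falling back to an absolute "
            "threshold of any motion above baseline",
            RuntimeWarning,
            stacklevel=2,
        )
        peak_thr = onset_thr = 0.0
    else:
        peak_thr = peak_k * sd
        onset_thr = onset_k * sd

    peak_sel = post.copy()
    if peak_window_ms is not None:
        peak_sel &= norm.time_ms <= peak_window_ms
    peak = float(norm.values[peak_sel].max()) if peak_sel.any() else float("-inf")
    peak_ok = peak > peak_thr if sd == 0 else peak >= peak_thr

    above = post & (norm.values > onset_thr)
    idx = np.flatnonzero(above)
    onset_ms = bout_end_ms = duration_ms = None
    if idx.size:
        onset_ms = float(norm.time_ms[idx[0]])
        after = np.flatnonzero((np.arange(norm.values.size) > idx[0])
                               & (norm.values <= onset_thr))
        if after.size:
            bout_end_ms = float(norm.time_ms[after[0]])
            duration_ms = bout_end_ms - onset_ms
    return GlobalResponse(
        peak=peak, peak_ok=bool(peak_ok), onset_ms=onset_ms,
        bout_end_ms=bout_end_ms, duration_ms=duration_ms,
        peak_k=peak_k, onset_k=onset_k, baseline_sd=sd,
    )
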