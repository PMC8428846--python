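"""Shared data carriers: frame stacks, ROI traces, pose tracks.

Conventions used throughout the toolkit:

* frame indices are 0-based; the image origin is top-left with y increasing
  downward (video convention);
* times are reported in milliseconds relative to stimulus onset, so an event
  at frame ``f`` has latency ``(f - onset_frame) * 1000 / fps``;
* sides (left/right) are as viewed in the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, ValidationError


@dataclass
class FrameStack:
    """8-bit grayscale video stack.

    Attributes
    ----------
    frames
        ``(n_frames, height, width)`` uint8 array.
    fps
        Acquisition rate, frames/s.
    onset_frame
        Index of the stimulus-onset frame.
    """

    frames: np.ndarray
    fps: float
    onset_frame: int

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValidationError(
                f"frame stack must be (frames, height, width), got shape {self.frames.shape}"
            )
        if self.fps <= 0:
            raise ConfigError("fps must be > 0")
        if not (0 <= self.onset_frame < self.n_frames):
            raise ConfigError(
                f"stimulus onset frame {self.onset_frame} outside stack of "
                f"{self.n_frames} frames"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    def time_ms(self, frame: int | np.ndarray) -> float | np.ndarray:
        """Time of a frame in ms relative to stimulus onset."""
        return (np.asarray(frame) - self.onset_frame) * 1000.0 / self.fps


@dataclass
class ROITrace:
    """Mean 8-bit intensity inside the stimulation-site ROI, per frame."""

    intensity: np.ndarray
    fps: float
    onset_frame: int
    mouse_id: str = "m0"
    trial_id: str = "t0"

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 1 or self.intensity.size == 0:
            raise ValidationError("intensity must be a non-empty 1-D array")
        if np.nanmin(self.intensity) < 0 or np.nanmax(self.intensity) > 255:
            raise ValidationError("ROI intensities must lie in [0, 255]")
        if self.fps <= 0:
            raise ConfigError("fps must be > 0")
        if not (0 <= self.onset_frame < self.intensity.size):
            raise ConfigError(
                f"onset_frame {self.onset_frame} outside trace of length "
                f"{self.intensity.size}"
            )

    @property
    def n_frames(self) -> int:
        return self.intensity.size

    def time_ms(self, frame: int | np.ndarray) -> float | np.ndarray:
        return (np.asarray(frame) - self.onset_frame) * 1000.0 / self.fps


@dataclass
class PoseTrack:
    """Per-frame (x, y, likelihood) for named body parts.

    ``x``, ``y`` and ``likelihood`` are ``(n_frames, n_parts)`` float arrays;
    removed points are NaN in x/y. ``stimulation_frames`` are the frame
    indices contaminated by the stimulation laser.
    """

    x: np.ndarray
    y: np.ndarray
    likelihood: np.ndarray
    parts: list[str]
    fps: float = 400.0
    onset_frame: int = 0
    stimulation_frames: tuple[int, ...] = ()
    stimulated_side: str = "unknown"
    mm_per_px: float = 0.32
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        if not (self.x.shape == self.y.shape == self.likelihood.shape):
            raise ValidationError("x, y, likelihood must have identical shapes")
        if self.x.ndim != 2 or self.x.shape[1] != len(self.parts):
            raise ValidationError(
                f"expected (n_frames, {len(self.parts)}) arrays, got {self.x.shape}"
            )
        finite = np.isfinite(self.likelihood)
        if finite.any():
            lo, hi = self.likelihood[finite].min(), self.likelihood[finite].max()
            if lo < 0 or hi > 1:
                raise ValidationError(
                    f"likelihoods must lie in [0, 1], found range [{lo}, {hi}]"
                )
        if self.fps <= 0:
            raise ConfigError("fps must be > 0")
        if self.stimulated_side not in ("left", "right", "unknown"):
            raise ValidationError(f"bad stimulated_side {self.stimulated_side!r}")

    @property
    def n_frames(self) -> int:
        return self.x.shape[0]

    @property
    def n_parts(self) -> int:
        return len(self.parts)

    def part_index(self, part: str) -> int:
        try:
            return self.parts.index(part)
        except ValueError as exc:
            raise KeyError(f"unknown body part {part!r}; have {self.parts}") from exc

    def xy(self, part: str) -> np.ndarray:
        """``(n_frames, 2)`` coordinates of one part."""
        j = self.part_index(part)
        return np.column_stack([self.x[:, j], self.y[:, j]])

    def time_ms(self, frame: int | np.ndarray) -> float | np.ndarray:
        return (np.asarray(frame) - self.onset_frame) * 1000.0 / self.fps

    def copy(self) -> "PoseTrack":
        return PoseTrack(
            x=self.x.copy(),
            y=self.y.copy(),
            likelihood=self.likelihood.copy(),
            parts=list(self.parts),
            fps=self.fps,
            onset_frame=self.onset_frame,
            stimulation_frames=tuple(self.stimulation_frames),
            stimulated_side=self.stimulated_side,
            mm_per_px=self.mm_per_px,
            meta=dict(self.meta),
        )


#: Canonical analysis parts for whole-body pose work.
ANALYSIS_PARTS = (
    "nose",
    "left_hind_digits",
    "left_hind_heel",
    "right_hind_digits",
    "right_hind_heel",
    "tail_base",
)
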