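"""Run configuration and calibrated constants.

A :class:`RunConfig` carries everything a pipeline run needs that is not in
the data itself: camera frame rates, the stimulus-onset frame, the baseline
window, the detection rule, and the named thresholds used throughout the
toolkit. Defaults reproduce the published analysis settings; every threshold
is overridable per run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

#: Calibrated laser spot areas (mm^2) for the eight scanned stimulus sizes.
SPOT_AREAS_MM2: dict[str, float] = {
    "S1": 0.0185,
    "S2": 0.0416,
    "S3": 0.0898,
    "S4": 0.176,
    "S5": 0.308,
    "S6": 0.577,
    "S7": 1.155,
    "S8": 2.307,
}

#: Named analysis thresholds with their published defaults.
DEFAULT_THRESHOLDS: dict[str, float] = {
    # withdrawal detection
    "sd_multiple": 5.0,            # sd5 rule: drop below mean - 5*SD
    "strict_fall_frac": 0.20,      # strict rule: fall by 20% of baseline ...
    "strict_sd_multiple": 4.0,     # ... and exceed 4*SD of baseline
    "full_extent_pct": 75.0,       # >=75% signal decrease = full response
    "roi_diameter_px": 60.0,       # circular ROI on the stimulation site
    # trace quality control
    "qc_min_baseline_mean": 3.0,
    "qc_snr": 23.0,                # baseline mean/SD floor (see docs/methods)
    "qc_min_latency_ms": 10.0,     # latencies <=10 ms are implausible
    # motion energy
    "delta_threshold_lowspeed": 5.0,   # 8-bit units, 40 fps whole-body view
    "delta_threshold_highspeed": 7.0,  # 8-bit units, 400 fps view
    "peak_k": 5.0,                 # peak must reach peak_k * baseline SD
    "onset_k": 10.0,               # onset/termination at onset_k * baseline SD
    # pose post-processing
    "p_cutoff": 0.95,              # tracking-likelihood floor
    "jump_px": 10.0,               # single-frame jump threshold
    "max_missing_frac": 0.10,
    "max_bad_frames": 10.0,
    "min_disp_px": 0.5,            # movement-onset displacement floor
    "min_rate_px_per_frame": 0.5,
    "persist_frames": 10.0,
    "mm_per_px": 0.32,             # 400 fps whole-body camera scale
    "limb_window_px": 60.0,        # saturation window for limb detection
    "limb_t_pre_ms": 7.5,
    "limb_t_post_ms": 5.0,
}

_RULES = ("sd5", "strict")


@dataclass
class RunConfig:
    """Configuration for a pipeline run.

    Parameters
    ----------
    frame_rate
        Frames per second, either a scalar or a mapping from camera role
        (``"local"``, ``"wholebody"``) to fps.
    stimulus_onset
        Stimulus-onset frame index (0-based).
    baseline_window
        ``(start, stop)`` frame range (half-open) for baseline statistics;
        must end at or before the stimulus onset. ``None`` means all frames
        before the onset.
    detection_rule
        ``"sd5"`` (drop below mean - 5 SD) or ``"strict"`` (fall by 20% of
        baseline and beyond 4 SD).
    thresholds
        Named scalar overrides merged over :data:`DEFAULT_THRESHOLDS`.
    """

    frame_rate: float | dict[str, float] = 1000.0
    stimulus_onset: int = 500
    baseline_window: tuple[int, int] | None = None
    detection_rule: str = "sd5"
    thresholds: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        rates = (
            self.frame_rate.values()
            if isinstance(self.frame_rate, dict)
            else [self.frame_rate]
        )
        if any(r <= 0 for r in rates):
            raise ConfigError("frame_rate must be > 0")
        if self.detection_rule not in _RULES:
            raise ConfigError(
                f"detection_rule must be one of {_RULES}, got {self.detection_rule!r}"
            )
        if self.baseline_window is not None:
            start, stop = self.baseline_window
            if not (0 <= start < stop):
                raise ConfigError(f"invalid baseline_window {self.baseline_window}")
            if stop > self.stimulus_onset:
                raise ConfigError("baseline_window must end at or before stimulus_onset")
        unknown = set(self.thresholds) - set(DEFAULT_THRESHOLDS)
        if unknown:
            raise ConfigError(f"unknown threshold names: {sorted(unknown)}")
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged

    def fps(self, role: str = "local") -> float:
        """Frame rate for a camera role."""
        if isinstance(self.frame_rate, dict):
            try:
                return float(self.frame_rate[role])
            except KeyError as exc:
                raise ConfigError(f"no frame rate for camera role {role!r}") from exc
        return float(self.frame_rate)

    def threshold(self, name: str) -> float:
        return float(self.thresholds[name])

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a config from YAML or JSON (by extension)."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} did not contain a mapping")
        if "baseline_window" in data and data["baseline_window"] is not None:
            data["baseline_window"] = tuple(data["baseline_window"])
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["baseline_window"] is not None:
            d["baseline_window"] = list(d["baseline_window"])
        return d
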