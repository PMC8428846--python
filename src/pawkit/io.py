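"""Readers and writers for the toolkit's file formats.

Frame stacks are exchanged as dense NPY/NPZ arrays or per-frame PNG
directories; AVI/MP4 files are decoded through imageio when a video backend
is available. Pose tables use the DeepLabCut wide CSV layout (3-row header:
scorer / bodyparts / coords) or a flat ``part_x, part_y, part_likelihood``
variant. ROI trace tables are long CSV (``mouse_id, trial_id, time_ms,
intensity``) or wide CSV (a ``time_ms`` column plus one ``mouse/trial``
column per trial). All CSVs are comma-separated UTF-8 with '.' decimals.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .core import FrameStack, PoseTrack, ROITrace
from .errors import ConfigError, FormatError, ParseError, ValidationError

_LUMA = np.array([0.299, 0.587, 0.114])


def _to_gray_u8(frames: np.ndarray) -> np.ndarray:
    frames = np.asarray(frames)
    if frames.ndim == 4:  # multi-channel: collapse by luminance
        frames = frames[..., :3] @ _LUMA
    if frames.ndim != 3:
        raise FormatError(f"cannot interpret array of shape {frames.shape} as a stack")
    return np.clip(np.round(frames), 0, 255).astype(np.uint8)


def read_frame_stack(
    path: str | Path,
    config: RunConfig | None = None,
    fps: float | None = None,
    onset_frame: int | None = None,
    camera: str = "local",
) -> FrameStack:
    """Read an 8-bit grayscale stack from NPY/NPZ, a PNG directory, or video.

    Frame rate and stimulus onset come from ``config`` (or the explicit
    keyword overrides). Multi-channel frames are collapsed by luminance.
    """
    path = Path(path)
    if fps is None:
        fps = config.fps(camera) if config is not None else 1000.0
    if onset_frame is None:
        onset_frame = config.stimulus_onset if config is not None else 0
    if not path.exists():
        raise FormatError(f"no such file or directory: {path}")
    if path.is_dir():
        pngs = sorted(path.glob("*.png"))
        if not pngs:
            raise FormatError(f"directory {path} contains no PNG frames")
        import imageio.v3 as iio

        frames = np.stack([iio.imread(p) for p in pngs])
    elif path.suffix == ".npy":
        frames = np.load(path)
    elif path.suffix == ".npz":
        with np.load(path) as z:
            if "frames" not in z:
                raise FormatError(f"{path} has no 'frames' array (keys: {list(z)})")
            frames = z["frames"]
    elif path.suffix.lower() in (".avi", ".mp4"):
        try:
            import imageio.v3 as iio

            frames = np.stack(list(iio.imiter(path)))
        except Exception as exc:  # no video backend, corrupt file, ...
            raise FormatError(
                f"could not decode video {path} (a video backend such as "
                f"imageio-ffmpeg may be required): {exc}"
            ) from exc
    else:
        raise FormatError(f"unsupported frame-stack format {path.suffix!r}")
    frames = _to_gray_u8(frames)
    if frames.shape[0] == 0:
        raise FormatError(f"{path} contains no frames")
    if onset_frame >= frames.shape[0]:
        raise ConfigError(
            f"stimulus onset frame {onset_frame} beyond last frame "
            f"({frames.shape[0]} frames in {path})"
        )
    return FrameStack(frames=frames, fps=fps, onset_frame=onset_frame)


def write_frame_stack(stack: FrameStack, path: str | Path) -> Path:
    """Write a stack as .npz (key ``frames``) or a per-frame PNG directory."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(path, frames=stack.frames,
                            fps=stack.fps, onset_frame=stack.onset_frame)
    elif path.suffix == ".npy":
        np.save(path, stack.frames)
    else:  # directory of PNGs
        import imageio.v3 as iio

        path.mkdir(parents=True, exist_ok=True)
        width = len(str(stack.n_frames - 1))
        for i in range(stack.n_frames):
            iio.imwrite(path / f"frame_{i:0{width}d}.png", stack.frames[i])
    return path


# ---------------------------------------------------------------------------
# Pose tables (DeepLabCut wide layout)
# ---------------------------------------------------------------------------

def read_pose_table(
    path: str | Path,
    fps: float = 400.0,
    onset_frame: int = 0,
    stimulated_side: str = "unknown",
    stimulation_frames: tuple[int, ...] = (),
) -> PoseTrack:
    """Read a wide pose CSV (DeepLabCut 3-row header or flat single header)."""
    path = Path(path)
    with open(path, newline="") as fh:
        first = fh.readline()
    if first.split(",")[0].strip() in ("scorer", "bodyparts"):
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        parts = list(dict.fromkeys(df.columns.get_level_values(1)))
        cols: dict[str, dict[str, np.ndarray]] = {}
        for part in parts:
            sub = df.xs(part, axis=1, level=1)
            sub.columns = sub.columns.get_level_values(-1)
            cols[part] = {c: sub[c].to_numpy() for c in sub.columns}
    else:
        df = pd.read_csv(path)
        pat = re.compile(r"^(.*)_(x|y|likelihood)$")
        cols = {}
        for c in df.columns:
            m = pat.match(c)
            if m:
                cols.setdefault(m.group(1), {})[m.group(2)] = df[c].to_numpy()
        parts = list(cols)
    if not parts:
        raise FormatError(f"{path} has no recognisable body-part columns")
    for part, d in cols.items():
        missing = {"x", "y", "likelihood"} - set(d)
        if missing:
            raise FormatError(f"part {part!r} is missing columns {sorted(missing)}")
    def _numeric(part: str, name: str, v: np.ndarray) -> np.ndarray:
        arr = pd.to_numeric(pd.Series(v), errors="coerce").to_numpy(float)
        bad = np.flatnonzero(np.isnan(arr) & ~pd.isna(pd.Series(v)).to_numpy())
        if bad.size:
            raise ParseError(
                f"non-numeric value in {part}.{name} at row {int(bad[0])}"
            )
        return arr

    x = np.column_stack([_numeric(p, "x", cols[p]["x"]) for p in parts])
    y = np.column_stack([_numeric(p, "y", cols[p]["y"]) for p in parts])
    lik = np.column_stack([_numeric(p, "likelihood", cols[p]["likelihood"]) for p in parts])
    finite = np.isfinite(lik)
    if finite.any() and (lik[finite].min() < 0 or lik[finite].max() > 1):
        raise ValidationError(f"{path}: likelihoods outside [0, 1]")
    return PoseTrack(
        x=x, y=y, likelihood=lik, parts=list(parts), fps=fps,
        onset_frame=onset_frame, stimulated_side=stimulated_side,
        stimulation_frames=stimulation_frames,
    )


def write_pose_table(track: PoseTrack, path: str | Path, scorer: str = "pawkit") -> Path:
    """Write a track in the DeepLabCut wide layout (3-row header)."""
    path = Path(path)
    data = {}
    for j, part in enumerate(track.parts):
        data[(scorer, part, "x")] = track.x[:, j]
        data[(scorer, part, "y")] = track.y[:, j]
        data[(scorer, part, "likelihood")] = track.likelihood[:, j]
    df = pd.DataFrame(data)
    df.columns = pd.MultiIndex.from_tuples(df.columns,
                                           names=["scorer", "bodyparts", "coords"])
    df.to_csv(path)
    return path


# ---------------------------------------------------------------------------
# ROI trace tables
# ---------------------------------------------------------------------------

_LONG_COLS = {"mouse_id", "trial_id", "time_ms", "intensity"}


def read_trace_table(
    path: str | Path, fps: float | None = None
) -> list[ROITrace]:
    """Read per-trial ROI intensity time courses (long or wide CSV).

    Long layout: columns ``mouse_id, trial_id, time_ms, intensity`` with the
    stimulus at time 0. Wide layout: a ``time_ms`` column plus one column
    per trial named ``mouse/trial``. The frame rate is inferred from the
    time grid unless given.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if _LONG_COLS <= set(df.columns):
        groups = df.groupby(["mouse_id", "trial_id"], sort=True)
        lengths = groups.size().unique()
        if lengths.size > 1:
            raise FormatError(
                f"{path}: traces have unequal lengths {sorted(lengths.tolist())}"
            )
        traces = []
        for (mouse, trial), g in groups:
            g = g.sort_values("time_ms")
            traces.append(_make_trace(g["time_ms"].to_numpy(float),
                                      g["intensity"].to_numpy(float),
                                      fps, str(mouse), str(trial), path))
        return traces
    if "time_ms" in df.columns:
        t = df["time_ms"].to_numpy(float)
        traces = []
        for c in [c for c in df.columns if c != "time_ms"]:
            if "/" not in c:
                raise FormatError(
                    f"{path}: wide column {c!r} lacks a mouse id "
                    "(expected 'mouse/trial')"
                )
            mouse, trial = c.split("/", 1)
            traces.append(_make_trace(t, df[c].to_numpy(float), fps, mouse, trial, path))
        return traces
    raise FormatError(
        f"{path}: expected long columns {sorted(_LONG_COLS)} or a wide table "
        "with a 'time_ms' column"
    )


def _make_trace(
    t: np.ndarray, v: np.ndarray, fps: float | None, mouse: str, trial: str,
    path: Path,
) -> ROITrace:
    dt = np.diff(t)
    if dt.size == 0 or (dt <= 0).any():
        raise FormatError(f"{path}: time column is not strictly increasing")
    step = float(np.median(dt))
    if fps is None:
        fps = 1000.0 / step
    onset = int(np.argmin(np.abs(t)))
    if abs(t[onset]) > step / 2:
        raise FormatError(f"{path}: no sample at the stimulus time (0 ms)")
    return ROITrace(intensity=v, fps=fps, onset_frame=onset,
                    mouse_id=mouse, trial_id=trial)


def write_trace_table(traces: list[ROITrace], path: str | Path) -> Path:
    """Write traces in the long CSV layout (stimulus at 0 ms)."""
    path = Path(path)
    rows = []
    for tr in traces:
        t = (np.arange(tr.n_frames) - tr.onset_frame) * 1000.0 / tr.fps
        rows.append(pd.DataFrame({
            "mouse_id": tr.mouse_id, "trial_id": tr.trial_id,
            "time_ms": t, "intensity": tr.intensity,
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Trial tables and event JSON
# ---------------------------------------------------------------------------

def events_to_table(events: list, protocol: dict | None = None) -> pd.DataFrame:
    """One row per trial from a list of WithdrawalEvent objects."""
    rows = []
    for e in events:
        row = {
            "mouse_id": e.mouse_id,
            "trial_id": e.trial_id,
            "responded": e.responded,
            "latency_ms": e.latency_ms,
            "rise_time_ms": e.rise_time_ms,
            "extent_pct": e.extent_pct,
            "extent_class": e.extent_class,
            "rule": e.rule,
            "qc_pass": e.qc_pass,
            "qc_reasons": ";".join(e.qc_reasons),
        }
        if protocol:
            row.update(protocol)
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.duplicated(["mouse_id", "trial_id"]).any():
        raise ValidationError("(mouse_id, trial_id) pairs must be unique")
    return df


def write_events(
    events: list, out_dir: str | Path, run_info: dict | None = None
) -> Path:
    """Write an events CSV plus per-trial JSON details under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = events_to_table(events)
    table.to_csv(out / "events.csv", index=False)
    details = {
        f"{e.mouse_id}/{e.trial_id}": {
            "responded": bool(e.responded),
            "latency_ms": e.latency_ms,
            "rise_time_ms": e.rise_time_ms,
            "extent_pct": e.extent_pct,
            "extent_class": e.extent_class,
            "rule": e.rule,
            "qc_pass": bool(e.qc_pass),
            "qc_reasons": list(e.qc_reasons),
        }
        for e in events
    }
    payload: dict = {"trials": details}
    if run_info:
        payload["run"] = run_info
    (out / "events.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    return out
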