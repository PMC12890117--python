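"""Readers and writers binding the pipeline to files on disk.

Video input is a directory of numbered PNG/TIFF frames (``frame_0000.png``
...) with an optional ``video.json`` sidecar carrying fps and geometry, or
any single-file format imageio can decode (MP4/AVI require an ffmpeg
plugin; without one a clear I/O error is raised).  Tables travel as CSV, or
as XLSX through a declarative sheet/column mapping so supplementary-style
spreadsheet layouts need no custom parser.  Channel geometry and run
options come from a YAML/JSON config.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import AssayIOError, ConfigurationError
from .flow import ChannelGeometry, FlowProfile, FrameStack, VelocityEstimate

__all__ = [
    "read_frame_stack",
    "read_image",
    "load_config",
    "geometry_from_config",
    "read_table",
    "profile_to_frame",
    "velocity_summary",
]

_FRAME_PATTERNS = ("*.png", "*.tif", "*.tiff")


def read_image(path: "str | Path") -> np.ndarray:
    import imageio.v3 as iio

    path = Path(path)
    if not path.exists():
        raise AssayIOError(f"image not found: {path}")
    try:
        return np.asarray(iio.imread(path))
    except Exception as exc:  # noqa: BLE001 - surface the file name
        raise AssayIOError(f"cannot read image {path}: {exc}") from exc


def read_frame_stack(path: "str | Path", fps: float | None = None) -> FrameStack:
    """Load a video as a FrameStack.

    A directory is read as a sorted numbered frame sequence; ``video.json``
    in it, if present, supplies fps and metadata.  A file is decoded with
    imageio (requires a suitable plugin for MP4/AVI).
    """
    import imageio.v3 as iio

    path = Path(path)
    if path.is_dir():
        files: list[Path] = []
        for pattern in _FRAME_PATTERNS:
            files.extend(path.glob(pattern))
        if not files:
            raise AssayIOError(f"no PNG/TIFF frames found in {path}")
        files = sorted(files)
        frames = np.stack([np.asarray(iio.imread(f)) for f in files])
        metadata: dict = {}
        sidecar = path / "video.json"
        if sidecar.exists():
            metadata = json.loads(sidecar.read_text())
            fps = fps if fps is not None else metadata.get("fps")
        return FrameStack(frames=frames, fps=float(fps or 30.0), metadata=metadata)
    if not path.exists():
        raise AssayIOError(f"video not found: {path}")
    try:
        frames = np.asarray(iio.imread(path))
    except Exception as exc:  # noqa: BLE001
        raise AssayIOError(
            f"cannot decode {path}: {exc} (MP4/AVI need an imageio ffmpeg "
            "plugin; a PNG frame-sequence directory always works)"
        ) from exc
    if frames.ndim == 2:
        frames = frames[None]
    return FrameStack(frames=frames, fps=float(fps or 30.0))


def load_config(path: "str | Path") -> dict:
    path = Path(path)
    if not path.exists():
        raise AssayIOError(f"config not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def geometry_from_config(config: dict) -> ChannelGeometry:
    """Build a ChannelGeometry from a config mapping (keys: roi, entry_line,
    channel_length_px, optional line_offsets)."""
    try:
        kwargs = dict(
            roi=tuple(config["roi"]),
            entry_line=int(config["entry_line"]),
            channel_length_px=int(config["channel_length_px"]),
        )
    except KeyError as exc:
        raise ConfigurationError(f"geometry config missing key: {exc}") from exc
    if "line_offsets" in config:
        kwargs["line_offsets"] = tuple(float(o) for o in config["line_offsets"])
    return ChannelGeometry(**kwargs)


def read_table(
    path: "str | Path",
    sheet: "str | int | None" = None,
    columns: dict | None = None,
) -> pd.DataFrame:
    """Read a CSV or XLSX table, optionally renaming columns declaratively.

    ``columns`` maps source column names (as they appear in the file) to the
    canonical names the pipeline uses, e.g. ``{"AT (ng/mL)": "conc_ng_ml"}``;
    only the mapped columns are kept when a mapping is given.
    """
    path = Path(path)
    if not path.exists():
        raise AssayIOError(f"table not found: {path}")
    try:
        if path.suffix.lower() in (".xlsx", ".xls"):
            df = pd.read_excel(path, sheet_name=sheet if sheet is not None else 0)
        else:
            df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise AssayIOError(f"cannot read table {path}: {exc}") from exc
    if columns:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise ConfigurationError(
                f"{path} lacks mapped columns {missing}; has {list(df.columns)}"
            )
        df = df[list(columns)].rename(columns=columns)
    return df


def profile_to_frame(profile: FlowProfile) -> pd.DataFrame:
    """Tidy per-line, per-frame view of a profile (line, frame, distance_px,
    removed_flag)."""
    rows = []
    removed = set(profile.provenance)
    for line in range(profile.n_lines):
        for f in range(profile.n_frames):
            d = profile.distances[line, f]
            original_f = f + (profile.f0 if profile.shifted else 0)
            rows.append(
                (line, f, d if np.isfinite(d) else np.nan, original_f in removed)
            )
    return pd.DataFrame(rows, columns=["line", "frame", "distance_px", "removed_flag"])


def velocity_summary(
    estimate: VelocityEstimate, profile: FlowProfile, channel: str = "0"
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "channel": channel,
                "velocity_px_per_frame": estimate.velocity,
                "se": estimate.se,
                "f0": profile.f0,
                "window_frames": estimate.window[1] - estimate.window[0],
                "window_seconds": estimate.window_seconds,
                "n_removed_frames": len(profile.provenance),
            }
        ]
    )
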