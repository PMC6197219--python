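"""File I/O for two-channel movies, traces, and event tables.

Movies are stored as a pair of multi-page TIFF stacks (activity + structural
channel) plus a YAML sidecar carrying the frame rate and channel names.
Tabular data (optic flow, velocity, ratio traces, events) round-trips through
CSV with named columns.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "TwoChannelMovie",
    "save_movie",
    "load_movie",
    "load_interleaved_movie",
    "save_optic_flow_csv",
    "load_optic_flow_csv",
]


@dataclass
class TwoChannelMovie:
    """Time-ordered pair of co-registered image stacks.

    ``activity`` holds the calcium-indicator (GCaMP6s-like) channel and
    ``structural`` the activity-independent (tdTomato-like) channel. Both are
    ``(n_frames, height, width)`` arrays acquired simultaneously, so they share
    frame timestamps and any tissue deformation.
    """

    activity: np.ndarray
    structural: np.ndarray
    frame_rate: float
    channel_names: tuple[str, str] = ("activity", "structural")

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        self.structural = np.asarray(self.structural, dtype=float)
        if self.activity.shape != self.structural.shape:
            raise ValueError(
                f"channel shape mismatch: {self.activity.shape} vs "
                f"{self.structural.shape}"
            )
        if self.activity.ndim != 3:
            raise ValueError("channels must be (n_frames, height, width)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.activity.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.activity.shape[1:]

    @property
    def timestamps(self) -> np.ndarray:
        """Frame acquisition times in seconds (frame 0 at t = 0)."""
        return np.arange(self.n_frames) / self.frame_rate


def save_movie(movie: TwoChannelMovie, directory: str | Path) -> Path:
    """Write a movie as two float32 TIFF stacks plus a metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        directory / "activity.tif",
        movie.activity.astype(np.float32),
        photometric="minisblack",
    )
    tifffile.imwrite(
        directory / "structural.tif",
        movie.structural.astype(np.float32),
        photometric="minisblack",
    )
    meta = {
        "frame_rate": float(movie.frame_rate),
        "channel_names": list(movie.channel_names),
        "n_frames": int(movie.n_frames),
    }
    with open(directory / "movie.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)
    return directory


def load_movie(directory: str | Path) -> TwoChannelMovie:
    """Load a movie written by :func:`save_movie`.

    Raises ``ValueError`` naming the missing metadata field, and refuses
    channel stacks of unequal length rather than returning partial data.
    """
    directory = Path(directory)
    meta_path = directory / "movie.yaml"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar: {meta_path}")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    for key in ("frame_rate", "channel_names", "n_frames"):
        if key not in meta:
            raise ValueError(f"metadata missing required field: {key!r}")
    activity = tifffile.imread(directory / "activity.tif")
    structural = tifffile.imread(directory / "structural.tif")
    activity = np.atleast_3d(activity)
    structural = np.atleast_3d(structural)
    if activity.shape[0] != structural.shape[0]:
        raise ValueError(
            f"channel length mismatch: {activity.shape[0]} vs {structural.shape[0]}"
        )
    if activity.shape[0] != meta["n_frames"]:
        raise ValueError(
            f"stack has {activity.shape[0]} frames but metadata declares "
            f"{meta['n_frames']} (file truncated?)"
        )
    return TwoChannelMovie(
        activity=activity,
        structural=structural,
        frame_rate=float(meta["frame_rate"]),
        channel_names=tuple(meta["channel_names"]),
    )


def load_interleaved_movie(
    path: str | Path,
    frame_rate: float,
    channel_order: tuple[str, str] = ("activity", "structural"),
) -> TwoChannelMovie:
    """De-interleave a single 2N-page stack into an N-frame two-channel movie.

    Page ``2i`` belongs to ``channel_order[0]`` and page ``2i + 1`` to
    ``channel_order[1]``.
    """
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] % 2 != 0:
        raise ValueError("interleaved stack must have an even number of pages")
    channels = {channel_order[0]: stack[0::2], channel_order[1]: stack[1::2]}
    return TwoChannelMovie(
        activity=channels["activity"],
        structural=channels["structural"],
        frame_rate=frame_rate,
    )


def save_optic_flow_csv(path: str | Path, t, ap, ml, yaw) -> None:
    pd.DataFrame({"t": t, "ap": ap, "ml": ml, "yaw": yaw}).to_csv(path, index=False)


def load_optic_flow_csv(path: str | Path):
    df = pd.read_csv(path)
    for col in ("t", "ap", "ml", "yaw"):
        if col not in df.columns:
            raise ValueError(f"optic-flow CSV missing column {col!r}")
    return df
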