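"""Trajectory container and plain-text track I/O.

A :class:`Track` is one locus trajectory: ordered ``(frame, t, x, y)``
samples at a fixed frame interval ``dt``. Coordinates are in micrometres,
times in seconds, frames are 0-based. Frames may have gaps (blinking);
within a track they are strictly increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Track", "tracks_to_dataframe", "dataframe_to_tracks", "write_tracks_csv", "read_tracks_csv"]

TRACK_CSV_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um", "label"]


@dataclass
class Track:
    """One 2D locus trajectory sampled at fixed frame interval.

    Parameters
    ----------
    track_id : int
        Identifier, unique within one collection of tracks.
    frames : ndarray of int
        Strictly increasing 0-based frame indices.
    x, y : ndarray of float
        Observed coordinates in µm (localization noise included when the
        track is synthetic and noise was requested).
    dt : float
        Frame interval in seconds.
    label : str or None
        Ground-truth motion-component label for synthetic tracks.
    x_true, y_true : ndarray or None
        Noise-free coordinates for synthetic tracks, kept separate so
        detection and MSD stages can be scored against truth.
    """

    track_id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    dt: float
    label: str | None = None
    x_true: np.ndarray | None = field(default=None, repr=False)
    y_true: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.frames) == len(self.x) == len(self.y)):
            raise ValueError("frames, x and y must have equal length")
        if len(self.frames) >= 2 and np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def t(self) -> np.ndarray:
        """Sample times in seconds (``frame * dt``)."""
        return self.frames * self.dt

    @property
    def duration(self) -> float:
        """Track span in seconds: last time minus first time."""
        if len(self.frames) == 0:
            return 0.0
        return float((self.frames[-1] - self.frames[0]) * self.dt)

    @property
    def is_gapless(self) -> bool:
        return len(self.frames) < 2 or bool(
            np.all(np.diff(self.frames) == 1)
        )


def tracks_to_dataframe(tracks: list[Track]) -> pd.DataFrame:
    """Flatten tracks into the long-format schema used by all CSV outputs."""
    parts = []
    for tr in tracks:
        parts.append(
            pd.DataFrame(
                {
                    "track_id": tr.track_id,
                    "frame": tr.frames,
                    "t_s": tr.t,
                    "x_um": tr.x,
                    "y_um": tr.y,
                    "label": tr.label if tr.label is not None else "",
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=TRACK_CSV_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def dataframe_to_tracks(df: pd.DataFrame, dt: float) -> list[Track]:
    """Rebuild :class:`Track` objects from the long-format table."""
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        label = None
        if "label" in grp.columns:
            lab = grp["label"].iloc[0]
            if isinstance(lab, str) and lab:
                label = lab
        tracks.append(
            Track(
                track_id=int(tid),
                frames=grp["frame"].to_numpy(),
                x=grp["x_um"].to_numpy(),
                y=grp["y_um"].to_numpy(),
                dt=dt,
                label=label,
            )
        )
    return tracks


def write_tracks_csv(tracks: list[Track], path) -> None:
    tracks_to_dataframe(tracks).to_csv(path, index=False)


def read_tracks_csv(path, dt: float) -> list[Track]:
    df = pd.read_csv(path, keep_default_na=False)
    return dataframe_to_tracks(df, dt=dt)
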