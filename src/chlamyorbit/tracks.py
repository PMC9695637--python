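"""Shared trajectory container and the track CSV dialect.

A :class:`Track` holds the time-ordered centroid positions of one cell.
Positions are in micrometres in an image-style coordinate frame (x to the
right, y down); times are in seconds. Every module in the package reads and
writes the same CSV dialect (``track_id,frame,t_s,x_um,y_um``, comma-
separated, UTF-8, '.' decimal, header row mandatory), so tracks round-trip
between the simulator, the tracker and the analysis stages without loss.

Sign convention: the fitted angular velocity is positive when the polar
angle ``atan2(y - cy, x - cx)`` about the orbit centre increases with time
(counter-clockwise in the standard x-right / y-up sense). The convention is
recorded in the CSV header comment.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TRACK_COLUMNS = ("track_id", "frame", "t_s", "x_um", "y_um")

_CSV_HEADER_COMMENT = (
    "# track CSV dialect: track_id,frame,t_s,x_um,y_um; positions in "
    "micrometres, x right / y down; positive omega = increasing "
    "atan2(y-cy, x-cx)\n"
)


@dataclasses.dataclass
class Track:
    """Time-ordered centroid samples of a single cell.

    Parameters
    ----------
    track_id
        Integer identity of the cell within one recording.
    frame
        Frame indices, strictly increasing, at most one sample per frame.
    t
        Sample times in seconds.
    x, y
        Centroid coordinates in micrometres.
    """

    track_id: int
    frame: np.ndarray
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=np.int64)
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.frame.size
        if not (self.t.size == self.x.size == self.y.size == n):
            raise ValueError(f"track {self.track_id}: field lengths differ")
        if n == 0:
            raise ValueError(f"track {self.track_id}: empty track")
        if np.any(np.diff(self.frame) <= 0):
            raise ValueError(
                f"track {self.track_id}: frames must be strictly increasing"
            )
        if np.any(np.diff(self.t) <= 0):
            raise ValueError(f"track {self.track_id}: times must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return int(self.frame.size)

    @property
    def duration(self) -> float:
        """Time span of the track in seconds."""
        return float(self.t[-1] - self.t[0])

    @property
    def positions(self) -> np.ndarray:
        """(n, 2) array of (x, y) positions in micrometres."""
        return np.column_stack([self.x, self.y])

    def clip(self, t_start: float, t_stop: float) -> "Track":
        """Return the sub-track with ``t_start <= t <= t_stop``."""
        keep = (self.t >= t_start) & (self.t <= t_stop)
        if not keep.any():
            raise ValueError(
                f"track {self.track_id}: no samples in [{t_start}, {t_stop}] s"
            )
        return Track(self.track_id, self.frame[keep], self.t[keep],
                     self.x[keep], self.y[keep])

    def transformed(self, rotation: float = 0.0,
                    translation: Sequence[float] = (0.0, 0.0)) -> "Track":
        """Rigidly rotate (radians, about the origin) then translate (μm)."""
        c, s = np.cos(rotation), np.sin(rotation)
        x = c * self.x - s * self.y + translation[0]
        y = s * self.x + c * self.y + translation[1]
        return Track(self.track_id, self.frame, self.t, x, y)


def tracks_to_frame(tracks: Iterable[Track]) -> pd.DataFrame:
    """Concatenate tracks into a long-format DataFrame (shared dialect)."""
    parts = [
        pd.DataFrame({
            "track_id": tr.track_id,
            "frame": tr.frame,
            "t_s": tr.t,
            "x_um": tr.x,
            "y_um": tr.y,
        })
        for tr in tracks
    ]
    if not parts:
        return pd.DataFrame(columns=list(TRACK_COLUMNS))
    return pd.concat(parts, ignore_index=True)


def frame_to_tracks(df: pd.DataFrame) -> list[Track]:
    """Split a long-format DataFrame into Track objects (sorted by id)."""
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track table missing columns: {sorted(missing)}")
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        tracks.append(Track(int(tid), grp["frame"].to_numpy(),
                            grp["t_s"].to_numpy(), grp["x_um"].to_numpy(),
                            grp["y_um"].to_numpy()))
    return tracks


def write_tracks(tracks: Iterable[Track], path: str | Path) -> None:
    """Write tracks to CSV, 6 decimal places (the dialect's guaranteed precision)."""
    df = tracks_to_frame(tracks)
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_CSV_HEADER_COMMENT)
        df.to_csv(fh, index=False, float_format="%.6f")


def read_tracks(path: str | Path) -> list[Track]:
    """Read a track CSV written by any stage of the pipeline."""
    df = pd.read_csv(path, comment="#")
    return frame_to_tracks(df)
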