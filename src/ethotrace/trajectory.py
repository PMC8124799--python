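"""Per-identity centroid time series at fixed fps."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TrajectorySet"]


@dataclass
class TrajectorySet:
    """Centroid trajectories for a fixed group of identities.

    Attributes
    ----------
    xy : ndarray, shape (n_frames, n_individuals, 2)
        Pixel coordinates per frame and identity; NaN marks a gap
        (undetected).
    fps : float
        Video frame rate.
    scale : float
        Centimeters per pixel; 1.0 keeps everything in pixels.
    contours : list, optional
        Per-frame contour lists retained by the tracker (used by the
        behavior module for body statistics and crops).
    """

    xy: np.ndarray
    fps: float
    scale: float = 1.0
    contours: list | None = None

    def __post_init__(self):
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 3 or self.xy.shape[2] != 2:
            raise ValueError("xy must have shape (frames, individuals, 2)")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.xy.shape[1]

    @property
    def duration(self) -> float:
        """Video duration in seconds."""
        return self.n_frames / self.fps

    def individual(self, j: int) -> np.ndarray:
        """(n_frames, 2) coordinates of individual ``j`` (0-based)."""
        return self.xy[:, j, :]

    def detected_fraction(self) -> float:
        """Fraction of (frame, identity) slots with a detection."""
        return float(1.0 - np.isnan(self.xy[..., 0]).mean())

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy frame: columns ``frame, id, x, y`` (raw pixels, NaN for gaps)."""
        f, n, _ = self.xy.shape
        frames = np.repeat(np.arange(f), n)
        ids = np.tile(np.arange(1, n + 1), f)
        flat = self.xy.reshape(f * n, 2)
        return pd.DataFrame({"frame": frames, "id": ids,
                             "x": flat[:, 0], "y": flat[:, 1]})

    def to_csv(self, path: str | Path) -> None:
        """Write coordinates as CSV; gaps become empty cells, not zeros."""
        self.to_dataframe().to_csv(path, index=False, na_rep="")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, fps: float, scale: float = 1.0) -> "TrajectorySet":
        frames = np.sort(df["frame"].unique())
        ids = np.sort(df["id"].unique())
        xy = np.full((len(frames), len(ids), 2), np.nan)
        fidx = {f: i for i, f in enumerate(frames)}
        iidx = {v: i for i, v in enumerate(ids)}
        for row in df.itertuples(index=False):
            xy[fidx[row.frame], iidx[row.id]] = (row.x, row.y)
        return cls(xy=xy, fps=fps, scale=scale)

    @classmethod
    def from_csv(cls, path: str | Path, fps: float, scale: float = 1.0) -> "TrajectorySet":
        return cls.from_dataframe(pd.read_csv(path), fps=fps, scale=scale)
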