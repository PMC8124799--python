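"""Buffered video reading and frame preprocessing.

Decoding runs in a producer thread feeding a bounded queue, so the analysis
thread never waits on I/O while buffered frames exist.  Preprocessing masks
the region of interest, converts sRGB to CIE-XYZ (D65) keeping the luminance
channel, min–max normalizes to [0, 255] and median-smooths the result.
"""

from __future__ import annotations

import logging
import queue
import threading
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.color import rgb2xyz

from .avi import AviReader, VideoOpenError

__all__ = ["Frame", "Roi", "FrameBuffer", "open_stream", "preprocess", "VideoOpenError"]

log = logging.getLogger(__name__)

_SENTINEL = object()


@dataclass(frozen=True)
class Frame:
    """One video frame: 8-bit pixel grid plus its 0-based index."""

    pixels: np.ndarray
    index: int

    def __post_init__(self):
        if self.index < 0:
            raise ValueError("frame index must be >= 0")
        if self.pixels.ndim not in (2, 3):
            raise ValueError("pixels must be 2-D (gray) or 3-D (color)")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def is_color(self) -> bool:
        return self.pixels.ndim == 3


class Roi:
    """Region of interest: a circle or polygon in pixel coordinates.

    Origin is the top-left corner, x rightward, y downward.  The same object
    doubles as the analysis region for residence-time statistics.
    """

    def __init__(self, kind: str, *, center: tuple[float, float] | None = None,
                 radius: float | None = None,
                 vertices: Sequence[tuple[float, float]] | None = None):
        kind = kind.lower()
        if kind == "circle":
            if center is None or radius is None or radius <= 0:
                raise ValueError("circle roi needs center and positive radius")
            self.center = (float(center[0]), float(center[1]))
            self.radius = float(radius)
        elif kind == "polygon":
            if vertices is None or len(vertices) < 3:
                raise ValueError("polygon roi needs >= 3 vertices")
            self.vertices = [(float(x), float(y)) for x, y in vertices]
            self._poly = None  # built lazily; shapely import cost
        else:
            raise ValueError(f"unknown roi type: {kind!r}")
        self.kind = kind

    @classmethod
    def from_dict(cls, d: dict) -> "Roi":
        d = dict(d)
        kind = d.pop("type")
        if kind == "circle":
            c = d["center"]
            center = (c["x"], c["y"]) if isinstance(c, dict) else tuple(c)
            return cls("circle", center=center, radius=d["radius"])
        return cls("polygon", vertices=[tuple(v) for v in d["vertices"]])

    def contains(self, x, y) -> np.ndarray:
        """Vectorized membership test for points (x, y)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.kind == "circle":
            cx, cy = self.center
            return (x - cx) ** 2 + (y - cy) ** 2 <= self.radius**2
        import shapely

        if self._poly is None:
            self._poly = shapely.Polygon(self.vertices)
        covered = shapely.intersects_xy(self._poly, x.ravel(), y.ravel())
        return covered.reshape(x.shape)

    def mask(self, height: int, width: int) -> np.ndarray:
        """Boolean mask of shape (height, width), True inside the region."""
        yy, xx = np.mgrid[0:height, 0:width]
        return self.contains(xx, yy).reshape(height, width)


class FrameBuffer:
    """Producer/consumer frame stack over a video source.

    A reader thread decodes frames into a bounded queue; iteration yields
    every frame exactly once, in order.  ``fps`` and ``n_frames`` are exposed
    from the container metadata.
    """

    def __init__(self, reader: AviReader, capacity: int = 64):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self._reader = reader
        self.fps: float = reader.fps
        self.n_frames: int = reader.n_frames
        self.width: int = reader.width
        self.height: int = reader.height
        self._queue: queue.Queue = queue.Queue(maxsize=capacity)
        self._error: Optional[BaseException] = None
        self._thread = threading.Thread(target=self._produce, daemon=True)
        self._thread.start()

    def _produce(self) -> None:
        try:
            for i in range(self._reader.n_frames):
                self._queue.put(Frame(self._reader.read_frame(i), i))
        except BaseException as exc:  # surfaced on the consumer side
            self._error = exc
        finally:
            self._queue.put(_SENTINEL)

    def __iter__(self) -> Iterator[Frame]:
        while True:
            item = self._queue.get()
            if item is _SENTINEL:
                if self._error is not None:
                    raise VideoOpenError(str(self._error)) from self._error
                self._thread.join()
                self._reader.close()
                return
            yield item

    def close(self) -> None:
        # drain so the producer can finish
        while True:
            item = self._queue.get()
            if item is _SENTINEL:
                break
        self._thread.join()
        self._reader.close()


def _open_reader(path: str | Path) -> AviReader:
    path = Path(path)
    if not path.exists():
        raise VideoOpenError(f"no such file: {path}")
    try:
        return AviReader(path)
    except VideoOpenError as avi_err:
        # fall back to imageio for other containers if a backend is present
        try:
            import imageio.v3 as iio

            frames = iio.imread(path, index=None)
            meta = iio.immeta(path)
        except Exception:
            raise avi_err from None
        return _ArrayReader(np.asarray(frames), float(meta.get("fps", 30.0)))


class _ArrayReader:
    """Adapter giving in-memory frame stacks the AviReader interface."""

    def __init__(self, frames: np.ndarray, fps: float = 30.0):
        if frames.ndim == 3:
            frames = frames[..., None].repeat(3, axis=3)
        self._frames = frames
        self.n_frames = len(frames)
        self.height, self.width = frames.shape[1:3]
        self.fps = fps
        if self.n_frames == 0:
            raise VideoOpenError("zero-frame video")

    def read_frame(self, i: int) -> np.ndarray:
        return self._frames[i]

    def close(self) -> None:
        pass


def open_stream(path: str | Path, capacity: int = 64) -> FrameBuffer:
    """Open a video for buffered, in-order frame delivery.

    Parameters
    ----------
    path : str or Path
        Video file (uncompressed AVI natively; other containers via an
        installed imageio backend).
    capacity : int
        Maximum number of decoded frames held ahead of the consumer.
    """
    return FrameBuffer(_open_reader(path), capacity=capacity)


def preprocess(frame: Frame, roi: Roi | None = None, median_kernel: int = 3) -> Frame:
    """Mask, desaturate to XYZ luminance, normalize, and median-smooth.

    Steps, in order: pixels outside ``roi`` are set to 0; color input is
    converted sRGB→CIE-XYZ (D65) and the Y (luminance) channel kept;
    intensities are min–max rescaled to [0, 255]; a ``median_kernel`` square
    median filter is applied last.  A constant frame normalizes to 0.
    """
    if median_kernel < 1 or median_kernel % 2 == 0:
        raise ValueError("median_kernel must be odd and >= 1")
    px = frame.pixels
    if px.ndim == 3:
        y = rgb2xyz(px)[..., 1]  # luminance in [0, 1]
    else:
        warnings.warn("grayscale input: XYZ conversion skipped", stacklevel=2)
        y = px.astype(float)
    if roi is not None:
        y = np.where(roi.mask(*y.shape), y, 0.0)
    lo, hi = float(y.min()), float(y.max())
    if hi > lo:
        y = (y - lo) / (hi - lo) * 255.0
    else:
        log.warning("constant frame %d: normalized to 0", frame.index)
        y = np.zeros_like(y)
    out = np.clip(np.rint(y), 0, 255).astype(np.uint8)
    if median_kernel > 1:
        out = ndimage.median_filter(out, size=median_kernel, mode="nearest")
    return Frame(out, frame.index)
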