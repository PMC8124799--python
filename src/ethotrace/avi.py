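"""Minimal uncompressed AVI (RIFF, BI_RGB 24-bit) reader and writer.

Lossless video storage so that segmentation of synthetic footage is exact:
every frame is stored as a raw bottom-up BGR bitmap (``00db`` chunks), the
format every mainstream player and OpenCV can open.  Only this one codec is
handled; anything else should go through an external backend.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np

__all__ = ["AviWriter", "AviReader", "write_video", "VideoOpenError"]


class VideoOpenError(RuntimeError):
    """Raised when a video file cannot be opened or decoded."""


def _pad4(n: int) -> int:
    return (n + 3) & ~3


@dataclass
class _StreamInfo:
    width: int
    height: int
    fps: float
    n_frames: int
    bit_count: int


class AviWriter:
    """Write 8-bit RGB frames to an uncompressed AVI file.

    Parameters
    ----------
    path : str or Path
        Output file; created/truncated on open.
    fps : float
        Playback rate recorded in the stream header.

    All frames must share one shape ``(height, width, 3)``, dtype uint8.
    """

    def __init__(self, path: str | Path, fps: float = 30.0):
        if fps <= 0:
            raise ValueError("fps must be positive")
        self._path = Path(path)
        self._fps = float(fps)
        self._fh = open(self._path, "wb")
        self._frames_written = 0
        self._shape: tuple[int, int] | None = None
        self._index: list[tuple[int, int]] = []  # (offset in movi, size)
        self._movi_start = 0
        self._header_budget = 2048  # fixed-size header region, padded with JUNK
        self._fh.seek(self._header_budget)
        self._closed = False

    # -- context manager -------------------------------------------------
    def __enter__(self) -> "AviWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def append(self, frame: np.ndarray) -> None:
        """Append one RGB frame (H, W, 3) uint8."""
        frame = np.asarray(frame)
        if frame.ndim == 2:
            frame = np.repeat(frame[:, :, None], 3, axis=2)
        if frame.ndim != 3 or frame.shape[2] != 3:
            raise ValueError("expected (H, W, 3) RGB frame")
        if frame.dtype != np.uint8:
            raise ValueError("expected uint8 frame")
        h, w = frame.shape[:2]
        if self._shape is None:
            self._shape = (h, w)
            self._movi_pos = self._fh.tell()
        elif self._shape != (h, w):
            raise ValueError("all frames must share one shape")
        # bottom-up BGR rows padded to 4 bytes
        bgr = frame[::-1, :, ::-1]
        row_bytes = w * 3
        stride = _pad4(row_bytes)
        if stride != row_bytes:
            padded = np.zeros((h, stride), dtype=np.uint8)
            padded[:, :row_bytes] = bgr.reshape(h, row_bytes)
            payload = padded.tobytes()
        else:
            payload = bgr.tobytes()
        self._index.append((self._fh.tell(), len(payload)))
        self._fh.write(b"00db" + struct.pack("<I", len(payload)))
        self._fh.write(payload)
        if len(payload) & 1:
            self._fh.write(b"\0")
        self._frames_written += 1

    def close(self) -> None:
        if self._closed:
            return
        self._closed = True
        if self._shape is None:
            self._fh.close()
            self._path.unlink(missing_ok=True)
            raise ValueError("no frames written")
        h, w = self._shape
        n = self._frames_written
        data_end = self._fh.tell()

        # idx1: one entry per frame, offsets relative to start of 'movi' list data
        movi_list_pos = self._header_budget - 12  # LIST size(4) 'movi'
        idx = bytearray()
        for off, size in self._index:
            rel = off - (movi_list_pos + 8)
            idx += b"00db" + struct.pack("<III", 0x10, rel, size)
        self._fh.write(b"idx1" + struct.pack("<I", len(idx)) + bytes(idx))
        file_end = self._fh.tell()

        usec = int(round(1_000_000 / self._fps))
        frame_bytes = _pad4(w * 3) * h
        avih = struct.pack(
            "<14I",
            usec, frame_bytes * int(self._fps), 0, 0x10,  # AVIF_HASINDEX
            n, 0, 1, frame_bytes, w, h, 0, 0, 0, 0,
        )
        # rate/scale as a rational approximating fps
        scale, rate = 1000, int(round(self._fps * 1000))
        strh = (
            b"vids" + b"DIB " + struct.pack("<IHHIIIIIIIII", 0, 0, 0, 0,
                                            scale, rate, 0, n, frame_bytes, 0, 0, 0)
            + struct.pack("<4H", 0, 0, w, h)
        )
        strf = struct.pack("<IiiHHIIiiII", 40, w, h, 1, 24, 0, frame_bytes, 0, 0, 0, 0)

        def chunk(tag: bytes, payload: bytes) -> bytes:
            return tag + struct.pack("<I", len(payload)) + payload + (b"\0" if len(payload) & 1 else b"")

        def lst(tag: bytes, payload: bytes) -> bytes:
            return b"LIST" + struct.pack("<I", 4 + len(payload)) + tag + payload

        strl = lst(b"strl", chunk(b"strh", strh) + chunk(b"strf", strf))
        hdrl = lst(b"hdrl", chunk(b"avih", avih) + strl)

        header = b"RIFF" + struct.pack("<I", file_end - 8) + b"AVI " + hdrl
        junk_size = movi_list_pos - len(header) - 8
        if junk_size < 0:
            raise RuntimeError("header overflow")  # pragma: no cover
        header += chunk(b"JUNK", b"\0" * junk_size)
        header += b"LIST" + struct.pack("<I", 4 + (data_end - self._header_budget)) + b"movi"
        assert len(header) == self._header_budget
        self._fh.seek(0)
        self._fh.write(header)
        self._fh.close()

    @property
    def frames_written(self) -> int:
        return self._frames_written


class AviReader:
    """Sequential reader for uncompressed (BI_RGB 24-bit) AVI files."""

    def __init__(self, path: str | Path):
        self._path = Path(path)
        if not self._path.exists():
            raise VideoOpenError(f"no such file: {self._path}")
        try:
            self._fh = open(self._path, "rb")
            self._parse()
        except VideoOpenError:
            raise
        except Exception as exc:  # corrupt container
            raise VideoOpenError(f"cannot decode {self._path}: {exc}") from exc
        if self.n_frames == 0:
            raise VideoOpenError(f"zero-frame video: {self._path}")

    def _parse(self) -> None:
        fh = self._fh
        magic = fh.read(12)
        if len(magic) < 12 or magic[:4] != b"RIFF" or magic[8:12] != b"AVI ":
            raise VideoOpenError(f"not an AVI file: {self._path}")
        self._frame_offsets: list[tuple[int, int]] = []
        info: dict = {}
        riff_end = 8 + struct.unpack("<I", magic[4:8])[0]
        self._walk(12, riff_end, info)
        if "width" not in info:
            raise VideoOpenError("missing stream format")
        if info.get("bit_count") != 24 or info.get("compression", 0) != 0:
            raise VideoOpenError("only uncompressed 24-bit AVI is supported")
        self.width: int = info["width"]
        self.height: int = info["height"]
        self.fps: float = info.get("fps", 30.0)
        self.n_frames: int = len(self._frame_offsets)

    def _walk(self, pos: int, end: int, info: dict) -> None:
        fh = self._fh
        while pos + 8 <= end:
            fh.seek(pos)
            head = fh.read(8)
            if len(head) < 8:
                break
            tag = head[:4]
            size = struct.unpack("<I", head[4:8])[0]
            if tag == b"LIST":
                fh.seek(pos + 8)
                self._walk(pos + 12, pos + 8 + size, info)
            elif tag == b"avih":
                data = fh.read(size)
                usec = struct.unpack("<I", data[:4])[0]
                if usec:
                    info.setdefault("fps", 1_000_000 / usec)
            elif tag == b"strh":
                data = fh.read(size)
                if data[:4] == b"vids":
                    scale, rate = struct.unpack("<II", data[20:28])
                    if scale:
                        info["fps"] = rate / scale
            elif tag == b"strf":
                data = fh.read(size)
                if len(data) >= 40 and "width" not in info:
                    (_, w, h, _, bits, comp) = struct.unpack("<IiiHHI", data[:20])
                    info["width"], info["height"] = w, abs(h)
                    info["bit_count"], info["compression"] = bits, comp
                    info["top_down"] = h < 0
            elif tag in (b"00db", b"00dc") and size > 0:
                self._frame_offsets.append((pos + 8, size))
            pos += 8 + size + (size & 1)

    def read_frame(self, index: int) -> np.ndarray:
        """Decode frame ``index`` as an (H, W, 3) RGB uint8 array."""
        off, size = self._frame_offsets[index]
        self._fh.seek(off)
        raw = self._fh.read(size)
        stride = _pad4(self.width * 3)
        arr = np.frombuffer(raw[: stride * self.height], dtype=np.uint8)
        arr = arr.reshape(self.height, stride)[:, : self.width * 3]
        arr = arr.reshape(self.height, self.width, 3)
        return arr[::-1, :, ::-1].copy()  # bottom-up BGR → top-down RGB

    def __iter__(self) -> Iterator[np.ndarray]:
        for i in range(self.n_frames):
            yield self.read_frame(i)

    def __len__(self) -> int:
        return self.n_frames

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "AviReader":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def write_video(path: str | Path, frames, fps: float = 30.0) -> int:
    """Write an iterable of RGB frames to ``path``; returns the frame count."""
    with AviWriter(path, fps=fps) as w:
        for f in frames:
            w.append(f)
        return w.frames_written
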