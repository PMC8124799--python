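"""Synthetic videos and frame sets with exact ground truth.

Animals are rendered as filled 2:1 ellipses (so body length is well defined)
without anti-aliasing, moving over a uniform or procedurally cluttered
background.  Every generated artifact is fully determined by its seed, and
per-frame ground truth (centroid, area, length, pair flag) is exported next
to the video, which makes round-trip tests of the whole tracking pipeline
possible without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .avi import AviWriter

__all__ = ["MergeEvent", "SceneSpec", "GroundTruth", "render_scene",
           "generate_video", "generate_pair_pose_set", "clutter_background"]


@dataclass(frozen=True)
class MergeEvent:
    """Scripted occlusion: blob ``b`` rides attached to blob ``a`` for a while."""

    a: int
    b: int
    start: int
    duration: int
    ramp: int = 10


@dataclass
class SceneSpec:
    """Parameters of a synthetic scene.

    ``body_length`` is the full major-axis length of one animal in pixels;
    the minor axis is half of it.  ``layout="lanes"`` places blobs in
    separate horizontal lanes moving horizontally (no crossings unless a
    merge event scripts one); ``layout="random"`` gives random headings with
    wall bounces.  ``size_jitter`` draws each blob's body length from
    N(body_length, (size_jitter·body_length)²) once per blob.
    """

    width: int = 320
    height: int = 240
    n_blobs: int = 3
    body_length: float = 24.0
    speed: float = 2.0
    heading_noise_deg: float = 0.0
    duration: int = 100
    fps: float = 30.0
    seed: int = 0
    background: str = "uniform"       # "uniform" | "clutter"
    background_level: int = 30
    blob_intensity: int = 220
    layout: str = "lanes"             # "lanes" | "random"
    size_jitter: float = 0.0
    merge_events: tuple[MergeEvent, ...] = ()

    def __post_init__(self):
        margin = self.body_length
        if self.width - 2 * margin <= 0 or self.height - 2 * margin <= 0:
            raise ValueError("blob larger than frame")
        if self.n_blobs < 1 or self.duration < 1:
            raise ValueError("need at least one blob and one frame")


@dataclass
class GroundTruth:
    """Per-frame, per-blob truth: centroid, area, length, pair-event flag."""

    table: pd.DataFrame  # columns: frame, id, x, y, area, length, pair_flag
    fps: float

    def positions(self) -> np.ndarray:
        """(n_frames, n_blobs, 2) programmed centers."""
        frames = self.table["frame"].max() + 1
        ids = self.table["id"].max()
        xy = np.full((frames, ids, 2), np.nan)
        for row in self.table.itertuples(index=False):
            xy[row.frame, row.id - 1] = (row.x, row.y)
        return xy

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, fps: float = 30.0) -> "GroundTruth":
        return cls(pd.read_csv(path), fps=fps)


def clutter_background(width: int, height: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded procedural texture: coarse noise upsampled to a patchy scene."""
    coarse = rng.integers(40, 200, size=(height // 16 + 1, width // 16 + 1))
    img = np.kron(coarse, np.ones((16, 16)))[:height, :width]
    fine = rng.integers(-15, 16, size=(height, width))
    return np.clip(img + fine, 0, 255).astype(np.uint8)


def _ellipse_mask(width: int, height: int, cx: float, cy: float,
                  a: float, b: float, theta: float) -> np.ndarray:
    """Boolean raster of an oriented filled ellipse (no anti-aliasing)."""
    x0 = max(0, int(np.floor(cx - a - 1)))
    x1 = min(width, int(np.ceil(cx + a + 2)))
    y0 = max(0, int(np.floor(cy - a - 1)))
    y1 = min(height, int(np.ceil(cy + a + 2)))
    out = np.zeros((height, width), dtype=bool)
    if x1 <= x0 or y1 <= y0:
        return out
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx = xx - cx
    dy = yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    out[y0:y1, x0:x1] = u * u + v * v <= 1.0
    return out


@dataclass
class _Blob:
    x: float
    y: float
    heading: float
    length: float  # full major axis

    @property
    def a(self) -> float:
        return self.length / 2.0

    @property
    def b(self) -> float:
        return self.length / 4.0


def _init_blobs(spec: SceneSpec, rng: np.random.Generator) -> list[_Blob]:
    margin = spec.body_length
    lengths = spec.body_length * (
        1.0 + spec.size_jitter * rng.standard_normal(spec.n_blobs)
        if spec.size_jitter > 0 else np.ones(spec.n_blobs)
    )
    blobs = []
    if spec.layout == "lanes":
        usable = spec.height - 2 * margin
        for i in range(spec.n_blobs):
            y = margin + usable * (i + 0.5) / spec.n_blobs
            x = margin + (spec.width - 2 * margin) * rng.uniform(0.2, 0.8)
            heading = 0.0 if rng.uniform() < 0.5 else np.pi
            blobs.append(_Blob(x, y, heading, float(lengths[i])))
    else:
        for i in range(spec.n_blobs):
            for _ in range(200):
                x = rng.uniform(margin, spec.width - margin)
                y = rng.uniform(margin, spec.height - margin)
                if all((x - b.x) ** 2 + (y - b.y) ** 2 > (2 * spec.body_length) ** 2
                       for b in blobs):
                    break
            blobs.append(_Blob(x, y, rng.uniform(0, 2 * np.pi), float(lengths[i])))
    return blobs


def _advance(blob: _Blob, spec: SceneSpec, rng: np.random.Generator) -> None:
    if spec.heading_noise_deg > 0:
        blob.heading += np.radians(rng.normal(0.0, spec.heading_noise_deg))
    nx = blob.x + spec.speed * np.cos(blob.heading)
    ny = blob.y + spec.speed * np.sin(blob.heading)
    margin = spec.body_length
    if nx < margin or nx > spec.width - margin:
        blob.heading = np.pi - blob.heading
        nx = blob.x + spec.speed * np.cos(blob.heading)
    if ny < margin or ny > spec.height - margin:
        blob.heading = -blob.heading
        ny = blob.y + spec.speed * np.sin(blob.heading)
    blob.x = float(np.clip(nx, margin, spec.width - margin))
    blob.y = float(np.clip(ny, margin, spec.height - margin))


def _merge_offset(ev: MergeEvent, t: int) -> float | None:
    """Blend weight in [0,1] of blob b's attachment to blob a at frame t."""
    t0, t1 = ev.start, ev.start + ev.duration
    if t < t0 - ev.ramp or t >= t1 + ev.ramp:
        return None
    if t < t0:
        return (t - (t0 - ev.ramp)) / ev.ramp
    if t < t1:
        return 1.0
    return 1.0 - (t - t1 + 1) / ev.ramp


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render all frames of a scene.

    Returns ``(frames, truth)`` where frames is a uint8 array of shape
    (duration, height, width) (grayscale; the writer expands to RGB).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.background == "clutter":
        bg = clutter_background(spec.width, spec.height, rng)
    else:
        bg = np.full((spec.height, spec.width), spec.background_level, dtype=np.uint8)
    blobs = _init_blobs(spec, rng)
    frames = np.empty((spec.duration, spec.height, spec.width), dtype=np.uint8)
    records = []
    from .track import _min_rect_length  # measurement-consistent length

    for t in range(spec.duration):
        centers: list[tuple[float, float, float]] = []  # cx, cy, theta
        for i, blob in enumerate(blobs):
            cx, cy, th = blob.x, blob.y, blob.heading
            centers.append((cx, cy, th))
        pair_flags = [0] * spec.n_blobs
        for ev in spec.merge_events:
            w = _merge_offset(ev, t)
            if w is not None:
                ax, ay, ath = centers[ev.a]
                bx, by, bth = centers[ev.b]
                # target: attached just behind a, guaranteeing one blob
                tx = ax + 0.45 * blobs[ev.a].length * np.cos(ath + np.pi)
                ty = ay + 0.45 * blobs[ev.a].length * np.sin(ath + np.pi)
                centers[ev.b] = (bx + w * (tx - bx), by + w * (ty - by), ath)
                if w >= 1.0:
                    pair_flags[ev.a] = pair_flags[ev.b] = 1
        frame = bg.copy()
        masks = []
        for i, blob in enumerate(blobs):
            cx, cy, th = centers[i]
            m = _ellipse_mask(spec.width, spec.height, cx, cy, blob.a, blob.b, th)
            masks.append(m)
            frame[m] = spec.blob_intensity
        frames[t] = frame
        for i, blob in enumerate(blobs):
            ys, xs = np.nonzero(masks[i])
            area = float(len(xs))
            length = _min_rect_length(np.column_stack([xs, ys])) if len(xs) else 0.0
            records.append({"frame": t, "id": i + 1,
                            "x": centers[i][0], "y": centers[i][1],
                            "area": area, "length": length,
                            "pair_flag": pair_flags[i]})
        for blob in blobs:
            _advance(blob, spec, rng)
    truth = GroundTruth(pd.DataFrame.from_records(records), fps=spec.fps)
    return frames, truth


def generate_video(spec: SceneSpec, path: str | Path,
                   truth_path: str | Path | None = None) -> GroundTruth:
    """Render a scene and write it as an uncompressed AVI plus truth CSV."""
    frames, truth = render_scene(spec)
    with AviWriter(path, fps=spec.fps) as w:
        for f in frames:
            w.append(np.repeat(f[:, :, None], 3, axis=2))
    if truth_path is not None:
        truth.to_csv(truth_path)
    return truth


def generate_pair_pose_set(
    spec: SceneSpec,
    n_pos: int,
    n_neg: int,
    n_singles: int = 3,
    pair_scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Frames with head-to-head merged pairs (label 1) or only singles (label 0).

    Positive frames contain one pair built from two ellipses joined along
    their major axes (combined area and length ≈ 2× a single body, i.e.
    inside the body-stats window the paired-posture heuristic tests) plus
    ``n_singles`` separated singles; negative frames contain singles only.
    ``pair_scale`` scales each pair member (e.g. 1.5 builds a 3×-area pair
    that should fall outside the window).

    Returns ``(frames, labels, info)``; info holds per-frame blob counts.
    """
    if n_pos < 0 or n_neg < 0 or n_pos + n_neg < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    frames = np.empty((n_pos + n_neg, H, W), dtype=np.uint8)
    labels = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
    margin = 2 * spec.body_length
    info = []

    def random_center(placed, min_dist):
        for _ in range(500):
            x = rng.uniform(margin, W - margin)
            y = rng.uniform(margin, H - margin)
            if all((x - px) ** 2 + (y - py) ** 2 > min_dist**2 for px, py in placed):
                return x, y
        raise RuntimeError("could not place blob without contact")

    for f in range(n_pos + n_neg):
        frame = np.full((H, W), spec.background_level, dtype=np.uint8)
        placed: list[tuple[float, float]] = []
        n_obj = 0
        if labels[f] == 1:
            # the pair is built at the nominal (median) body size so its
            # combined area/length sits centrally in the heuristic's window
            L = spec.body_length * pair_scale
            a, b = L / 2, L / 4
            theta = rng.uniform(0, 2 * np.pi)
            cx, cy = random_center(placed, 2.5 * margin)
            # two bodies joined head-to-head: centers 2a·0.98 apart so the
            # rasters touch into one blob with near-additive area
            off = 0.98 * a
            for s in (-1, 1):
                m = _ellipse_mask(W, H, cx + s * off * np.cos(theta),
                                  cy + s * off * np.sin(theta), a, b, theta)
                frame[m] = spec.blob_intensity
            placed.append((cx, cy))
            n_obj += 1
        for _ in range(n_singles):
            L = spec.body_length * (1 + spec.size_jitter * rng.standard_normal())
            theta = rng.uniform(0, 2 * np.pi)
            cx, cy = random_center(placed, 2.2 * margin)
            m = _ellipse_mask(W, H, cx, cy, L / 2, L / 4, theta)
            frame[m] = spec.blob_intensity
            placed.append((cx, cy))
            n_obj += 1
        frames[f] = frame
        info.append({"frame": f, "label": int(labels[f]), "n_objects": n_obj})
    return frames, labels, pd.DataFrame(info)
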