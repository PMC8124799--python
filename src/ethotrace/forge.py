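"""Automatic instance-segmentation training data and detector scoring.

Labeled training images for a deep detector are forged by copy-paste: frames
of a homogeneous-background video are sampled at random, the animals are
segmented, and each animal's pixels are pasted at a random in-bounds position
of a randomly drawn background image; the bounding box, class, and mask of
every pasted object are recorded concurrently.  Scoring uses box IoU,
greedy score-ranked matching, precision/recall accumulation, and 11-point
interpolated average precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .segment import Detection, ThresholdDetector, detect_instances
from .video import Frame, open_stream, preprocess

__all__ = [
    "ObjectAnnotation",
    "AnnotationRecord",
    "ForgeConfig",
    "PRCurve",
    "forge_dataset",
    "serialize_annotations",
    "load_annotations",
    "iou",
    "match_detections",
    "average_precision",
]

RECALL_LEVELS = np.round(np.arange(0.0, 1.01, 0.1), 1)  # 0, 0.1, ..., 1.0


@dataclass
class ObjectAnnotation:
    """One labeled object: center-format box, class, mask pixel list."""

    box: tuple[float, float, float, float]       # center x, y, width, height
    label: str
    mask: np.ndarray                             # (k, 2) int (x, y) points

    def validate(self, width: int, height: int) -> None:
        cx, cy, w, h = self.box
        if not (0 <= cx - w / 2 and cx + w / 2 <= width
                and 0 <= cy - h / 2 and cy + h / 2 <= height):
            raise ValueError(f"box {self.box} outside {width}x{height} image")
        if len(self.mask):
            mx, my = np.asarray(self.mask).T
            if ((mx < cx - w / 2 - 0.5).any() or (mx > cx + w / 2 + 0.5).any()
                    or (my < cy - h / 2 - 0.5).any() or (my > cy + h / 2 + 0.5).any()):
                raise ValueError("mask pixel outside its box")


@dataclass
class AnnotationRecord:
    """All objects of one forged image."""

    image_id: str
    objects: list[ObjectAnnotation]


@dataclass
class ForgeConfig:
    """Forge settings: source video, background pool, counts, seed."""

    source_video: str | Path
    backgrounds: Sequence[np.ndarray]            # pool of uint8 images (H, W[, 3])
    n_images: int = 10
    objects_per_image: tuple[int, int] = (1, 3)  # inclusive range
    seed: int = 0
    mode: str = "otsu"                           # "otsu" | "manual"
    manual_threshold: float | None = None
    invert: bool = False
    min_area: int = 20
    label: str = "animal"
    max_overlap_iou: float = 0.2
    max_retries: int = 50

    def __post_init__(self):
        if not len(self.backgrounds):
            raise ValueError("background pool is empty")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        lo, hi = self.objects_per_image
        if lo < 1 or hi < lo:
            raise ValueError("invalid objects_per_image range")


def _harvest_objects(cfg: ForgeConfig, rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray]]:
    """Segment animals out of randomly sampled source frames.

    Returns a list of (pixel coordinates relative to box corner, intensity
    values) pairs, one per harvested animal.
    """
    from .avi import AviReader

    reader = AviReader(cfg.source_video)
    detector = ThresholdDetector(
        g=cfg.manual_threshold if cfg.mode == "manual" else None,
        invert=cfg.invert, min_area=cfg.min_area)
    harvested: list[tuple[np.ndarray, np.ndarray]] = []
    tries = 0
    n_wanted = max(20, cfg.n_images * cfg.objects_per_image[1])
    while len(harvested) < n_wanted:
        if tries >= cfg.max_retries and not harvested:
            raise RuntimeError("no contours found in sampled frames")
        if tries >= cfg.max_retries:
            break
        tries += 1
        idx = int(rng.integers(reader.n_frames))
        frame = preprocess(Frame(reader.read_frame(idx), idx))
        dets = detect_instances(frame, detector)
        for d in dets:
            if d.mask is None or not len(d.mask):
                continue
            pts = np.asarray(d.mask)
            origin = pts.min(axis=0)
            values = frame.pixels[pts[:, 1], pts[:, 0]]
            harvested.append((pts - origin, values))
    reader.close()
    return harvested


def forge_dataset(cfg: ForgeConfig) -> tuple[list[np.ndarray], list[AnnotationRecord]]:
    """Forge ``cfg.n_images`` copy-paste images with annotations.

    Deterministic given ``cfg.seed``: the same configuration reproduces the
    dataset byte for byte.
    """
    rng = np.random.default_rng(cfg.seed)
    objects = _harvest_objects(cfg, rng)
    images: list[np.ndarray] = []
    records: list[AnnotationRecord] = []
    for i in range(cfg.n_images):
        bg = cfg.backgrounds[int(rng.integers(len(cfg.backgrounds)))]
        canvas = np.asarray(bg).copy()
        if canvas.ndim == 3:
            canvas = canvas[..., 0].copy()  # forge works in grayscale
        H, W = canvas.shape
        n_obj = int(rng.integers(cfg.objects_per_image[0], cfg.objects_per_image[1] + 1))
        anns: list[ObjectAnnotation] = []
        placed_boxes: list[tuple[float, float, float, float]] = []
        for _ in range(n_obj):
            for _attempt in range(cfg.max_retries):
                pts, values = objects[int(rng.integers(len(objects)))]
                h = int(pts[:, 1].max()) + 1
                w = int(pts[:, 0].max()) + 1
                if w >= W or h >= H:
                    continue
                x0 = int(rng.integers(0, W - w))
                y0 = int(rng.integers(0, H - h))
                box = (x0 + (w - 1) / 2.0, y0 + (h - 1) / 2.0, float(w), float(h))
                if any(iou(box, b) > cfg.max_overlap_iou for b in placed_boxes):
                    continue
                shifted = pts + (x0, y0)
                canvas[shifted[:, 1], shifted[:, 0]] = values
                anns.append(ObjectAnnotation(box=box, label=cfg.label, mask=shifted))
                placed_boxes.append(box)
                break
        images.append(canvas)
        records.append(AnnotationRecord(image_id=f"image{i}", objects=anns))
    return images, records


def serialize_annotations(records: Sequence[AnnotationRecord], path: str | Path) -> None:
    """Write annotations as nested JSON: image → object → {box, class, mask}."""
    doc = {}
    for rec in records:
        objs = {}
        for j, o in enumerate(rec.objects):
            cx, cy, w, h = o.box
            objs[f"object{j}"] = {
                "box": {"center": {"x": cx, "y": cy}, "width": w, "height": h},
                "class": o.label,
                "mask": np.asarray(o.mask).astype(int).tolist(),
            }
        doc[rec.image_id] = objs
    Path(path).write_text(json.dumps(doc, indent=None, sort_keys=True))


def load_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Inverse of :func:`serialize_annotations` (lossless round trip)."""
    doc = json.loads(Path(path).read_text())
    records = []
    for image_id in sorted(doc, key=lambda s: (len(s), s)):
        objs = []
        for key in sorted(doc[image_id], key=lambda s: (len(s), s)):
            o = doc[image_id][key]
            b = o["box"]
            objs.append(ObjectAnnotation(
                box=(b["center"]["x"], b["center"]["y"], b["width"], b["height"]),
                label=o["class"],
                mask=np.asarray(o["mask"], dtype=int).reshape(-1, 2),
            ))
        records.append(AnnotationRecord(image_id=image_id, objects=objs))
    return records


def iou(box_a: Sequence[float], box_b: Sequence[float]) -> float:
    """Intersection over union of two center-format boxes (cx, cy, w, h)."""
    ax, ay, aw, ah = box_a
    bx, by, bw, bh = box_b
    if aw <= 0 or ah <= 0 or bw <= 0 or bh <= 0:
        raise ValueError("zero-area box")
    ix = max(0.0, min(ax + aw / 2, bx + bw / 2) - max(ax - aw / 2, bx - bw / 2))
    iy = max(0.0, min(ay + ah / 2, by + bh / 2) - max(ay - ah / 2, by - bh / 2))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return min(1.0, inter / union)  # guard one-ulp overshoot for identical boxes


def _ranked(predictions: Sequence[Detection]) -> list[Detection]:
    return sorted(predictions, key=lambda d: -(d.score if d.score is not None else 1.0))


def match_detections(predictions: Sequence[Detection],
                     targets: Sequence[ObjectAnnotation | Detection],
                     x: float = 0.5) -> tuple[int, int, int]:
    """Greedy score-ranked matching at IoU threshold ``x`` → (TP, FP, FN).

    Each prediction, taken in descending score order, is a true positive if
    its best-IoU unmatched target reaches the threshold, else a false
    positive; targets never matched are false negatives.
    """
    preds = _ranked(predictions)
    matched = [False] * len(targets)
    tp = fp = 0
    for p in preds:
        best, best_j = 0.0, -1
        for j, t in enumerate(targets):
            if matched[j]:
                continue
            v = iou(p.box, t.box)
            if v > best:
                best, best_j = v, j
        if best_j >= 0 and best >= x:
            matched[best_j] = True
            tp += 1
        else:
            fp += 1
    fn = matched.count(False)
    return tp, fp, fn


@dataclass
class PRCurve:
    """Precision/recall along the ranked detection list, with interpolated AP."""

    precision: np.ndarray          # per rank
    recall: np.ndarray             # per rank, non-decreasing
    interpolated: np.ndarray       # P_interp at the 11 recall levels
    ap: float


def average_precision(predictions: Sequence[Detection],
                      targets: Sequence[ObjectAnnotation | Detection],
                      x: float = 0.5) -> PRCurve:
    """11-point interpolated average precision of a ranked detection list.

    Precision and recall are accumulated rank by rank (greedy matching as in
    :func:`match_detections`); the interpolated precision at recall level r
    is the maximum precision at any recall ≥ r, and AP is the mean of the
    interpolated precision over the 11 levels 0, 0.1, …, 1.0.
    """
    if not len(targets):
        raise ValueError("average precision needs at least one target")
    preds = _ranked(predictions)
    matched = [False] * len(targets)
    tp = fp = 0
    prec, rec = [], []
    for p in preds:
        best, best_j = 0.0, -1
        for j, t in enumerate(targets):
            if matched[j]:
                continue
            v = iou(p.box, t.box)
            if v > best:
                best, best_j = v, j
        if best_j >= 0 and best >= x:
            matched[best_j] = True
            tp += 1
        else:
            fp += 1
        prec.append(tp / (tp + fp))
        rec.append(tp / len(targets))
    prec_a = np.asarray(prec)
    rec_a = np.asarray(rec)
    interp = np.zeros(len(RECALL_LEVELS))
    for i, r in enumerate(RECALL_LEVELS):
        at_least = prec_a[rec_a >= r - 1e-12] if len(prec_a) else np.zeros(0)
        interp[i] = at_least.max() if len(at_least) else 0.0
    ap = float(interp.mean())
    return PRCurve(precision=prec_a, recall=rec_a, interpolated=interp, ap=ap)
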