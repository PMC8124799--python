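"""Paired-posture (trophallaxis-like) auto-labeling and classifier evaluation.

When two social insects exchange food they face each other head-to-head, so
the merged blob has roughly twice the area and twice the body length of a
single animal.  The heuristic first estimates the median (M) and standard
deviation (sd) of single-body area and length from frames without crossings,
then labels a candidate blob as the paired behavior when its area lies in
[2(M_a − sd_a), 2(M_a + sd_a)] and its length in [2(M_l − sd_l),
2(M_l + sd_l)] (all bounds inclusive).  Crops labeled this way train the
binary recognizer; agreement with reference labels is summarized by the
confusion matrix, global accuracy, Cohen's kappa, and a large-sample Z test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from skimage.transform import resize

from .track import Contour, TrackerConfig, _segment_frame, extract_contours
from .video import Frame, open_stream

__all__ = [
    "BodyStats",
    "BehaviorSample",
    "ConfusionReport",
    "estimate_body_stats",
    "label_candidate",
    "build_labeled_set",
    "behavior_occurrence",
    "evaluate_classifier",
    "train_classifier",
]


@dataclass(frozen=True)
class BodyStats:
    """Median and standard deviation of single-body area (px²) and length (px)."""

    median_area: float
    sd_area: float
    median_length: float
    sd_length: float

    def __post_init__(self):
        if min(self.median_area, self.sd_area, self.median_length, self.sd_length) < 0:
            raise ValueError("body statistics must be non-negative")


@dataclass
class BehaviorSample:
    """One candidate crop with its heuristic label (1 = behavior present)."""

    crop: np.ndarray          # (H, W) float in [0, 1], classifier input size
    label: int
    frame_index: int = -1

    def __post_init__(self):
        if self.crop.size == 0:
            raise ValueError("empty crop")


def estimate_body_stats(contours_per_frame: Sequence[Sequence[Contour]],
                        n: int) -> BodyStats:
    """Body statistics from frames whose contour count equals the group size.

    Only such frames are crossing-free, so every contour there is a single
    body.  Raises when no crossing-free frame exists.
    """
    areas: list[float] = []
    lengths: list[float] = []
    for contours in contours_per_frame:
        if len(contours) == n:
            areas.extend(c.area for c in contours)
            lengths.extend(c.length for c in contours)
    if not areas:
        raise ValueError("no crossing-free frames: cannot estimate body statistics")
    return BodyStats(
        median_area=float(np.median(areas)),
        sd_area=float(np.std(areas)),
        median_length=float(np.median(lengths)),
        sd_length=float(np.std(lengths)),
    )


def label_candidate(blob: Contour | tuple[float, float], stats: BodyStats) -> int:
    """1 when the blob's area and length both sit in the doubled-body window."""
    if isinstance(blob, Contour):
        area, length = blob.area, blob.length
    else:
        area, length = blob
    ok_area = 2 * (stats.median_area - stats.sd_area) <= area <= 2 * (stats.median_area + stats.sd_area)
    ok_len = 2 * (stats.median_length - stats.sd_length) <= length <= 2 * (stats.median_length + stats.sd_length)
    return int(ok_area and ok_len)


def _crop(gray: np.ndarray, contour: Contour, out_size: tuple[int, int]) -> np.ndarray:
    pts = contour.pixels.astype(int)
    x0, y0 = pts.min(axis=0)
    x1, y1 = pts.max(axis=0)
    patch = gray[y0:y1 + 1, x0:x1 + 1].astype(float) / 255.0
    return resize(patch, out_size, preserve_range=True, anti_aliasing=True)


def build_labeled_set(video: str | Path, cfg: TrackerConfig,
                      crop_size: tuple[int, int] = (64, 64),
                      stats: BodyStats | None = None) -> tuple[list[BehaviorSample], BodyStats]:
    """Auto-label every detected blob crop of a video via the posture heuristic.

    Runs segmentation on each frame, estimates body statistics from the
    crossing-free frames (unless given), then crops each blob's bounding box
    from the preprocessed grayscale frame, resizes it to ``crop_size`` and
    labels it.  Fully deterministic for a given video and configuration.
    """
    from .video import preprocess

    stream = open_stream(video)
    frames_contours: list[tuple[np.ndarray, list[Contour]]] = []
    for frame in stream:
        mask = _segment_frame(frame, cfg)
        contours = extract_contours(mask, cfg.contour_filter)
        gray = preprocess(frame, roi=cfg.roi, median_kernel=cfg.median_kernel)
        frames_contours.append((gray.pixels, contours))
    if stats is None:
        stats = estimate_body_stats([c for _, c in frames_contours], cfg.n_individuals)
    samples: list[BehaviorSample] = []
    for t, (gray, contours) in enumerate(frames_contours):
        for c in contours:
            samples.append(BehaviorSample(crop=_crop(gray, c, crop_size),
                                          label=label_candidate(c, stats),
                                          frame_index=t))
    return samples, stats


def behavior_occurrence(classify: Callable[[np.ndarray], np.ndarray],
                        video: str | Path, cfg: TrackerConfig,
                        crop_size: tuple[int, int] = (64, 64)) -> float:
    """Percentage of frames in which the behavior occurs.

    ``classify`` maps a stack of crops (N, H, W) to binary labels; a frame
    counts as an occurrence when any of its candidate crops is classified 1.
    """
    stream = open_stream(video)
    from .video import preprocess

    n_frames = 0
    occurrences = 0
    for frame in stream:
        n_frames += 1
        mask = _segment_frame(frame, cfg)
        contours = extract_contours(mask, cfg.contour_filter)
        if not contours:
            continue
        gray = preprocess(frame, roi=cfg.roi, median_kernel=cfg.median_kernel)
        crops = np.stack([_crop(gray.pixels, c, crop_size) for c in contours])
        if np.asarray(classify(crops)).astype(int).any():
            occurrences += 1
    return 100.0 * occurrences / n_frames if n_frames else 0.0


@dataclass
class ConfusionReport:
    """2×2 confusion counts with accuracy, Cohen's kappa, and its Z statistic."""

    matrix: np.ndarray            # rows: truth 0/1, cols: prediction 0/1
    accuracy: float
    kappa: float
    z: float
    significant: bool             # two-sided 5% test of kappa != 0

    def summary(self) -> str:
        m = self.matrix
        return (f"confusion [[TN={m[0,0]}, FP={m[0,1]}], [FN={m[1,0]}, TP={m[1,1]}]]  "
                f"accuracy={self.accuracy:.4f}  kappa={self.kappa:.4f}  "
                f"Z={self.z:.2f} ({'significant' if self.significant else 'not significant'} at 5%)")


def evaluate_classifier(predictions: Sequence[int], truth: Sequence[int]) -> ConfusionReport:
    """Agreement of binary predictions with reference labels.

    Global accuracy is the confusion-matrix trace over the total; kappa is
    (p_o − p_e)/(1 − p_e) with the chance agreement p_e from the marginals;
    Z = kappa / SE₀(kappa) uses the large-sample null variance
    (p_e + p_e² − Σᵢ pᵢ₊ p₊ᵢ (pᵢ₊ + p₊ᵢ)) / (N (1 − p_e)²).
    """
    pred = np.asarray(predictions, dtype=int)
    ref = np.asarray(truth, dtype=int)
    if pred.shape != ref.shape or pred.size == 0:
        raise ValueError("predictions and truth must be equal-length, non-empty")
    m = np.zeros((2, 2), dtype=int)
    for t, p in ((0, 0), (0, 1), (1, 0), (1, 1)):
        m[t, p] = int(((ref == t) & (pred == p)).sum())
    total = m.sum()
    po = m.trace() / total
    row = m.sum(axis=1) / total     # truth marginals p_i+
    col = m.sum(axis=0) / total     # prediction marginals p_+i
    pe = float((row * col).sum())
    if pe >= 1.0:
        kappa = 1.0 if po >= 1.0 else 0.0
        z = float("inf") if kappa == 1.0 else 0.0
    else:
        kappa = (po - pe) / (1 - pe)
        var0 = (pe + pe**2 - float((row * col * (row + col)).sum())) / (total * (1 - pe) ** 2)
        z = kappa / np.sqrt(var0) if var0 > 0 else float("inf") * np.sign(kappa or 1)
    return ConfusionReport(matrix=m, accuracy=float(po), kappa=float(kappa),
                           z=float(z), significant=bool(abs(z) > 1.959963984540054))


def train_classifier(samples: Sequence[BehaviorSample],
                     spec=None,
                     split: tuple[float, float, float] = (0.7, 0.2, 0.1),
                     seed: int = 0,
                     epochs: int = 100):
    """Train the behavior recognizer on heuristic-labeled samples.

    Samples are split stratified into train/validation/test fractions
    (default 70/20/10); training follows the fixed optimizer/loss recipe.
    Returns ``(classifier, history, test_report)`` where the report evaluates
    the held-out test fraction (None when the test fraction is empty).
    """
    from .nn import BehaviorClassifier, ClassifierSpec

    labels = np.asarray([s.label for s in samples], dtype=int)
    if len(labels) == 0:
        raise ValueError("no samples")
    if len(np.unique(labels)) < 2:
        raise ValueError("training needs both classes present")
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    train_idx, val_idx, test_idx = [], [], []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        idx = idx[rng.permutation(len(idx))]
        n = len(idx)
        n_tr = int(round(split[0] * n))
        n_va = int(round(split[1] * n))
        train_idx.extend(idx[:n_tr])
        val_idx.extend(idx[n_tr:n_tr + n_va])
        test_idx.extend(idx[n_tr + n_va:])
    crops = np.stack([s.crop for s in samples])
    spec = spec or ClassifierSpec(input_size=crops.shape[1:])
    clf = BehaviorClassifier(spec, seed=seed)
    val = ((crops[val_idx], labels[val_idx].astype(float)) if val_idx else None)
    hist = clf.fit(crops[train_idx], labels[train_idx], epochs=epochs, val=val)
    report = None
    if test_idx:
        preds = clf.predict(crops[test_idx])
        report = evaluate_classifier(preds, labels[test_idx])
    return clf, hist, report
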