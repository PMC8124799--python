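"""Foreground segmentation: global thresholding, Otsu's method, morphology.

Otsu's threshold is computed from the normalized gray-level histogram: for a
candidate level ``k`` the pixels split into background (≤ k) and foreground
(> k) classes with weights ω0, ω1 and means μ0, μ1; the chosen k maximizes
the between-class variance σ_b² = ω0·ω1·(μ1 − μ0)², which is equivalent to
minimizing the within-class variance since their sum is the total variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import dilation as _sk_dilation, erosion as _sk_erosion


def _dilate(mask: np.ndarray, fp: np.ndarray) -> np.ndarray:
    return _sk_dilation(mask.astype(np.uint8), fp).astype(bool)


def _erode(mask: np.ndarray, fp: np.ndarray) -> np.ndarray:
    return _sk_erosion(mask.astype(np.uint8), fp).astype(bool)

from .video import Frame

__all__ = [
    "OtsuResult",
    "Detection",
    "Detector",
    "DetectorError",
    "threshold_manual",
    "threshold_otsu",
    "otsu_curve",
    "morph_cleanup",
    "detect_instances",
    "ThresholdDetector",
]


class DetectorError(RuntimeError):
    """A plug-in detector failed or violated its contract."""


@dataclass(frozen=True)
class OtsuResult:
    """Chosen threshold ``k`` with its between-class variance and histogram."""

    k: int
    sigma_b2: float
    histogram: np.ndarray  # per-level probabilities p_i, sums to 1


@dataclass
class Detection:
    """One detected instance: center-format box, class label, pixel mask, score."""

    box: tuple[float, float, float, float]  # center x, center y, width, height
    label: str = "animal"
    mask: np.ndarray | None = None  # (k, 2) array of (x, y) pixel points
    score: float | None = None

    def validate(self, width: int, height: int) -> None:
        cx, cy, w, h = self.box
        if w <= 0 or h <= 0:
            raise DetectorError("box with non-positive extent")
        if cx - w / 2 < -0.5 or cy - h / 2 < -0.5 or cx + w / 2 > width - 0.5 or cy + h / 2 > height - 0.5:
            raise DetectorError(f"box {self.box} outside {width}x{height} image")
        if self.score is not None and not 0 <= self.score <= 1:
            raise DetectorError("score outside [0, 1]")
        if self.mask is not None and len(self.mask):
            mx, my = np.asarray(self.mask).T
            if (mx < cx - w / 2 - 0.5).any() or (mx > cx + w / 2 + 0.5).any() or (
                my < cy - h / 2 - 0.5
            ).any() or (my > cy + h / 2 + 0.5).any():
                raise DetectorError("mask pixels outside their box")

    @property
    def corner_box(self) -> tuple[float, float, float, float]:
        """Box as (x_min, y_min, width, height)."""
        cx, cy, w, h = self.box
        return (cx - w / 2, cy - h / 2, w, h)


class Detector(Protocol):
    """Contract for pluggable instance detectors (e.g. a trained deep model)."""

    def __call__(self, frame: Frame) -> Sequence[Detection]: ...


def _as_gray(frame: Frame | np.ndarray) -> np.ndarray:
    px = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    if px.ndim != 2:
        raise ValueError("segmentation expects a grayscale frame; run preprocess first")
    return px


def threshold_manual(frame: Frame | np.ndarray, g: float, invert: bool = False) -> np.ndarray:
    """Binary mask from a user-chosen global threshold ``g``.

    Foreground is ``pixel > g`` (bright animals on dark background); set
    ``invert`` for dark animals on a light background.
    """
    if not 0 <= g <= 255:
        raise ValueError("threshold must be in [0, 255]")
    px = _as_gray(frame)
    mask = px <= g if invert else px > g
    return mask.astype(np.uint8)


def otsu_curve(px: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Between- and within-class variance at every gray level.

    Returns ``(levels, sigma_b2, sigma_w2)`` over all 256 levels; entries where
    one class is empty are NaN.
    """
    counts = np.bincount(px.ravel(), minlength=256).astype(float)
    p = counts / counts.sum()
    levels = np.arange(256)
    omega0 = np.cumsum(p)
    omega1 = 1.0 - omega0
    mu_cum = np.cumsum(p * levels)
    mu_t = mu_cum[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum / omega0
        mu1 = (mu_t - mu_cum) / omega1
        sigma_b2 = omega0 * omega1 * (mu1 - mu0) ** 2
    valid = (omega0 > 0) & (omega1 > 0)
    sigma_b2 = np.where(valid, sigma_b2, np.nan)
    sigma_t2 = float(np.sum(p * (levels - mu_t) ** 2))
    sigma_w2 = sigma_t2 - sigma_b2
    return levels, sigma_b2, sigma_w2


def threshold_otsu(frame: Frame | np.ndarray) -> tuple[OtsuResult, np.ndarray]:
    """Otsu's automatic threshold plus the resulting binary mask.

    The threshold maximizes the between-class variance; ties break toward the
    smallest level so results are deterministic.  Raises on constant frames
    (the histogram is degenerate: no split yields two nonempty classes).
    """
    px = _as_gray(frame)
    counts = np.bincount(px.ravel(), minlength=256)
    if np.count_nonzero(counts) < 2:
        raise ValueError("degenerate histogram: frame has a single gray level")
    _, sigma_b2, _ = otsu_curve(px)
    k = int(np.nanargmax(sigma_b2))  # nanargmax returns the first (smallest) maximizer
    result = OtsuResult(k=k, sigma_b2=float(sigma_b2[k]), histogram=counts / counts.sum())
    return result, (px > k).astype(np.uint8)


def morph_cleanup(
    mask: np.ndarray,
    dilate_kernel: int = 3,
    erode_kernel: int = 3,
    iterations: int = 1,
) -> np.ndarray:
    """Morphological cleanup: dilate, subtract the gradient, then erode.

    Dilation bridges fragments of one animal detected separately; the
    morphological gradient (dilation minus erosion of the dilated mask) is
    subtracted to strip undesirable edges; a final erosion removes specks.
    """
    for k in (dilate_kernel, erode_kernel):
        if k < 1 or k % 2 == 0:
            raise ValueError("kernels must be odd and >= 1")
    out = np.asarray(mask).astype(bool)
    dil_fp = _ellipse_footprint(dilate_kernel)
    ero_fp = _ellipse_footprint(erode_kernel)
    for _ in range(iterations):
        dilated = _dilate(out, dil_fp)
        gradient = _dilate(dilated, dil_fp) & ~_erode(dilated, dil_fp)
        out = _erode(dilated & ~gradient, ero_fp)
    return out.astype(np.uint8)


def _ellipse_footprint(size: int) -> np.ndarray:
    if size == 1:
        return np.ones((1, 1), dtype=bool)
    r = size / 2.0
    yy, xx = np.mgrid[0:size, 0:size] - (size - 1) / 2.0
    return (xx / r) ** 2 + (yy / r) ** 2 <= 1.0


class ThresholdDetector:
    """Reference detector: Otsu (or manual) threshold + connected components.

    Satisfies the :class:`Detector` contract on homogeneous scenes; every
    component becomes one detection with a constant score of 1.
    """

    def __init__(self, g: float | None = None, invert: bool = False,
                 min_area: int = 1, cleanup: bool = False):
        self.g = g
        self.invert = invert
        self.min_area = min_area
        self.cleanup = cleanup

    def __call__(self, frame: Frame) -> list[Detection]:
        px = _as_gray(frame)
        if self.g is not None:
            mask = threshold_manual(px, self.g, self.invert)
        else:
            if np.count_nonzero(np.bincount(px.ravel(), minlength=256)) < 2:
                return []
            _, mask = threshold_otsu(px)
            if self.invert:
                mask = 1 - mask
        if self.cleanup:
            mask = morph_cleanup(mask)
        labels, n = ndimage.label(mask)
        dets: list[Detection] = []
        for i in range(1, n + 1):
            ys, xs = np.nonzero(labels == i)
            if len(xs) < self.min_area:
                continue
            x0, x1 = xs.min(), xs.max()
            y0, y1 = ys.min(), ys.max()
            box = ((x0 + x1) / 2.0, (y0 + y1) / 2.0, float(x1 - x0 + 1), float(y1 - y0 + 1))
            dets.append(Detection(box=box, mask=np.column_stack([xs, ys]), score=1.0))
        return dets


def detect_instances(frame: Frame, detector: Detector) -> list[Detection]:
    """Run a detector on one frame, validate, and rank by descending score."""
    try:
        dets = list(detector(frame))
    except DetectorError:
        raise
    except Exception as exc:
        raise DetectorError(f"detector failed on frame {frame.index}: {exc}") from exc
    for d in dets:
        d.validate(frame.width, frame.height)
    return sorted(dets, key=lambda d: -(d.score if d.score is not None else 1.0))
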