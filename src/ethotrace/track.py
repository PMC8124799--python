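"""Contour extraction, occlusion splitting, and identity maintenance.

The tracker turns per-frame binary masks into labeled centroids.  Merged
individuals (fewer contours than the expected group size) are separated by
k-means with k-means++ seeding on the merged blob's pixels.  Identities are
carried across frames by minimum-cost assignment between consecutive centroid
sets (Hungarian row/column-reduction and zero-covering procedure on the
Euclidean distance matrix).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .segment import morph_cleanup, threshold_manual, threshold_otsu
from .video import Frame, FrameBuffer, preprocess

log = logging.getLogger(__name__)

__all__ = [
    "Contour",
    "ContourFilter",
    "CentroidSet",
    "extract_contours",
    "split_merged",
    "kmeans_pp",
    "hungarian",
    "assign_identities",
    "TrackerConfig",
    "track",
]

# Cost used to pad rectangular assignment problems; far above any image distance.
_PROHIBITIVE = 1e9


@dataclass
class Contour:
    """A detected body: boundary polygon, area, length, centroid, pixels."""

    boundary: np.ndarray      # (k, 2) ordered (x, y) polygon vertices
    area: float               # px², pixel count of the filled region
    length: float             # px, major axis of the min-area rotated rectangle
    centroid: tuple[float, float]
    pixels: np.ndarray        # (m, 2) (x, y) coordinates of the filled region

    @property
    def aspect(self) -> float:
        return self.area / self.length if self.length > 0 else 0.0


@dataclass
class ContourFilter:
    """Size gates applied to candidate contours (area, length, area/length)."""

    min_area: float = 1.0
    max_area: float = np.inf
    min_length: float = 0.0
    max_length: float = np.inf
    min_ratio: float = 0.0
    max_ratio: float = np.inf

    def __post_init__(self):
        for lo, hi in ((self.min_area, self.max_area),
                       (self.min_length, self.max_length),
                       (self.min_ratio, self.max_ratio)):
            if lo > hi:
                raise ValueError("filter minimum exceeds maximum")

    def accepts(self, c: Contour) -> bool:
        return (self.min_area <= c.area <= self.max_area
                and self.min_length <= c.length <= self.max_length
                and self.min_ratio <= c.aspect <= self.max_ratio)


@dataclass
class CentroidSet:
    """Labeled centroids of one frame; labels 1..n, unique within the frame."""

    frame_index: int
    points: np.ndarray          # (n, 2) float (x, y); NaN rows mark gaps
    labels: np.ndarray          # (n,) int identity labels

    def __post_init__(self):
        if len(set(self.labels.tolist())) != len(self.labels):
            raise ValueError("identity labels must be unique within a frame")


def _min_rect_length(points: np.ndarray) -> float:
    """Major-axis length of the minimum-area rotated rectangle around points."""
    from shapely import MultiPoint

    pts = np.asarray(points, dtype=float)
    if len(pts) == 1:
        return 1.0
    hull = MultiPoint(pts).convex_hull
    rect = hull.minimum_rotated_rectangle
    if rect.geom_type == "Point":
        return 1.0
    if rect.geom_type == "LineString":
        return float(rect.length) + 1.0
    xy = np.asarray(rect.exterior.coords)
    sides = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    return float(sides.max()) + 1.0  # +1: pixel centers → pixel extents


def _boundary_polygon(region_mask: np.ndarray, origin: tuple[int, int]) -> np.ndarray:
    """External boundary of a region as extreme points only (collinear runs collapsed)."""
    from skimage import measure

    padded = np.pad(region_mask, 1)
    contours = measure.find_contours(padded.astype(float), 0.5)
    if not contours:
        return np.zeros((0, 2))
    rc = max(contours, key=len)  # external boundary is the longest
    poly = measure.approximate_polygon(rc, tolerance=0.0)  # drop collinear points
    y0, x0 = origin
    # find_contours gives (row, col); convert to (x, y) in the full image
    return np.column_stack([poly[:, 1] - 1 + x0, poly[:, 0] - 1 + y0])


def extract_contours(mask: np.ndarray, cfilter: ContourFilter | None = None) -> list[Contour]:
    """External contours of a binary mask, with area/length/centroid, filtered.

    Components are 8-connected; holes are ignored (no hierarchy).  Area is the
    filled pixel count, length the major axis of the minimum-area rotated
    bounding rectangle, centroid the pixel-coordinate mean.
    """
    mask = np.asarray(mask).astype(bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    out: list[Contour] = []
    if n == 0:
        return out
    slices = ndimage.find_objects(labels)
    for i, sl in enumerate(slices, start=1):
        region = labels[sl] == i
        ys, xs = np.nonzero(region)
        y0, x0 = sl[0].start, sl[1].start
        xs = xs + x0
        ys = ys + y0
        pixels = np.column_stack([xs, ys]).astype(float)
        area = float(len(xs))
        length = _min_rect_length(pixels)
        centroid = (float(xs.mean()), float(ys.mean()))
        boundary = _boundary_polygon(region, (y0, x0))
        c = Contour(boundary=boundary, area=area, length=length,
                    centroid=centroid, pixels=pixels)
        if cfilter is None or cfilter.accepts(c):
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# k-means++ splitting of merged blobs
# ---------------------------------------------------------------------------

def kmeans_pp(points: np.ndarray, k: int, rng: np.random.Generator,
              max_iter: int = 100,
              history: list | None = None) -> tuple[np.ndarray, np.ndarray, float]:
    """One k-means run with k-means++ seeding.

    The first center is drawn uniformly from the data; each subsequent center
    is a data point drawn with probability proportional to its squared
    distance to the nearest already-chosen center.  Lloyd iterations then run
    to a local minimum of the within-cluster sum of squared distances φ.

    Returns ``(centers, assignment, phi)``; when ``history`` is a list, the
    objective after each Lloyd update is appended to it.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if k < 1 or n < k:
        raise ValueError(f"need at least k={k} points, got {n}")
    centers = np.empty((k, 2), dtype=float)
    centers[0] = pts[rng.integers(n)]
    d2 = np.sum((pts - centers[0]) ** 2, axis=1)
    for i in range(1, k):
        total = d2.sum()
        if total <= 0:  # all remaining points coincide with a chosen center
            centers[i] = pts[rng.integers(n)]
        else:
            centers[i] = pts[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, np.sum((pts - centers[i]) ** 2, axis=1))
    assign = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        dist = np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2)
        new_assign = dist.argmin(axis=1)
        for j in range(k):
            sel = new_assign == j
            if sel.any():
                centers[j] = pts[sel].mean(axis=0)
            else:  # empty cluster: reseed at the farthest point
                centers[j] = pts[dist.min(axis=1).argmax()]
                new_assign[dist.min(axis=1).argmax()] = j
        if history is not None:
            d2i = np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2)
            a2i = d2i.argmin(axis=1)
            history.append(float((d2i[np.arange(n), a2i] ** 2).sum()))
        if np.array_equal(new_assign, assign) and _ > 0:
            break
        assign = new_assign
    dist = np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=2)
    assign = dist.argmin(axis=1)
    phi = float((dist[np.arange(n), assign] ** 2).sum())
    return centers, assign, phi


def split_merged(points: np.ndarray, k: int, seed: int,
                 restarts: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Split a merged blob's pixels into ``k`` clusters; best of ``restarts`` runs.

    Deterministic given ``seed``; returns ``(centers, assignment)`` of the run
    with the lowest within-cluster sum of squares.
    """
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(max(1, restarts)):
        centers, assign, phi = kmeans_pp(points, k, rng)
        if best is None or phi < best[0]:
            best = (phi, centers, assign)
    return best[1], best[2]


# ---------------------------------------------------------------------------
# Hungarian assignment
# ---------------------------------------------------------------------------

def hungarian(cost: np.ndarray) -> np.ndarray:
    """Minimum-cost assignment on a square matrix.

    Implements the classical reduction procedure: subtract each row's minimum,
    then each column's; cover all zeros with the fewest lines; while fewer
    than n lines suffice, shift the smallest uncovered entry (subtract from
    uncovered rows, add to covered columns) and re-cover.  Returns ``col[i]``,
    the column assigned to row ``i``.  Ties resolve to the lexicographically
    smallest assignment by construction of the zero search.
    """
    c = np.asarray(cost, dtype=float).copy()
    n, m = c.shape
    if n != m:
        raise ValueError("hungarian expects a square matrix")
    c -= c.min(axis=1, keepdims=True)
    c -= c.min(axis=0, keepdims=True)

    starred = np.zeros((n, n), dtype=bool)
    primed = np.zeros((n, n), dtype=bool)
    row_cov = np.zeros(n, dtype=bool)
    col_cov = np.zeros(n, dtype=bool)

    # initial independent zeros
    for i in range(n):
        for j in range(n):
            if c[i, j] == 0 and not row_cov[i] and not col_cov[j]:
                starred[i, j] = True
                row_cov[i] = True
                col_cov[j] = True
    row_cov[:] = False
    col_cov[:] = False

    while True:
        col_cov = starred.any(axis=0)
        if col_cov.all():
            break
        while True:
            # find an uncovered zero
            zero = None
            for i in range(n):
                if row_cov[i]:
                    continue
                js = np.nonzero((c[i] == 0) & ~col_cov)[0]
                if len(js):
                    zero = (i, js[0])
                    break
            if zero is None:
                # adjust: smallest uncovered value
                minval = c[~row_cov][:, ~col_cov].min()
                c[~row_cov] -= minval
                c[:, col_cov] += minval
                continue
            i, j = zero
            primed[i, j] = True
            sj = np.nonzero(starred[i])[0]
            if len(sj):
                row_cov[i] = True
                col_cov[sj[0]] = False
            else:
                # augmenting path of alternating primed/starred zeros
                path = [(i, j)]
                while True:
                    si = np.nonzero(starred[:, path[-1][1]])[0]
                    if not len(si):
                        break
                    path.append((si[0], path[-1][1]))
                    pj = np.nonzero(primed[path[-1][0]])[0]
                    path.append((path[-1][0], pj[0]))
                for (pi, pj) in path:
                    starred[pi, pj] = not starred[pi, pj]
                primed[:] = False
                row_cov[:] = False
                col_cov[:] = False
                break
    return starred.argmax(axis=1)


def assign_identities(prev: CentroidSet, curr_points: np.ndarray) -> CentroidSet:
    """Carry identity labels from the previous frame to new centroids.

    Minimizes the total Euclidean displacement over all bijections between the
    previous labeled centroids and the new unlabeled ones.  Unequal sizes are
    padded: a previous identity with no available detection keeps its old
    position at prohibitive cost and is recorded as a gap (NaN) this frame.
    """
    if len(prev.points) == 0 or len(curr_points) == 0:
        raise ValueError("cannot assign identities with an empty centroid set")
    curr_points = np.asarray(curr_points, dtype=float)
    n_prev, n_curr = len(prev.points), len(curr_points)
    n = max(n_prev, n_curr)

    prev_pts = prev.points
    prev_ok = ~np.isnan(prev_pts).any(axis=1)
    # distance from every previous identity to every current detection;
    # identities currently in a gap match anything at moderate (not prohibitive)
    # cost so they can re-anchor.
    cost = np.full((n, n), _PROHIBITIVE, dtype=float)
    for i in range(n_prev):
        if prev_ok[i]:
            cost[i, :n_curr] = np.linalg.norm(curr_points - prev_pts[i], axis=1)
        else:
            cost[i, :n_curr] = _PROHIBITIVE / 1e3
    col = hungarian(cost)

    new_points = np.full((n_prev, 2), np.nan)
    for i in range(n_prev):
        j = col[i]
        if j < n_curr and cost[i, j] < _PROHIBITIVE / 1e6:
            new_points[i] = curr_points[j]
    # re-anchor gap identities that did land on a detection
    for i in range(n_prev):
        j = col[i]
        if j < n_curr and not prev_ok[i]:
            new_points[i] = curr_points[j]
    return CentroidSet(frame_index=prev.frame_index + 1,
                       points=new_points, labels=prev.labels.copy())


# ---------------------------------------------------------------------------
# End-to-end tracking
# ---------------------------------------------------------------------------

@dataclass
class TrackerConfig:
    """Settings for the mask→trajectory pipeline."""

    n_individuals: int
    mode: str = "otsu"                      # "otsu" | "manual"
    manual_threshold: float | None = None
    invert: bool = False
    contour_filter: ContourFilter = field(default_factory=ContourFilter)
    median_kernel: int = 3
    cleanup: bool = True
    dilate_kernel: int = 3
    erode_kernel: int = 3
    roi: Optional[object] = None
    seed: int = 0
    lost_warning_frames: int = 10

    def __post_init__(self):
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.mode == "manual" and self.manual_threshold is None:
            raise ValueError("manual mode needs manual_threshold")


def _segment_frame(frame: Frame, cfg: TrackerConfig) -> np.ndarray:
    gray = preprocess(frame, roi=cfg.roi, median_kernel=cfg.median_kernel)
    if cfg.mode == "manual":
        mask = threshold_manual(gray, cfg.manual_threshold, invert=cfg.invert)
    else:
        try:
            _, mask = threshold_otsu(gray)
        except ValueError:
            return np.zeros(gray.pixels.shape, dtype=np.uint8)
        if cfg.invert:
            mask = 1 - mask
    if cfg.cleanup:
        mask = morph_cleanup(mask, cfg.dilate_kernel, cfg.erode_kernel)
    return mask


def _frame_centroids(mask: np.ndarray, cfg: TrackerConfig,
                     rng: np.random.Generator) -> tuple[np.ndarray, list[Contour]]:
    """Centroids for one frame, splitting merged blobs so that up to n exist."""
    n = cfg.n_individuals
    contours = extract_contours(mask, cfg.contour_filter)
    if not contours:
        return np.zeros((0, 2)), contours
    if len(contours) > n:
        contours = sorted(contours, key=lambda c: -c.area)[:n]
    centroids = [c.centroid for c in contours]
    if len(contours) < n:
        deficit = n - len(contours)
        largest = max(range(len(contours)), key=lambda i: contours[i].area)
        pts = contours[largest].pixels
        k = deficit + 1
        if len(pts) >= k:
            centers, _ = split_merged(pts, k, seed=int(rng.integers(2**31)))
            centroids = [c.centroid for i, c in enumerate(contours) if i != largest]
            centroids.extend([tuple(c) for c in centers])
    return np.asarray(centroids, dtype=float), contours


def track(stream: FrameBuffer, cfg: TrackerConfig) -> "TrajectorySet":
    """Segment, split, and identity-assign every frame of a stream.

    Returns a :class:`~ethotrace.trajectory.TrajectorySet` with one centroid
    per identity per frame (NaN where undetected).  The first frame's labels
    are assigned deterministically by sorting centroids by (y, x).
    """
    from .trajectory import TrajectorySet

    n = cfg.n_individuals
    rng = np.random.default_rng(cfg.seed)
    rows: list[np.ndarray] = []
    contours_per_frame: list[list[Contour]] = []
    state: CentroidSet | None = None
    lost_run = 0
    for frame in stream:
        mask = _segment_frame(frame, cfg)
        centroids, contours = _frame_centroids(mask, cfg, rng)
        contours_per_frame.append(contours)
        if len(centroids) == 0:
            lost_run += 1
            if lost_run == cfg.lost_warning_frames:
                log.warning("tracking lost: no contours for %d consecutive frames "
                            "up to frame %d", lost_run, frame.index)
            if state is None:
                rows.append(np.full((n, 2), np.nan))
            else:
                state = CentroidSet(frame.index, np.full((n, 2), np.nan), state.labels)
                rows.append(state.points.copy())
            continue
        lost_run = 0
        if state is None or np.isnan(state.points).all():
            # (re-)anchor: label by scan order (y, then x)
            order = np.lexsort((centroids[:, 0], centroids[:, 1]))
            pts = np.full((n, 2), np.nan)
            pts[: len(order)] = centroids[order]
            state = CentroidSet(frame.index, pts, np.arange(1, n + 1))
        else:
            state = assign_identities(state, centroids)
        rows.append(state.points.copy())
    if not rows:
        raise ValueError("empty stream")
    xy = np.stack(rows)  # (frames, n, 2)
    return TrajectorySet(xy=xy, fps=stream.fps, contours=contours_per_frame)
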