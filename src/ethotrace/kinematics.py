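"""Kinematic and collective-motion statistics from tracked trajectories.

Individual measures: tracked distance (cumulative path length), mean/max
velocity, turning angle (mean absolute per-step movement angle), meandering
(total absolute turning per unit distance), activity budget (resting /
intermediate / fast time from per-frame step thresholds), centrality
(proximity-event count), and time in a region of interest.

Group measures per frame: polarization p = |Σ u_j| / i and angular momentum
r = |Σ u_j × d_j| / i, with u_j the unit heading of individual j, d_j the
unit vector from the group center of mass to j, and i the number of moving
individuals.  Time in the polarized / swarming / milling states follows the
0.65 / 0.35 conventions of the collective-motion literature.

The detection rate discounts frame-steps whose instantaneous speed exceeds
twice the 95th percentile of the pooled group speed (false detections) and
the fraction of frames without a detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .trajectory import TrajectorySet
from .video import Roi

__all__ = [
    "KinematicConfig",
    "GroupFrameState",
    "KinematicReport",
    "steps",
    "tracked_distance",
    "velocities",
    "turning_angle",
    "meandering",
    "activity_times",
    "interactions",
    "network_density",
    "time_in_region",
    "group_state_series",
    "group_times",
    "detection_rate",
    "compute_report",
]


@dataclass
class KinematicConfig:
    """Analysis thresholds and units.

    ``tl``/``th`` are the low/high movement thresholds (distance per frame)
    and ``ti`` the interaction distance, all in the unit selected by
    ``threshold_unit`` ("cm" converts via the trajectory scale, "px" is raw).
    """

    tl: float = 0.0
    th: float = np.inf
    ti: float = 0.0
    roi: Optional[Roi] = None
    threshold_unit: str = "px"

    def __post_init__(self):
        if not 0 <= self.tl <= self.th:
            raise ValueError("need 0 <= tl <= th")
        if self.ti < 0:
            raise ValueError("ti must be >= 0")
        if self.threshold_unit not in ("px", "cm"):
            raise ValueError("threshold_unit must be 'px' or 'cm'")

    def to_px(self, value: float, scale: float) -> float:
        return value / scale if self.threshold_unit == "cm" else value


@dataclass(frozen=True)
class GroupFrameState:
    """Polarization and angular momentum of the group at one frame."""

    frame_index: int
    p: float
    r: float


def steps(traj: np.ndarray) -> np.ndarray:
    """Per-frame displacement vectors; NaN rows where either endpoint is a gap."""
    traj = np.asarray(traj, dtype=float)
    if traj.ndim != 2 or traj.shape[1] != 2:
        raise ValueError("trajectory must have shape (frames, 2)")
    if len(traj) < 2:
        raise ValueError("need at least 2 positions")
    return np.diff(traj, axis=0)


def _valid_steps(traj: np.ndarray) -> np.ndarray:
    d = steps(traj)
    return d[~np.isnan(d).any(axis=1)]


def tracked_distance(traj: np.ndarray, scale: float = 1.0) -> float:
    """Cumulative Euclidean path length; gaps contribute no step."""
    traj = np.asarray(traj, dtype=float)
    if np.isnan(traj).any(axis=1).all():
        return float("nan")  # never detected: undefined
    d = _valid_steps(traj)
    return float(np.linalg.norm(d, axis=1).sum() * scale)


def velocities(traj: np.ndarray, fps: float, scale: float = 1.0) -> tuple[float, float]:
    """(mean, max) velocity: tracked distance over duration, largest step × fps."""
    if fps <= 0 or len(traj) < 2:
        raise ValueError("need fps > 0 and at least 2 positions")
    td = tracked_distance(traj, scale)
    duration = len(traj) / fps
    d = _valid_steps(traj)
    vmax = float(np.linalg.norm(d, axis=1).max() * scale * fps) if len(d) else float("nan")
    return td / duration, vmax


def _step_angles_deg(traj: np.ndarray) -> np.ndarray:
    """Absolute movement angle per step, degrees in [0, 90].

    |arctan(Δy/Δx)| folded by the two-argument arctangent so vertical steps
    (Δx = 0) are finite (90°).  Zero-length steps contribute 0°.
    """
    d = _valid_steps(traj)
    if len(d) == 0:
        return np.zeros(0)
    ang = np.degrees(np.arctan2(np.abs(d[:, 1]), np.abs(d[:, 0])))
    ang[(d == 0).all(axis=1)] = 0.0
    return ang


def turning_angle(traj: np.ndarray) -> float:
    """Mean absolute movement angle over displacement steps, degrees."""
    ang = _step_angles_deg(traj)
    if len(ang) == 0:
        return float("nan")
    return float(ang.mean())


def meandering(traj: np.ndarray, scale: float = 1.0) -> float:
    """Summed absolute movement angle divided by tracked distance (deg/length)."""
    td = tracked_distance(traj, scale)
    if not np.isfinite(td) or td == 0:
        return float("nan")
    return float(_step_angles_deg(traj).sum() / td)


def activity_times(traj: np.ndarray, tl: float, th: float, fps: float,
                   scale: float = 1.0) -> tuple[float, float, float]:
    """(resting, mean-movement, fast-movement) time in seconds.

    Each per-frame step ``mf`` (scaled units/frame) is classed as resting
    (mf ≤ tl), intermediate (tl < mf ≤ th), or fast (mf > th); class counts
    divide by fps.
    """
    if not 0 <= tl <= th:
        raise ValueError("need 0 <= tl <= th")
    d = _valid_steps(traj)
    mf = np.linalg.norm(d, axis=1) * scale
    resting = int((mf <= tl).sum())
    mean_mv = int(((mf > tl) & (mf <= th)).sum())
    fast = int((mf > th).sum())
    return resting / fps, mean_mv / fps, fast / fps


def interactions(trajset: TrajectorySet, ti: float) -> tuple[list[list[tuple[int, int]]], np.ndarray]:
    """Proximity events: pairs within ``ti`` per frame, and centrality per individual.

    A pair (j, k) interacts in a frame when their centroid distance (pixels)
    is ≤ ti (pixels).  Centrality of j is the total number of frame-pair
    events involving j.
    """
    if trajset.n_individuals < 2:
        raise ValueError("interactions need at least 2 individuals")
    n = trajset.n_individuals
    centrality = np.zeros(n, dtype=int)
    per_frame: list[list[tuple[int, int]]] = []
    for f in range(trajset.n_frames):
        pts = trajset.xy[f]
        pairs: list[tuple[int, int]] = []
        for j in range(n):
            for k in range(j + 1, n):
                if np.isnan(pts[[j, k]]).any():
                    continue
                if np.linalg.norm(pts[j] - pts[k]) <= ti:
                    pairs.append((j, k))
                    centrality[j] += 1
                    centrality[k] += 1
        per_frame.append(pairs)
    return per_frame, centrality


def network_density(trajset: TrajectorySet, ti: float) -> float:
    """Interaction-network density 2m / (n(n−1)).

    Nodes are individuals; an edge joins each pair that interacted in at
    least one frame.
    """
    n = trajset.n_individuals
    if n < 2:
        raise ValueError("network density needs n >= 2")
    per_frame, _ = interactions(trajset, ti)
    edges = {pair for pairs in per_frame for pair in pairs}
    return 2 * len(edges) / (n * (n - 1))


def time_in_region(traj: np.ndarray, ri: Roi, fps: float) -> float:
    """Seconds spent inside the region of interest."""
    traj = np.asarray(traj, dtype=float)
    ok = ~np.isnan(traj).any(axis=1)
    if not ok.any():
        return 0.0
    inside = ri.contains(traj[ok, 0], traj[ok, 1])
    return float(np.count_nonzero(inside) / fps)


def group_state_series(trajset: TrajectorySet) -> list[GroupFrameState]:
    """Polarization p and angular momentum r per frame.

    Headings come from the displacement into each frame; individuals with a
    gap or zero displacement are excluded and the divisor i reduced.  Frames
    with no moving individual yield NaN (excluded from state-time counts).
    The center of mass is taken over the included individuals.
    """
    if trajset.n_individuals < 2:
        raise ValueError("group states need at least 2 individuals")
    out: list[GroupFrameState] = []
    xy = trajset.xy
    for f in range(1, trajset.n_frames):
        disp = xy[f] - xy[f - 1]
        ok = ~np.isnan(disp).any(axis=1)
        norms = np.linalg.norm(disp, axis=1)
        ok &= norms > 0
        i = int(ok.sum())
        if i == 0:
            out.append(GroupFrameState(f, float("nan"), float("nan")))
            continue
        u = disp[ok] / norms[ok, None]
        p = float(np.linalg.norm(u.sum(axis=0)) / i)
        com = xy[f][ok].mean(axis=0)
        rad = xy[f][ok] - com
        rnorm = np.linalg.norm(rad, axis=1)
        nz = rnorm > 0
        d = np.zeros_like(rad)
        d[nz] = rad[nz] / rnorm[nz, None]
        cross = u[:, 0] * d[:, 1] - u[:, 1] * d[:, 0]
        r = float(abs(cross.sum()) / i)
        out.append(GroupFrameState(f, p, r))
    return out


def group_times(states: list[GroupFrameState], fps: float) -> tuple[float, float, float]:
    """(polarized, swarming, milling) time in seconds.

    Polarized: p > 0.65 and r < 0.35; swarming: p < 0.35 and r < 0.35;
    milling: p < 0.35 and r > 0.65.
    """
    gp = gs = gm = 0
    for s in states:
        if np.isnan(s.p) or np.isnan(s.r):
            continue
        if s.p > 0.65 and s.r < 0.35:
            gp += 1
        elif s.p < 0.35 and s.r < 0.35:
            gs += 1
        elif s.p < 0.35 and s.r > 0.65:
            gm += 1
    return gp / fps, gs / fps, gm / fps


def detection_rate(trajset: TrajectorySet) -> float:
    """Fraction of the video with valid detections, discounting speed outliers.

    A frame-step is a false detection when its instantaneous speed exceeds
    twice the 95th percentile of the pooled instantaneous speeds of the whole
    group.  The rate is (1 − outliers/steps) scaled by the detected fraction,
    clamped to [0, 1].
    """
    if trajset.n_frames < 2:
        raise ValueError("detection rate needs at least 2 frames")
    speeds = []
    for j in range(trajset.n_individuals):
        d = steps(trajset.individual(j))
        s = np.linalg.norm(d, axis=1)
        speeds.append(s[~np.isnan(s)])
    pooled = np.concatenate(speeds) if speeds else np.zeros(0)
    detected = trajset.detected_fraction()
    if len(pooled) == 0:
        return 0.0
    p95 = np.percentile(pooled, 95)
    n_false = int((pooled > 2 * p95).sum())
    dr = (1.0 - n_false / len(pooled)) * detected
    return float(min(1.0, max(0.0, dr)))


@dataclass
class KinematicReport:
    """All per-individual, per-group, and per-video statistics of one run."""

    individuals: pd.DataFrame       # one row per identity
    network_density: float
    group_polarized_time: float
    group_swarming_time: float
    group_milling_time: float
    detection_rate: float
    fps: float
    scale: float

    def to_csv(self, path) -> None:
        df = self.individuals.copy()
        group = pd.DataFrame([{ "id": "group",
                                "network_density": self.network_density,
                                "group_polarized_time_s": self.group_polarized_time,
                                "group_swarming_time_s": self.group_swarming_time,
                                "group_milling_time_s": self.group_milling_time,
                                "detection_rate": self.detection_rate }])
        pd.concat([df, group], ignore_index=True).to_csv(path, index=False, na_rep="")


def compute_report(trajset: TrajectorySet, cfg: KinematicConfig) -> KinematicReport:
    """Compute the full statistics table for a tracked video."""
    scale = trajset.scale
    fps = trajset.fps
    tl = cfg.to_px(cfg.tl, scale) * scale
    th = cfg.to_px(cfg.th, scale) * scale
    ti_px = cfg.to_px(cfg.ti, scale)

    rows = []
    n = trajset.n_individuals
    if n >= 2:
        _, centrality = interactions(trajset, ti_px)
        nd = network_density(trajset, ti_px)
        states = group_state_series(trajset)
        gp, gs, gm = group_times(states, fps)
    else:
        centrality = np.zeros(n, dtype=int)
        nd, gp, gs, gm = float("nan"), float("nan"), float("nan"), float("nan")
    for j in range(n):
        traj = trajset.individual(j)
        td = tracked_distance(traj, scale)
        vmean, vmax = velocities(traj, fps, scale)
        rest, mid, fast = activity_times(traj, tl, th, fps, scale)
        row = {
            "id": j + 1,
            "tracked_distance": td,
            "mean_velocity": vmean,
            "max_velocity": vmax,
            "turning_angle_deg": turning_angle(traj),
            "meandering_deg_per_unit": meandering(traj, scale),
            "resting_time_s": rest,
            "mean_movement_time_s": mid,
            "fast_movement_time_s": fast,
            "centrality": int(centrality[j]),
            "region_time_s": time_in_region(traj, cfg.roi, fps) if cfg.roi else float("nan"),
        }
        rows.append(row)
    return KinematicReport(
        individuals=pd.DataFrame(rows),
        network_density=nd,
        group_polarized_time=gp,
        group_swarming_time=gs,
        group_milling_time=gm,
        detection_rate=detection_rate(trajset),
        fps=fps,
        scale=scale,
    )
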