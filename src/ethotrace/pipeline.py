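"""End-to-end orchestration: video in, coordinate and statistics CSVs out."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .config import RunConfig
from .kinematics import KinematicReport, compute_report
from .trajectory import TrajectorySet
from .video import open_stream

log = logging.getLogger(__name__)

__all__ = ["OutputBundle", "run_tracking", "write_outputs"]


@dataclass
class OutputBundle:
    """Files produced by one run; raw coordinates are always written."""

    coordinates_csv: Path
    report_csv: Path | None
    trajectories: TrajectorySet
    report: KinematicReport | None
    detection_rate: float | None


def write_outputs(trajset: TrajectorySet, report: KinematicReport | None,
                  out_dir: str | Path, stem: str = "run") -> tuple[Path, Path | None]:
    """Write the coordinate CSV (frame,id,x,y; gaps empty) and the report CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    coords = out_dir / f"{stem}_coordinates.csv"
    trajset.to_csv(coords)
    report_path = None
    if report is not None:
        report_path = out_dir / f"{stem}_kinematics.csv"
        report.to_csv(report_path)
    return coords, report_path


def run_tracking(config: RunConfig) -> OutputBundle:
    """Track a video and write the output bundle.

    On a statistics failure the raw coordinates are still written and the
    error is logged with its stage; the detection rate is reported at the
    end of a successful run.
    """
    from .track import track

    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    tcfg = config.tracker_config()
    log.info("segmentation mode=%s invert=%s median_kernel=%d cleanup=%s seed=%d",
             config.mode, config.invert, config.median_kernel, config.cleanup, config.seed)
    stream = open_stream(config.video)
    trajset = track(stream, tcfg)
    trajset.scale = config.scale
    stem = Path(config.video).stem
    report = None
    dr = None
    try:
        kcfg = config.kinematics.build(roi=config.roi.build() if config.roi else None)
        report = compute_report(trajset, kcfg)
        dr = report.detection_rate
    except Exception:
        log.exception("stage=kinematics failed; raw coordinates retained")
    coords, report_path = write_outputs(trajset, report, config.output_dir, stem)
    if dr is not None:
        log.info("detection rate: %.4f", dr)
    return OutputBundle(coordinates_csv=coords, report_csv=report_path,
                        trajectories=trajset, report=report, detection_rate=dr)
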