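"""Format readers and writers binding the pipeline to disk.

Everything is plain text: CSV for signals and tables, JSON for summaries
and sidecars, PNG stacks for masks (handled in :mod:`ratresp.synthetic`).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .evaluation import RecordingComparison, StudySummary, round_half_even
from .rr_estimation import RRSeries
from .segmentation import IoUReport
from .signal_extraction import TimeSeries

__all__ = [
    "write_timeseries_csv", "read_timeseries_csv", "write_rr_csv",
    "write_summary_json", "write_spectrum_csv", "write_iou_report_csv",
    "write_comparison_csv", "write_study_summary_json", "iter_frames",
]


def write_timeseries_csv(path: str | Path, ts: TimeSeries) -> None:
    pd.DataFrame({"sample_index": np.arange(len(ts)),
                  "time_s": ts.times,
                  "value": ts.values}).to_csv(path, index=False)


def read_timeseries_csv(path: str | Path) -> TimeSeries:
    df = pd.read_csv(path)
    if len(df) < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = np.diff(df["time_s"].to_numpy()).mean()
    return TimeSeries(df["value"].to_numpy(), 1.0 / dt)


def write_rr_csv(path: str | Path, rr: RRSeries) -> None:
    pd.DataFrame({"time_s": rr.times,
                  "rr_breaths_per_min": rr.values}).to_csv(path, index=False)


def write_summary_json(path: str | Path, mean_rr: float, n_breaths: int,
                       coverage_fraction: float) -> None:
    Path(path).write_text(json.dumps({
        "mean_rr": None if np.isnan(mean_rr) else mean_rr,
        "n_breaths": n_breaths,
        "coverage_fraction": coverage_fraction,
    }, indent=2))


def write_spectrum_csv(path: str | Path, freq_bpm: np.ndarray,
                       power: np.ndarray) -> None:
    pd.DataFrame({"breaths_per_min": freq_bpm,
                  "power": power}).to_csv(path, index=False)


def write_iou_report_csv(path: str | Path, report: IoUReport) -> None:
    """Per-group IoU table (Rat ID, N, IoU Box, IoU Mask) plus overall row."""
    rows = []
    for i, lab in enumerate(report.group_labels):
        rows.append({
            "rat_id": lab, "n": int(report.group_ns[i]),
            "iou_box_mean": report.box_means[i],
            "iou_box_sd": report.box_sds[i],
            "iou_mask_mean": report.mask_means[i],
            "iou_mask_sd": report.mask_sds[i],
        })
    rows.append({"rat_id": "overall", "n": int(report.group_ns.sum()),
                 "iou_box_mean": report.overall_box, "iou_box_sd": "",
                 "iou_mask_mean": report.overall_mask, "iou_mask_sd": ""})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_comparison_csv(path: str | Path,
                         rows: list[RecordingComparison]) -> None:
    """Per-recording comparison table, values rounded half-even at 2 dp."""
    pd.DataFrame([{
        "day": r.day, "mt": r.mt, "rat_id": r.rat_id,
        "mean_edr_bpm": round_half_even(r.mean_edr),
        "mean_cam_bpm": round_half_even(r.mean_cam),
        "rel_error_pct": round_half_even(r.rel_error),
        "abs_error_bpm": round_half_even(r.abs_error),
    } for r in rows]).to_csv(path, index=False)


def write_study_summary_json(path: str | Path, s: StudySummary) -> None:
    Path(path).write_text(json.dumps({
        "n_recordings": s.n_recordings,
        "mean_edr_overall": s.mean_edr_overall,
        "mean_cam_overall": s.mean_cam_overall,
        "mean_rel_error_pct": s.mean_rel_error,
        "mean_abs_error_bpm": s.mean_abs_error,
        "edr_min": s.edr_min, "edr_max": s.edr_max, "edr_sd": s.edr_sd,
    }, indent=2))


def iter_frames(source: str | Path, fps: float | None = None,
                ) -> tuple[Iterator[np.ndarray], float, int | None]:
    """Yield intensity frames from a video file or an image directory.

    Returns (iterator, fps, n_frames_or_None). Image directories require
    an explicit fps (no guessing); video files take it from metadata.
    """
    import imageio.v3 as iio

    source = Path(source)
    if source.is_dir():
        frames = sorted(p for p in source.iterdir()
                        if p.suffix.lower() in (".png", ".tif", ".tiff",
                                                ".jpg", ".jpeg"))
        if not frames:
            raise ValueError(f"no image frames found in {source}")
        if fps is None:
            raise ValueError("fps is required for image directories "
                             "(pass --fps)")
        return (iio.imread(p) for p in frames), fps, len(frames)
    if not source.exists():
        raise ValueError(f"input {source} does not exist")
    try:
        meta = iio.immeta(source)
        video_fps = fps or meta.get("fps")
    except Exception as exc:
        raise ValueError(
            f"cannot read video {source}: {exc}; supply a directory of "
            f"PNG frames plus --fps instead") from exc
    if not video_fps:
        raise ValueError(f"{source}: fps missing from metadata; pass --fps")
    return iio.imiter(source), float(video_fps), None
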