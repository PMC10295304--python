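"""Published reference measurements from the telemetry-validated rat study.

Two summary tables from the original three-rat experiment (five days, up
to four measurement times per day, ECG transponder reference) ship with
the package so its evaluation arithmetic can be exercised and checked
against the published numbers without access to the raw videos:

* ``EDR_CAMERA_ROWS`` — per-recording mean ECG-derived respiratory rate
  and mean camera respiratory rate (breaths/min), together with the
  relative (%) and absolute (breaths/min) errors as printed.
* ``IOU_ROWS`` — per-rat segmentation quality on held-out animals:
  image count, bounding-box IoU and mask IoU (mean ± SD, %), and the
  segmentation network's mean certainty score (%).
"""

from __future__ import annotations

from .evaluation import RecordingComparison, compare_recording

__all__ = ["EDR_CAMERA_ROWS", "IOU_ROWS", "reference_comparisons"]

# (day, measurement time, rat, mean EDR, mean camera RR,
#  printed relative error %, printed absolute error)
EDR_CAMERA_ROWS: list[tuple[str, str, str, float, float, float, float]] = [
    ("Day 2", "MT3", "R1", 96.28, 99.56, 3.41, 3.28),
    ("Day 2", "MT3", "R2", 79.08, 98.63, 24.72, 19.55),
    ("Day 2", "MT3", "R3", 91.34, 103.23, 13.02, 11.89),
    ("Day 2", "MT4", "R1", 94.05, 80.29, 14.63, 13.76),
    ("Day 2", "MT4", "R2", 85.55, 97.73, 14.24, 12.18),
    ("Day 2", "MT4", "R3", 94.97, 96.83, 1.96, 1.86),
    ("Day 3", "MT1", "R1", 94.61, 92.88, 1.83, 1.73),
    ("Day 3", "MT1", "R2", 90.69, 82.72, 8.79, 7.97),
    ("Day 3", "MT1", "R3", 89.70, 91.45, 1.95, 1.75),
    ("Day 3", "MT2", "R1", 96.28, 91.64, 4.82, 4.64),
    ("Day 3", "MT2", "R2", 93.45, 90.37, 3.30, 3.08),
    ("Day 3", "MT2", "R3", 89.27, 87.77, 1.68, 1.50),
    ("Day 3", "MT3", "R1", 98.73, 99.01, 0.28, 0.28),
    ("Day 3", "MT3", "R2", 96.32, 103.90, 7.87, 7.58),
    ("Day 3", "MT3", "R3", 90.27, 91.15, 0.97, 0.88),
    ("Day 3", "MT4", "R1", 98.87, 89.18, 9.80, 9.69),
    ("Day 3", "MT4", "R2", 92.41, 88.86, 3.84, 3.55),
    ("Day 3", "MT4", "R3", 90.60, 95.97, 5.93, 5.37),
    ("Day 4", "MT1", "R1", 97.40, 90.03, 7.57, 7.37),
    ("Day 4", "MT1", "R2", 89.80, 87.75, 2.33, 2.09),
    ("Day 4", "MT1", "R3", 90.34, 98.22, 8.72, 7.88),
    ("Day 4", "MT2", "R1", 92.79, 92.75, 0.04, 0.04),
    ("Day 4", "MT2", "R2", 92.74, 91.49, 1.35, 1.25),
    ("Day 4", "MT2", "R3", 90.55, 92.68, 2.35, 2.13),
    ("Day 4", "MT3", "R1", 97.29, 97.04, 0.26, 0.25),
    ("Day 4", "MT3", "R2", 84.80, 93.48, 10.24, 8.68),
    ("Day 4", "MT3", "R3", 91.48, 97.03, 6.07, 5.55),
    ("Day 4", "MT4", "R1", 89.24, 88.32, 1.03, 0.92),
    ("Day 4", "MT4", "R2", 89.74, 87.41, 2.60, 2.33),
    ("Day 4", "MT4", "R3", 87.79, 93.49, 6.49, 5.70),
    ("Day 5", "MT1", "R1", 98.03, 93.67, 4.45, 4.36),
    ("Day 5", "MT1", "R2", 93.69, 86.25, 7.94, 7.44),
    ("Day 5", "MT1", "R3", 93.89, 98.20, 4.59, 4.31),
    ("Day 5", "MT2", "R1", 93.86, 91.41, 2.61, 2.45),
    ("Day 5", "MT2", "R2", 85.30, 86.09, 0.93, 0.79),
    ("Day 5", "MT2", "R3", 93.95, 89.95, 4.26, 4.00),
]

# (rat, n images, box IoU mean, box IoU SD, mask IoU mean, mask IoU SD,
#  certainty mean, certainty SD) — all percentages
IOU_ROWS: list[tuple[str, int, float, float, float, float, float, float]] = [
    ("R1", 637, 82.27, 7.73, 86.86, 6.18, 99.84, 0.40),
    ("R2", 654, 82.85, 6.01, 88.28, 4.61, 99.90, 0.26),
    ("R3", 659, 82.42, 6.37, 88.09, 4.39, 99.80, 1.69),
]


def reference_comparisons() -> list[RecordingComparison]:
    """Recompute every reference row's errors from its two printed means."""
    return [compare_recording(edr, cam, day=d, mt=mt, rat_id=r)
            for d, mt, r, edr, cam, _, _ in EDR_CAMERA_ROWS]
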