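"""Camera-vs-reference error arithmetic and study-level summaries.

Each recording contributes one mean EDR rate and one mean camera rate;
the per-recording relative error is 100 * |cam - edr| / edr and the
absolute error |cam - edr|, both in breaths/min terms. Study summaries
are unweighted arithmetic means over recordings, with the min/max/SD of
the reference column alongside. All arithmetic is carried at full
precision; rounding (2 decimals, half-even) happens only at presentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["RecordingComparison", "StudySummary", "compare_recording",
           "summarize_study", "round_half_even"]


def round_half_even(x: float, ndigits: int = 2) -> float:
    """Banker's rounding used for all printed values."""
    return round(float(x), ndigits)


@dataclass
class RecordingComparison:
    """One recording's camera-vs-reference row."""

    day: str
    mt: str
    rat_id: str
    mean_edr: float      # breaths/min
    mean_cam: float      # breaths/min
    rel_error: float     # %
    abs_error: float     # breaths/min


@dataclass
class StudySummary:
    """Unweighted means over recordings plus reference-column spread."""

    n_recordings: int
    mean_edr_overall: float
    mean_cam_overall: float
    mean_rel_error: float
    mean_abs_error: float
    edr_min: float
    edr_max: float
    edr_sd: float        # sample SD (n-1) of the per-recording EDR means


def compare_recording(mean_edr: float, mean_cam: float,
                      day: str = "", mt: str = "",
                      rat_id: str = "") -> RecordingComparison:
    """Relative and absolute error of one recording against its reference."""
    if mean_edr <= 0:
        raise ValueError("reference mean must be positive")
    abs_error = abs(mean_cam - mean_edr)
    rel_error = 100.0 * abs_error / mean_edr
    return RecordingComparison(day, mt, rat_id, mean_edr, mean_cam,
                               rel_error, abs_error)


def summarize_study(rows: Iterable[RecordingComparison]) -> StudySummary:
    """Arithmetic means over recordings; order-independent."""
    rows = list(rows)
    if not rows:
        raise ValueError("no recordings to summarize")
    edr = np.array([r.mean_edr for r in rows])
    cam = np.array([r.mean_cam for r in rows])
    rel = np.array([r.rel_error for r in rows])
    ab = np.array([r.abs_error for r in rows])
    return StudySummary(
        n_recordings=len(rows),
        mean_edr_overall=float(edr.mean()),
        mean_cam_overall=float(cam.mean()),
        mean_rel_error=float(rel.mean()),
        mean_abs_error=float(ab.mean()),
        edr_min=float(edr.min()),
        edr_max=float(edr.max()),
        edr_sd=float(edr.std(ddof=1)) if len(rows) > 1 else 0.0,
    )
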