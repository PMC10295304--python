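"""From gated masks to a conditioned respiration signal.

The raw respiration signal R is the segmented area per frame: the rat's
thorax/abdomen expands and contracts with each breath, so the projected
region area oscillates at the respiratory frequency. Animal locomotion
corrupts R through imperfect tracking; the center-of-mass trajectory and
its derivatives span that nuisance motion, and projecting R onto the
orthogonal complement of this noise subspace (Z = R - Q (QtQ)^+ Qt R)
removes the motion-correlated component. Z is then band-passed to the
physiological band (1-3.3 Hz ~ 60-200 breaths/min) and despiked by
gradient clipping with interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .segmentation import MaskSequence

__all__ = [
    "TimeSeries", "RegionTrack", "NoiseRegressorSet",
    "track_region", "fill_gaps", "align_to_com", "area_signal",
    "build_noise_subspace", "denoise_projection", "bandpass_respiration",
    "clip_gradient", "standardize",
]


@dataclass
class TimeSeries:
    """Uniformly sampled scalar signal."""

    values: np.ndarray
    rate_hz: float
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.rate_hz

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.rate_hz


@dataclass
class RegionTrack:
    """Per-frame geometry of the segmented region.

    Invalid frames carry area 0 and NaN centroid; ``area[i] > 0`` iff
    ``valid[i]``. Bounding boxes are half-open (r0, c0, r1, c1).
    """

    area: np.ndarray
    com_x: np.ndarray
    com_y: np.ndarray
    bbox: np.ndarray
    valid: np.ndarray
    fps: float

    def __len__(self) -> int:
        return len(self.area)


@dataclass
class NoiseRegressorSet:
    """Noise channels Q, sample-aligned with R, each linearly detrended."""

    columns: np.ndarray        # (n, k)
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.columns = np.atleast_2d(np.asarray(self.columns, float))
        if not self.labels:
            self.labels = [f"q{i}" for i in range(self.columns.shape[1])]


def _detrend(x: np.ndarray) -> np.ndarray:
    """Subtract the least-squares line (zero best-fit slope and intercept)."""
    n = len(x)
    if n < 2:
        return x - x.mean() if n else x
    t = np.arange(n, dtype=float)
    slope, intercept = np.polyfit(t, x, 1)
    return x - (slope * t + intercept)


def track_region(seq: MaskSequence) -> RegionTrack:
    """Centroid, pixel area and tight bounding box for each valid frame."""
    n = len(seq)
    area = np.zeros(n)
    com_x = np.full(n, np.nan)
    com_y = np.full(n, np.nan)
    bbox = np.zeros((n, 4), dtype=int)
    valid = seq.valid.copy()
    if not valid.any():
        raise ValueError("all frames invalid; nothing to track")
    for i in np.flatnonzero(valid):
        m = seq.masks[i]
        a = np.count_nonzero(m)
        rows = np.flatnonzero(m.any(axis=1))
        cols = np.flatnonzero(m.any(axis=0))
        cy, cx = ndimage.center_of_mass(m)
        area[i] = a
        com_x[i], com_y[i] = cx, cy
        bbox[i] = (rows[0], cols[0], rows[-1] + 1, cols[-1] + 1)
    return RegionTrack(area, com_x, com_y, bbox, valid, seq.fps)


def fill_gaps(track: RegionTrack, max_gap_s: float = 0.5,
              ) -> list[RegionTrack]:
    """Interpolate short invalid runs; split at long ones.

    Runs of invalid frames up to ``max_gap_s * fps`` frames are bridged by
    linear interpolation of area and centroid. Longer runs (and invalid
    edges, which have only one neighbor) split the recording into
    independent, fully valid analysis segments.
    """
    max_gap = int(round(max_gap_s * track.fps))
    valid = track.valid
    n = len(valid)
    if not valid.any():
        return []
    # fill short interior gaps
    area = track.area.copy()
    com_x = track.com_x.copy()
    com_y = track.com_y.copy()
    filled = valid.copy()
    i = 0
    while i < n:
        if filled[i]:
            i += 1
            continue
        j = i
        while j < n and not filled[j]:
            j += 1
        run = j - i
        if 0 < i and j < n and run <= max_gap:
            w = (np.arange(1, run + 1)) / (run + 1)
            for arr in (area, com_x, com_y):
                arr[i:j] = arr[i - 1] + w * (arr[j] - arr[i - 1])
            filled[i:j] = True
        i = j
    # split into maximal filled runs
    segments: list[RegionTrack] = []
    i = 0
    while i < n:
        if not filled[i]:
            i += 1
            continue
        j = i
        while j < n and filled[j]:
            j += 1
        sl = slice(i, j)
        segments.append(RegionTrack(
            area[sl], com_x[sl], com_y[sl], track.bbox[sl].copy(),
            np.ones(j - i, dtype=bool), track.fps))
        i = j
    return segments


def align_to_com(seq: MaskSequence, track: RegionTrack) -> MaskSequence:
    """Shift every mask so all centers of mass coincide (integer pixels).

    Translation cannot change a mask's pixel count, so the area signal is
    bit-identical before and after; the aligned stack exists for visual QC
    and export only.
    """
    ref_x = np.nanmean(track.com_x[track.valid])
    ref_y = np.nanmean(track.com_y[track.valid])
    out = np.zeros_like(seq.masks)
    for i in range(len(seq)):
        if not track.valid[i]:
            continue
        dy = int(round(ref_y - track.com_y[i]))
        dx = int(round(ref_x - track.com_x[i]))
        out[i] = np.roll(np.roll(seq.masks[i], dy, axis=0), dx, axis=1)
    return MaskSequence(out, seq.scores.copy(), seq.fps, seq.valid.copy())


def area_signal(track: RegionTrack) -> TimeSeries:
    """Raw respiration signal R: segmented area per frame, in pixels."""
    return TimeSeries(track.area, track.fps, units="px^2")


def build_noise_subspace(track: RegionTrack) -> NoiseRegressorSet:
    """Noise regressors Q: detrended COM x/y and their first derivatives.

    Derivatives are first differences with the first sample duplicated
    (length-preserving), then detrended so every column has zero best-fit
    slope and intercept.
    """
    if len(track) < 3:
        raise ValueError("need at least 3 frames to build noise regressors")
    x = _detrend(track.com_x.astype(float))
    y = _detrend(track.com_y.astype(float))
    dx = _detrend(np.diff(x, prepend=x[0]))
    dy = _detrend(np.diff(y, prepend=y[0]))
    return NoiseRegressorSet(np.column_stack([x, y, dx, dy]),
                             ["com_x", "com_y", "d_com_x", "d_com_y"])


def denoise_projection(R: TimeSeries, Q: NoiseRegressorSet) -> TimeSeries:
    """Project R off the noise subspace: Z = R - Q (QtQ)^+ Qt R.

    Uses a pseudoinverse so rank-deficient Q (e.g. a motionless animal,
    all-zero columns) degrades gracefully to Z = R. After projection
    Qt Z = 0 to numerical tolerance, and projecting Z again is a no-op.
    """
    r = np.asarray(R.values, float)
    q = Q.columns
    if q.shape[0] != r.shape[0]:
        raise ValueError("R and Q are not sample-aligned")
    beta = np.linalg.pinv(q.T @ q) @ (q.T @ r)
    z = r - q @ beta
    return TimeSeries(z, R.rate_hz, units=R.units)


def bandpass_respiration(Z: TimeSeries, low_hz: float = 1.0,
                         high_hz: float = 3.3, order: int = 2) -> TimeSeries:
    """Zero-phase Butterworth band-pass onto the respiratory band.

    Second order by default, applied forward-backward (filtfilt) so breath
    peaks keep their timing; DC is removed by construction.
    """
    if Z.rate_hz <= 2 * high_hz:
        raise ValueError("sampling rate below Nyquist for the band")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=Z.rate_hz, output="sos")
    # settled length of the sos cascade, as sosfiltfilt pads it
    ntaps = 3 * (2 * sos.shape[0] + 1)
    if len(Z) <= 3 * ntaps:
        raise ValueError(
            f"series of {len(Z)} samples too short to filter "
            f"(needs > {3 * ntaps})")
    out = signal.sosfiltfilt(sos, Z.values)
    return TimeSeries(out, Z.rate_hz, units=Z.units)


def clip_gradient(series: TimeSeries, limit: float = 1.5) -> TimeSeries:
    """Invalidate samples adjoining a gradient above ``limit``; interpolate.

    Both endpoints of any first difference exceeding the limit are flagged
    and refilled by linear interpolation between the nearest surviving
    neighbors; flagged edges take the nearest surviving value.
    """
    x = series.values.copy()
    d = np.abs(np.diff(x))
    bad = np.zeros(len(x), dtype=bool)
    hit = d > limit
    bad[:-1] |= hit
    bad[1:] |= hit
    if bad.all():
        raise ValueError("gradient limit flags every sample")
    if bad.any():
        good = np.flatnonzero(~bad)
        x[bad] = np.interp(np.flatnonzero(bad), good, x[good])
    return TimeSeries(x, series.rate_hz, units=series.units)


def standardize(series: TimeSeries) -> TimeSeries:
    """Zero-mean, unit-variance copy (scale-free units for clipping)."""
    x = series.values - series.values.mean()
    sd = x.std()
    if sd > 0:
        x = x / sd
    return TimeSeries(x, series.rate_hz, units="sd")
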