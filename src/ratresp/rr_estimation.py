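"""Breath-peak detection and respiratory-rate computation.

Peaks are found with a zero-crossing scheme adapted from electrical
impedance tomography practice: detrend by subtracting the best-fit line,
locate sign changes, take the extreme sample between each pair of
crossings (maximum on positive lobes, minimum on negative), then reject
outlier peaks whose spacing from a neighbor falls below a fraction of the
median inter-peak interval. The instantaneous rate follows from the
inter-crest time d_peak as f_RR = 60 / d_peak breaths/min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_extraction import TimeSeries, _detrend

__all__ = ["BreathPeaks", "RRSeries", "detect_breath_peaks",
           "instantaneous_rr"]


@dataclass
class BreathPeaks:
    """Sample indices of respiration maxima (inhale crests) and minima."""

    maxima: np.ndarray
    minima: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.maxima = np.asarray(self.maxima, dtype=int)
        self.minima = np.asarray(self.minima, dtype=int)

    @property
    def is_empty(self) -> bool:
        return self.maxima.size == 0 and self.minima.size == 0


@dataclass
class RRSeries:
    """Instantaneous respiratory rate per consecutive crest pair.

    ``times`` stamps each value at the midpoint of its interval;
    ``mean_rr`` is NaN when fewer than two crests were available.
    """

    times: np.ndarray          # s
    values: np.ndarray         # breaths/min
    mean_rr: float

    @property
    def is_empty(self) -> bool:
        return self.values.size == 0


def _extrema_between_crossings(x: np.ndarray) -> tuple[list[int], list[int]]:
    """Extreme sample within each constant-sign lobe.

    Lobes are delimited by zero crossings; the partial lobes before the
    first and after the last crossing are included so a recording that
    starts or ends mid-breath still contributes its crest. A signal with
    no crossings at all yields nothing.
    """
    s = np.signbit(x)  # True where x < 0 (zeros count as positive)
    change = np.flatnonzero(s[1:] != s[:-1])  # crossing between i and i+1
    if change.size == 0:
        return [], []
    bounds = np.r_[-1, change, len(x) - 1]
    maxima: list[int] = []
    minima: list[int] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        lo, hi = a + 1, b + 1
        seg = x[lo:hi]
        if seg.size == 0:
            continue
        if not s[lo]:  # positive lobe (rising -> falling crossing)
            maxima.append(lo + int(np.argmax(seg)))
        else:
            minima.append(lo + int(np.argmin(seg)))
    return maxima, minima


def _reject_outliers(idx: np.ndarray, amp: np.ndarray,
                     outlier_frac: float) -> np.ndarray:
    """Drop peaks that sit closer to a neighbor than frac * median interval.

    When an interval is too short, the less extreme of its two endpoint
    peaks is discarded (a spurious double peak rides lower than the true
    crest); intervals and the median are recomputed after each removal.
    """
    idx = list(idx)
    amp = list(amp)
    while len(idx) >= 3:
        ivals = np.diff(idx)
        med = np.median(ivals)
        short = np.flatnonzero(ivals < outlier_frac * med)
        if short.size == 0:
            break
        k = short[0]
        # drop the weaker endpoint of the offending interval
        drop = k if amp[k] < amp[k + 1] else k + 1
        idx.pop(drop)
        amp.pop(drop)
    return np.asarray(idx, dtype=int)


def _interleave(x: np.ndarray, maxima: np.ndarray,
                minima: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Enforce strict max/min alternation after outlier rejection.

    Of any same-kind run, keep the most extreme sample, so survivors pair
    one inhale crest with one exhale trough.
    """
    tagged = [(i, +1) for i in maxima] + [(i, -1) for i in minima]
    tagged.sort()
    kept: list[tuple[int, int]] = []
    for i, kind in tagged:
        if kept and kept[-1][1] == kind:
            j, _ = kept[-1]
            if (kind == +1 and x[i] > x[j]) or (kind == -1 and x[i] < x[j]):
                kept[-1] = (i, kind)
        else:
            kept.append((i, kind))
    maxima = np.asarray([i for i, k in kept if k == +1], dtype=int)
    minima = np.asarray([i for i, k in kept if k == -1], dtype=int)
    return maxima, minima


def detect_breath_peaks(sig: TimeSeries,
                        outlier_frac: float = 0.3) -> BreathPeaks:
    """Zero-crossing breath-peak detection with distance-based outlier
    rejection.

    A signal without zero crossings (after linear detrending) yields an
    empty result rather than an error. The detection is invariant to
    positive rescaling of the signal.
    """
    x = _detrend(np.asarray(sig.values, float))
    scale = max(np.abs(np.asarray(sig.values, float)).max(initial=0.0), 1.0)
    if len(x) == 0 or np.abs(x).max() <= 1e-9 * scale:
        # constant or purely linear input: flat residual, no breaths
        return BreathPeaks(np.empty(0, int), np.empty(0, int), sig.rate_hz)
    maxima, minima = _extrema_between_crossings(x)
    maxima = _reject_outliers(np.asarray(maxima), x[maxima], outlier_frac)
    minima = _reject_outliers(np.asarray(minima), -x[minima], outlier_frac)
    maxima, minima = _interleave(x, maxima, minima)
    return BreathPeaks(maxima, minima, sig.rate_hz)


def instantaneous_rr(peaks: BreathPeaks) -> RRSeries:
    """f_RR = 60 / d_peak for each consecutive crest pair.

    d_peak is the crest spacing in samples divided by the sampling rate;
    each rate is stamped at the midpoint of its interval. The mean rate is
    the arithmetic mean over intervals (NaN when undefined).
    """
    m = peaks.maxima
    if m.size < 2:
        return RRSeries(np.empty(0), np.empty(0), float("nan"))
    d_peak = np.diff(m) / peaks.rate_hz           # s
    values = 60.0 / d_peak                        # breaths/min
    times = (m[:-1] + m[1:]) / 2.0 / peaks.rate_hz
    return RRSeries(times, values, float(values.mean()))
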