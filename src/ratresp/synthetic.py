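"""Ground-truthed synthetic inputs: breathing blobs and modulated rat ECG.

Two generators stand in for the laboratory recordings so every pipeline
stage is testable offline:

* ``generate_breathing_masks`` renders an elliptical "rat" whose rasterized
  area oscillates at the true respiratory rate while its center drifts
  slowly and jumps at programmed artifact times — motion corrupts the
  signal through tracking, not through true thorax size, so artifacts are
  step displacements of the center, never of the area.
* ``generate_rat_ecg`` sums narrow biphasic QRS-like pulses at the cardiac
  interval (rat heart rate about 300-420 bpm) whose R amplitudes are
  modulated at the respiratory frequency, plus 50 Hz powerline pickup and
  white noise. The amplitude modulation is what the ECG-derived-respiration
  branch recovers.

Both are deterministic for a fixed seed and return the exact analytic
truth alongside the rendered data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .segmentation import MaskSequence
from .signal_extraction import TimeSeries

__all__ = [
    "BlobSpec", "BlobTruth", "EcgSpec", "EcgTruth",
    "generate_breathing_masks", "generate_rat_ecg",
    "write_mask_dir", "read_mask_dir", "write_ecg_csv", "read_ecg_csv",
]


# ---------------------------------------------------------------------------
# Breathing blob

@dataclass
class BlobSpec:
    """Parameters of the synthetic breathing-blob recording.

    Defaults emulate a 30 s, 60 fps clip of a resting rat breathing at
    96 breaths/min with a visible area modulation of 5%, slow body drift
    and no artifacts; ``artifact_times`` adds instantaneous center jumps.
    """

    duration_s: float = 30.0
    fps: float = 60.0
    frame_shape: tuple[int, int] = (120, 160)
    rr_true: float = 96.0
    area_mean: float = 2500.0
    area_amplitude_frac: float = 0.05
    drift_amplitude: float = 6.0
    drift_hz: float = 0.2
    artifact_times: tuple[float, ...] = ()
    artifact_shift: float = 10.0
    noise_sd: float = 10.0           # px^2 equivalent on area
    aspect: float = 1.6              # major/minor semi-axis ratio
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 2 * self.rr_true / 60.0:
            raise ValueError("fps below Nyquist for rr_true")
        if not 0 <= self.area_amplitude_frac < 1:
            raise ValueError("area_amplitude_frac must be in [0, 1)")
        if self.duration_s <= 0 or self.area_mean <= 0:
            raise ValueError("duration_s and area_mean must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass
class BlobTruth:
    """Exact analytic per-frame area and center, plus the true rate."""

    area: np.ndarray       # noiseless analytic area, px^2
    center_x: np.ndarray   # column coordinate of the ellipse center
    center_y: np.ndarray   # row coordinate
    rr_true: float
    fps: float


def _ellipse_mask(shape: tuple[int, int], cx: float, cy: float,
                  a: float, b: float) -> np.ndarray:
    """Pixel centers inside ((x-cx)/a)^2 + ((y-cy)/b)^2 <= 1."""
    rows, cols = shape
    y = (np.arange(rows) + 0.5 - cy)[:, None] / b
    x = (np.arange(cols) + 0.5 - cx)[None, :] / a
    return x * x + y * y <= 1.0


def generate_breathing_masks(spec: BlobSpec,
                             ) -> tuple[MaskSequence, BlobTruth]:
    """Render the breathing ellipse and return masks plus analytic truth.

    The semi-axes scale with the instantaneous analytic area
    ``area_mean * (1 + frac * sin(2 pi (rr/60) t))`` at fixed aspect ratio;
    area noise jitters both semi-axes jointly so masks stay valid
    ellipses. Raises if the ellipse would leave the frame, naming the
    first offending frame.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    t = np.arange(n) / spec.fps
    f_resp = spec.rr_true / 60.0

    area_true = spec.area_mean * (
        1.0 + spec.area_amplitude_frac * np.sin(2 * math.pi * f_resp * t))

    rows, cols = spec.frame_shape
    cx0, cy0 = cols / 2.0, rows / 2.0
    phase_x, phase_y = rng.uniform(0, 2 * math.pi, size=2)
    cx = cx0 + spec.drift_amplitude * np.sin(
        2 * math.pi * spec.drift_hz * t + phase_x)
    cy = cy0 + spec.drift_amplitude * np.sin(
        2 * math.pi * spec.drift_hz * t + phase_y)
    for at in spec.artifact_times:
        theta = rng.uniform(0, 2 * math.pi)
        step = t >= at
        cx = cx + spec.artifact_shift * math.cos(theta) * step
        cy = cy + spec.artifact_shift * math.sin(theta) * step

    area_noisy = area_true + rng.normal(0.0, spec.noise_sd, size=n) \
        if spec.noise_sd > 0 else area_true
    # joint semi-axis jitter: both axes derive from the same noisy area
    b_axis = np.sqrt(np.maximum(area_noisy, 1.0) / (math.pi * spec.aspect))
    a_axis = spec.aspect * b_axis

    masks = np.zeros((n, rows, cols), dtype=bool)
    for i in range(n):
        if (cx[i] - a_axis[i] < 0 or cx[i] + a_axis[i] > cols
                or cy[i] - b_axis[i] < 0 or cy[i] + b_axis[i] > rows):
            raise ValueError(
                f"ellipse exceeds frame bounds at frame {i} "
                f"(t = {t[i]:.3f} s)")
        masks[i] = _ellipse_mask(spec.frame_shape, cx[i], cy[i],
                                 a_axis[i], b_axis[i])

    seq = MaskSequence(masks, np.ones(n), spec.fps)
    truth = BlobTruth(area_true, cx, cy, spec.rr_true, spec.fps)
    return seq, truth


# ---------------------------------------------------------------------------
# Rat ECG with respiratory amplitude modulation

@dataclass
class EcgSpec:
    """Parameters of the synthetic rat ECG.

    Defaults: 60 s at 500 samples/s, heart rate 360 bpm (rat range is
    roughly 300-420), respiration 96 breaths/min modulating the R-peak
    amplitude by 30%, faint 50 Hz powerline pickup and white noise.
    """

    duration_s: float = 60.0
    rate_hz: float = 500.0
    hr_bpm: float = 360.0
    rr_true: float = 96.0
    am_depth: float = 0.3
    powerline_amp: float = 0.05
    noise_sd: float = 0.02
    qrs_width_s: float = 0.008       # Gaussian sigma of the R wave
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hr_bpm <= self.rr_true:
            raise ValueError("hr_bpm must exceed rr_true")
        if not 0 <= self.am_depth < 1:
            raise ValueError("am_depth must be in [0, 1)")
        if self.rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("rate_hz and duration_s must be positive")


@dataclass
class EcgTruth:
    """Exact pulse centers, their amplitude factors, and the true rate."""

    r_times: np.ndarray        # s, continuous pulse centers
    r_indices: np.ndarray      # nearest sample index per pulse
    r_amplitudes: np.ndarray   # modulation factor at each pulse
    rr_true: float
    hr_bpm: float
    rate_hz: float


def generate_rat_ecg(spec: EcgSpec) -> tuple[TimeSeries, EcgTruth]:
    """Synthesize the amplitude-modulated rat ECG and its truth.

    Each beat is a biphasic QRS-like pulse (narrow Gaussian R wave with a
    shallower trailing S dip); beat k sits at (k + 1/2) * 60/hr_bpm s so
    every pulse lies fully inside the record.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.rate_hz))
    t = np.arange(n) / spec.rate_hz

    beat_period = 60.0 / spec.hr_bpm
    n_beats = int(spec.duration_s / beat_period)
    r_times = (np.arange(n_beats) + 0.5) * beat_period
    f_resp = spec.rr_true / 60.0
    amp = 1.0 + spec.am_depth * np.sin(2 * math.pi * f_resp * r_times)

    sig = np.zeros(n)
    sigma = spec.qrs_width_s
    half = int(round(6 * sigma * spec.rate_hz))
    for tk, ak in zip(r_times, amp):
        k = int(round(tk * spec.rate_hz))
        lo, hi = max(0, k - half), min(n, k + half + 1)
        tt = t[lo:hi] - tk
        pulse = np.exp(-0.5 * (tt / sigma) ** 2) \
            - 0.35 * np.exp(-0.5 * ((tt - 2.2 * sigma) / sigma) ** 2)
        sig[lo:hi] += ak * pulse

    if spec.powerline_amp:
        sig = sig + spec.powerline_amp * np.sin(2 * math.pi * 50.0 * t)
    if spec.noise_sd:
        sig = sig + rng.normal(0.0, spec.noise_sd, size=n)

    truth = EcgTruth(r_times, np.round(r_times * spec.rate_hz).astype(int),
                     amp, spec.rr_true, spec.hr_bpm, spec.rate_hz)
    return TimeSeries(sig, spec.rate_hz, units="a.u."), truth


# ---------------------------------------------------------------------------
# Fixture I/O: numbered PNG directory + JSON sidecar; two-column ECG CSV

def write_mask_dir(path: str | Path, seq: MaskSequence,
                   truth: BlobTruth | None = None) -> None:
    """Write masks as 0/255 PNGs plus a ``sequence.json`` sidecar."""
    import imageio.v3 as iio

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for i, m in enumerate(seq.masks):
        iio.imwrite(path / f"frame_{i:06d}.png",
                    (m.astype(np.uint8) * 255))
    sidecar = {
        "fps": seq.fps,
        "scores": seq.scores.tolist(),
        "kind": "masks",
    }
    if truth is not None:
        sidecar["truth"] = {
            "area": truth.area.tolist(),
            "center_x": truth.center_x.tolist(),
            "center_y": truth.center_y.tolist(),
            "rr_true": truth.rr_true,
            "fps": truth.fps,
        }
    (path / "sequence.json").write_text(json.dumps(sidecar))


def read_mask_dir(path: str | Path) -> tuple[MaskSequence, BlobTruth | None]:
    """Read a numbered PNG mask directory written by :func:`write_mask_dir`."""
    import imageio.v3 as iio

    path = Path(path)
    sidecar_path = path / "sequence.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"no sequence.json sidecar in {path}")
    sidecar = json.loads(sidecar_path.read_text())
    frames = sorted(path.glob("frame_*.png"))
    if not frames:
        raise FileNotFoundError(f"no frame_*.png files in {path}")
    masks = np.stack([np.asarray(iio.imread(f)) > 127 for f in frames])
    seq = MaskSequence(masks, np.asarray(sidecar["scores"], float),
                       float(sidecar["fps"]))
    truth = None
    if "truth" in sidecar:
        tr = sidecar["truth"]
        truth = BlobTruth(np.asarray(tr["area"]), np.asarray(tr["center_x"]),
                          np.asarray(tr["center_y"]), tr["rr_true"],
                          tr["fps"])
    return seq, truth


def write_ecg_csv(path: str | Path, ecg: TimeSeries) -> None:
    """Two-column CSV: time_s, amplitude."""
    import pandas as pd

    pd.DataFrame({"time_s": ecg.times, "amplitude": ecg.values}
                 ).to_csv(path, index=False)


def read_ecg_csv(path: str | Path) -> TimeSeries:
    """Read a (time_s, amplitude) CSV; the rate comes from the time axis."""
    import pandas as pd

    df = pd.read_csv(path)
    if df.shape[1] < 2 or len(df) < 2:
        raise ValueError(f"ECG CSV {path} needs >= 2 rows of (time, value)")
    tcol, vcol = df.columns[:2]
    dt = np.diff(df[tcol].to_numpy())
    if dt.min() <= 0 or not np.allclose(dt, dt.mean(), rtol=1e-3):
        raise ValueError(f"ECG CSV {path} is not uniformly sampled")
    return TimeSeries(df[vcol].to_numpy(), 1.0 / dt.mean(), units="a.u.")
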