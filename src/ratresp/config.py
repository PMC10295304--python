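"""Pipeline configuration.

All tunables of the respiration pipeline live in :class:`PipelineConfig`,
with defaults matching the published processing chain: a 0.99 segmentation
certainty gate, a second-order 1–3.3 Hz Butterworth respiration band
(60–200 breaths/min), a gradient clip limit of 1.5, and the rat-tuned
R-peak detector kernels (smoothwindow 0.05 s, avgwindow 0.1875 s,
min_delay 0.1 s).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml


@dataclass
class PipelineConfig:
    """Every tunable of the camera and ECG branches, with defaults.

    Attributes
    ----------
    score_threshold : float
        Segmentation certainty above which a frame counts as valid.
    band_low_hz, band_high_hz : float
        Respiration band edges (1 Hz = 60 breaths/min, 3.3 Hz = 198–200).
    butter_order : int
        Order of the Butterworth band-pass (applied zero-phase).
    clip_limit : float
        Gradient clip limit, in units of the standardized signal per sample.
    gap_max_s : float
        Longest run of invalid frames bridged by interpolation; longer gaps
        split the recording into independent segments.
    outlier_frac : float
        Breath-peak rejection threshold as a fraction of the median
        inter-peak interval.
    ecg_smoothwindow_s, ecg_avgwindow_s, ecg_min_delay_s, ecg_min_qrs : float
        Rat-tuned QRS detector parameters. ``ecg_min_qrs`` is a fraction of
        the mean candidate-region length (see :mod:`ratresp.ecg_edr`).
    ecg_grad_thresh_weight : float
        Multiplier on the moving-average gradient used as QRS threshold.
    ecg_lowpass_hz : float
        Low-pass cutoff applied on the EDR branch.
    powerline_hz, notch_q : float
        Powerline notch frequency and quality factor.
    edr_rate_hz : float
        Uniform resampling rate of the EDR signal.
    seed : int
        Seed for every stochastic component.
    """

    score_threshold: float = 0.99
    band_low_hz: float = 1.0
    band_high_hz: float = 3.3
    butter_order: int = 2
    clip_limit: float = 1.5
    gap_max_s: float = 0.5
    outlier_frac: float = 0.3
    ecg_smoothwindow_s: float = 0.05
    ecg_avgwindow_s: float = 0.1875
    ecg_min_delay_s: float = 0.1
    ecg_min_qrs: float = 0.1
    ecg_grad_thresh_weight: float = 1.5
    ecg_lowpass_hz: float = 4.0
    powerline_hz: float = 50.0
    notch_q: float = 30.0
    edr_rate_hz: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.band_low_hz < self.band_high_hz:
            raise ValueError("band_low_hz must be below band_high_hz")
        for name in ("ecg_smoothwindow_s", "ecg_avgwindow_s",
                     "ecg_min_delay_s", "gap_max_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    # -- YAML round trip ---------------------------------------------------
    # The file layout groups band/clip/gap keys the way the pipeline docs
    # name them (band.low_hz, clip.limit, gap.max_s); everything else is flat.

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return {
            "band": {"low_hz": d.pop("band_low_hz"),
                     "high_hz": d.pop("band_high_hz")},
            "clip": {"limit": d.pop("clip_limit")},
            "gap": {"max_s": d.pop("gap_max_s")},
            **d,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        flat: dict[str, Any] = {}
        if "band" in d:
            band = d.pop("band")
            flat["band_low_hz"] = band["low_hz"]
            flat["band_high_hz"] = band["high_hz"]
        if "clip" in d:
            flat["clip_limit"] = d.pop("clip")["limit"]
        if "gap" in d:
            flat["gap_max_s"] = d.pop("gap")["max_s"]
        flat.update(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
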