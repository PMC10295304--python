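"""Mask-producing stage: segmenter contract, validity gating, IoU evaluation.

The downstream respiration math only needs, per video frame, a binary mask
of the rat's thorax/abdominal region plus a certainty score in [0, 1].
Any segmenter satisfying that contract can be plugged in; this module ships
a reference intensity-threshold segmenter suitable for synthetic and
high-contrast footage, LabelMe polygon-annotation ingestion, and
intersection-over-union evaluation (mask and bounding-box variants).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "MaskSequence", "AnnotationSet", "IoUReport", "ThresholdConfig",
    "segment_threshold", "segment_frames", "gate_validity",
    "load_labelme", "polygons_to_masks", "rasterize_polygon",
    "iou", "iou_box", "mask_bbox", "aggregate_iou", "weighted_mean",
]

# A segmenter maps one frame to (binary mask, certainty score).
Segmenter = Callable[[np.ndarray], tuple[np.ndarray, float]]


# ---------------------------------------------------------------------------
# Containers

@dataclass
class MaskSequence:
    """Ordered per-frame binary masks with certainty scores.

    ``valid[i]`` is only ever True when ``scores[i]`` cleared the gate
    threshold and mask ``i`` is nonempty.
    """

    masks: np.ndarray          # (n, rows, cols) bool
    scores: np.ndarray         # (n,) float in [0, 1]
    fps: float
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.masks.ndim != 3:
            raise ValueError("masks must be a (n, rows, cols) stack")
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.scores) != len(self.masks):
            raise ValueError("scores and masks length mismatch")
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise ValueError("scores must lie in [0, 1]")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        nonempty = self.masks.any(axis=(1, 2))
        if self.valid is None:
            self.valid = nonempty
        self.valid = np.asarray(self.valid, dtype=bool) & nonempty

    def __len__(self) -> int:
        return len(self.masks)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.masks.shape[1:]


@dataclass
class AnnotationSet:
    """Per-image polygon annotations (LabelMe convention).

    ``polygons[i]`` is the list of (x=col, y=row) vertex arrays for image
    ``image_ids[i]``; ``frame_shape`` is (rows, cols).
    """

    image_ids: list[str]
    polygons: list[list[np.ndarray]]
    frame_shape: tuple[int, int]

    def __post_init__(self) -> None:
        rows, cols = self.frame_shape
        for img, polys in zip(self.image_ids, self.polygons):
            for p in polys:
                p = np.asarray(p, float)
                if p.ndim != 2 or p.shape[1] != 2 or len(p) < 3:
                    raise ValueError(
                        f"{img}: polygon needs >= 3 (x, y) vertices")
                if (p[:, 0] < 0).any() or (p[:, 0] > cols).any() \
                        or (p[:, 1] < 0).any() or (p[:, 1] > rows).any():
                    raise ValueError(f"{img}: vertex outside image bounds")


@dataclass
class IoUReport:
    """Per-group IoU summary with a count-weighted overall mean."""

    group_labels: list[str]
    group_ns: np.ndarray
    mask_means: np.ndarray
    mask_sds: np.ndarray
    box_means: np.ndarray
    box_sds: np.ndarray
    overall_mask: float
    overall_box: float


# ---------------------------------------------------------------------------
# Reference threshold segmenter

@dataclass
class ThresholdConfig:
    threshold: float = 0.5
    polarity: str = "bright"       # "bright": object above threshold
    min_region_area: int = 1


def _to_luminance(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame, dtype=float)
    if frame.ndim == 3:
        frame = frame @ np.array([0.2126, 0.7152, 0.0722])
    if frame.ndim != 2:
        raise ValueError("frame must be single-channel or RGB")
    return frame


def segment_threshold(frame: np.ndarray,
                      config: ThresholdConfig = ThresholdConfig(),
                      ) -> tuple[np.ndarray, float]:
    """Largest connected component past the threshold, holes filled.

    The certainty surrogate is ``1 - spurious_area / foreground_area``:
    1.0 when the foreground is a single blob, approaching 0 when it
    shatters into many components. It is *not* comparable to a neural
    network's softmax confidence.
    """
    lum = _to_luminance(frame)
    if config.polarity == "bright":
        fg = lum > config.threshold
    elif config.polarity == "dark":
        fg = lum < config.threshold
    else:
        raise ValueError("polarity must be 'bright' or 'dark'")
    labels, n = ndimage.label(fg)
    if n == 0:
        return np.zeros(lum.shape, dtype=bool), 0.0
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    keep = np.flatnonzero(sizes >= config.min_region_area) + 1
    if keep.size == 0:
        return np.zeros(lum.shape, dtype=bool), 0.0
    total = float(sizes.sum())
    best = keep[np.argmax(sizes[keep - 1])]
    mask = ndimage.binary_fill_holes(labels == best)
    spurious = total - float(sizes[best - 1])
    score = float(np.clip(1.0 - spurious / total, 0.0, 1.0))
    return mask, score


def segment_frames(frames: Iterable[np.ndarray], fps: float,
                   segmenter: Segmenter | None = None) -> MaskSequence:
    """Apply a segmenter frame-by-frame and collect a MaskSequence."""
    if segmenter is None:
        segmenter = lambda f: segment_threshold(f)  # noqa: E731
    masks, scores = [], []
    for frame in frames:
        m, s = segmenter(frame)
        masks.append(m)
        scores.append(s)
    if not masks:
        raise ValueError("no frames supplied")
    return MaskSequence(np.stack(masks), np.asarray(scores), fps)


def gate_validity(seq: MaskSequence,
                  score_threshold: float = 0.99) -> MaskSequence:
    """Mark frames valid when score > threshold and the mask is nonempty."""
    nonempty = seq.masks.any(axis=(1, 2))
    valid = (seq.scores > score_threshold) & nonempty
    return MaskSequence(seq.masks, seq.scores, seq.fps, valid)


# ---------------------------------------------------------------------------
# LabelMe annotations -> masks

def load_labelme(paths: Sequence[str | Path]) -> AnnotationSet:
    """Read LabelMe JSON files (keys ``shapes[].points``, ``imagePath``,
    ``imageHeight``, ``imageWidth``). All files must share one image size."""
    ids, polys, shape = [], [], None
    for path in paths:
        path = Path(path)
        try:
            doc = json.loads(path.read_text())
            this_shape = (int(doc["imageHeight"]), int(doc["imageWidth"]))
            pts = [np.asarray(s["points"], float) for s in doc["shapes"]]
            image_id = str(doc.get("imagePath", path.stem))
        except (json.JSONDecodeError, KeyError, TypeError) as exc:
            raise ValueError(f"malformed LabelMe JSON: {path}") from exc
        if shape is None:
            shape = this_shape
        elif this_shape != shape:
            raise ValueError(f"{path}: image size differs from first file")
        ids.append(image_id)
        polys.append(pts)
    if shape is None:
        raise ValueError("no annotation files given")
    return AnnotationSet(ids, polys, shape)


def rasterize_polygon(points: np.ndarray,
                      frame_shape: tuple[int, int]) -> np.ndarray:
    """Even-odd rasterization of one polygon at pixel centers.

    Pixel (r, c) covers [r, r+1) x [c, c+1); its center sits at
    (x, y) = (c + 0.5, r + 0.5). A pixel belongs to the mask iff a ray from
    its center crosses the polygon boundary an odd number of times, so
    orientation and self-overlap are handled by parity.
    """
    rows, cols = frame_shape
    verts = np.asarray(points, dtype=float)
    px = np.arange(cols) + 0.5
    py = (np.arange(rows) + 0.5)[:, None]
    inside = np.zeros((rows, cols), dtype=bool)
    x1, y1 = verts[:, 0], verts[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    for i in range(len(verts)):
        if y1[i] == y2[i]:
            continue  # horizontal edge never crosses a horizontal ray
        straddles = (y1[i] <= py) != (y2[i] <= py)
        xint = x1[i] + (py - y1[i]) * (x2[i] - x1[i]) / (y2[i] - y1[i])
        inside ^= straddles & (px < xint)
    return inside


def polygons_to_masks(ann: AnnotationSet,
                      frame_shape: tuple[int, int] | None = None,
                      fps: float = 1.0) -> MaskSequence:
    """Rasterize each image's polygons (union) into a binary mask stack."""
    shape = frame_shape or ann.frame_shape
    masks = []
    for polys in ann.polygons:
        m = np.zeros(shape, dtype=bool)
        for p in polys:
            m |= rasterize_polygon(p, shape)
        masks.append(m)
    return MaskSequence(np.stack(masks), np.ones(len(masks)), fps)


# ---------------------------------------------------------------------------
# IoU evaluation

def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over union of two same-shape binary masks.

    Both-empty is defined as 0 (total detection failure earns no credit).
    """
    a = np.asarray(mask_a, bool)
    b = np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return np.count_nonzero(a & b) / union


def mask_bbox(mask: np.ndarray) -> tuple[int, int, int, int] | None:
    """Tight half-open bounding box (r0, c0, r1, c1), or None if empty."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        return None
    return int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1


def iou_box(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """IoU of the tight axis-aligned bounding boxes of two masks."""
    a = np.asarray(mask_a, bool)
    b = np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    ba, bb = mask_bbox(a), mask_bbox(b)
    if ba is None or bb is None:
        return 0.0
    r0 = max(ba[0], bb[0]); c0 = max(ba[1], bb[1])
    r1 = min(ba[2], bb[2]); c1 = min(ba[3], bb[3])
    inter = max(0, r1 - r0) * max(0, c1 - c0)
    area_a = (ba[2] - ba[0]) * (ba[3] - ba[1])
    area_b = (bb[2] - bb[0]) * (bb[3] - bb[1])
    union = area_a + area_b - inter
    return inter / union if union else 0.0


def weighted_mean(means: Sequence[float], ns: Sequence[int]) -> float:
    """Count-weighted mean of per-group means: sum(n_i m_i) / sum(n_i)."""
    means = np.asarray(means, float)
    ns = np.asarray(ns, float)
    if means.size == 0 or ns.sum() <= 0:
        raise ValueError("need at least one nonempty group")
    return float((means * ns).sum() / ns.sum())


def aggregate_iou(per_image_mask: Mapping[str, Sequence[float]],
                  per_image_box: Mapping[str, Sequence[float]] | None = None,
                  ) -> IoUReport:
    """Per-group mean +/- sample SD and a count-weighted overall mean.

    Groups are typically one animal each; SD uses the n-1 convention.
    """
    if not per_image_mask:
        raise ValueError("need at least one group")
    if per_image_box is None:
        per_image_box = {k: v for k, v in per_image_mask.items()}
    labels = list(per_image_mask)
    ns, m_mean, m_sd, b_mean, b_sd = [], [], [], [], []
    for lab in labels:
        vals = np.asarray(per_image_mask[lab], float)
        bvals = np.asarray(per_image_box[lab], float)
        if vals.size == 0 or bvals.size == 0:
            raise ValueError(f"empty group: {lab}")
        ns.append(vals.size)
        m_mean.append(vals.mean())
        m_sd.append(vals.std(ddof=1) if vals.size > 1 else 0.0)
        b_mean.append(bvals.mean())
        b_sd.append(bvals.std(ddof=1) if bvals.size > 1 else 0.0)
    return IoUReport(
        group_labels=labels,
        group_ns=np.asarray(ns),
        mask_means=np.asarray(m_mean), mask_sds=np.asarray(m_sd),
        box_means=np.asarray(b_mean), box_sds=np.asarray(b_sd),
        overall_mask=weighted_mean(m_mean, ns),
        overall_box=weighted_mean(b_mean, ns),
    )
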