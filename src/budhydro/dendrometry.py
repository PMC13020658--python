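"""Optical dendrometry: frames -> corrected, normalised area series.

The extraction follows the classic threshold-and-count recipe: each
grayscale frame is binarised (dark tissue on light background), black
pixels are counted inside manually defined rectangular ROIs, the bud area
is the combined bud+stem ROI count minus the stem ROI count, and the
thermal-reference signal is removed before normalising every series to its
first measurement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

__all__ = [
    "ROIRect",
    "ROISet",
    "auto_threshold",
    "binarize",
    "measure_areas",
    "bud_area",
    "correct_and_normalize",
    "extract_series",
]


@dataclass(frozen=True)
class ROIRect:
    """Axis-aligned pixel rectangle, 0-based, half-open: rows [r0, r1), cols [c0, c1)."""

    r0: int
    c0: int
    r1: int
    c1: int

    def __post_init__(self) -> None:
        if not (self.r0 < self.r1 and self.c0 < self.c1):
            raise ValueError("ROI rectangle must have positive extent")
        if self.r0 < 0 or self.c0 < 0:
            raise ValueError("ROI rectangle must be non-negative")

    def check_within(self, shape: tuple) -> None:
        if self.r1 > shape[0] or self.c1 > shape[1]:
            raise ValueError(f"ROI {self} outside frame of shape {shape}")

    def slice(self) -> tuple:
        return (slice(self.r0, self.r1), slice(self.c0, self.c1))

    def disjoint(self, other: "ROIRect") -> bool:
        return (
            self.r1 <= other.r0
            or other.r1 <= self.r0
            or self.c1 <= other.c0
            or other.c1 <= self.c0
        )


@dataclass(frozen=True)
class ROISet:
    """The three measurement rectangles of one dendrometer sequence.

    The stem ROI need not be contained in the combined ROI (areas are
    subtracted, not masks), but the reference strip must be disjoint from
    both tissue ROIs.
    """

    combined_roi: ROIRect
    stem_roi: ROIRect
    reference_roi: ROIRect

    def __post_init__(self) -> None:
        if not self.reference_roi.disjoint(self.combined_roi):
            raise ValueError("reference ROI overlaps the combined ROI")
        if not self.reference_roi.disjoint(self.stem_roi):
            raise ValueError("reference ROI overlaps the stem ROI")

    def check_within(self, shape: tuple) -> None:
        for roi in (self.combined_roi, self.stem_roi, self.reference_roi):
            roi.check_within(shape)


def auto_threshold(frame: np.ndarray) -> float:
    """Per-sequence automatic threshold by between-class variance maximisation.

    Falls back to mid-gray for a constant frame, which carries no histogram
    structure.
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValueError("empty image")
    if frame.min() == frame.max():
        return 127.5
    thr = float(threshold_otsu(frame))
    # Otsu's level itself belongs to the dark class; for integer gray
    # levels the half-step up makes the strict darker-than rule include it.
    if np.issubdtype(frame.dtype, np.integer):
        thr += 0.5
    return thr


def binarize(frame: np.ndarray, threshold="auto") -> np.ndarray:
    """Threshold a grayscale frame; pixels *darker* than the threshold are foreground.

    ``threshold="auto"`` maximises between-class variance over the frame
    histogram (Otsu). A constant frame has no histogram structure, so auto
    mode falls back to mid-gray: an all-black frame is all foreground, an
    all-white frame all background.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("expected a single-channel image")
    if frame.size == 0:
        raise ValueError("empty image")
    if isinstance(threshold, str) and threshold == "auto":
        return frame < auto_threshold(frame)
    thr = float(threshold)
    if not (0.0 <= thr <= 255.0):
        raise ValueError("threshold outside the 8-bit gray range")
    return frame < thr


def measure_areas(mask: np.ndarray, rois: ROISet) -> tuple[int, int, int]:
    """Exact foreground pixel counts in (combined, stem, reference) ROIs."""
    mask = np.asarray(mask, dtype=bool)
    rois.check_within(mask.shape)
    return (
        int(mask[rois.combined_roi.slice()].sum()),
        int(mask[rois.stem_roi.slice()].sum()),
        int(mask[rois.reference_roi.slice()].sum()),
    )


def bud_area(combined_px: float, stem_px: float) -> float:
    """Bud-specific area = combined ROI count - stem ROI count.

    A negative result signals ROI misconfiguration and raises rather than
    being clamped to zero.
    """
    out = combined_px - stem_px
    if out < 0:
        raise ValueError(
            f"combined area ({combined_px}) smaller than stem area ({stem_px}); "
            "check ROI placement"
        )
    return out


def correct_and_normalize(
    tissue: np.ndarray, reference: np.ndarray, mode: str = "additive"
) -> np.ndarray:
    """Remove the shared thermal drift and normalise to the first sample.

    ``additive`` (default): rel(t) = tissue(t)/tissue(0) - (ref(t)/ref(0) - 1);
    ``multiplicative``: rel(t) = (tissue(t) * ref(0)/ref(t)) / tissue(0).
    Both are the identity when the reference is flat, and both anchor
    rel(0) = 1 exactly.
    """
    tissue = np.asarray(tissue, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if tissue.shape != reference.shape:
        raise ValueError("tissue and reference series must be aligned and equal length")
    if tissue.size == 0:
        raise ValueError("empty series")
    if tissue[0] <= 0 or reference[0] <= 0:
        raise ValueError("first sample of each series must be positive")
    if mode == "additive":
        return tissue / tissue[0] - (reference / reference[0] - 1.0)
    if mode == "multiplicative":
        if np.any(reference <= 0):
            raise ValueError("multiplicative correction needs a positive reference")
        return (tissue * reference[0] / reference) / tissue[0]
    raise ValueError(f"unknown correction mode: {mode}")


def _iter_frames(frames):
    if isinstance(frames, (str, Path)):
        paths = sorted(
            p for p in Path(frames).iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not paths:
            raise FileNotFoundError(f"no PNG/TIFF frames under {frames}")
        for p in paths:
            try:
                yield p.name, iio.imread(p)
            except Exception:  # corrupt frame: drop with a logged gap
                logger.warning("dropping unreadable frame %s", p)
    else:
        for i, frame in enumerate(frames):
            yield i, frame


def extract_series(
    frames,
    rois: ROISet,
    threshold="auto",
    timestamps=None,
    plant_id: str = "plant",
    correction: str = "additive",
) -> pd.DataFrame:
    """Run the full extraction over a frame directory or stack.

    The threshold is a per-sequence constant: ``"auto"`` selects it once by
    between-class variance maximisation on the first frame (mirroring the
    one-manual-threshold-per-sequence protocol), a number applies as given.
    Returns a tidy frame (plant_id, tissue, frame, timestamp, raw_area_px,
    relative_area) for tissues bud, stem and reference.
    """
    combined, stem, ref, labels = [], [], [], []
    thr = threshold
    for label, frame in _iter_frames(frames):
        if isinstance(thr, str) and thr == "auto":
            thr = auto_threshold(frame)
        mask = binarize(frame, thr)
        c, s, r = measure_areas(mask, rois)
        combined.append(c)
        stem.append(s)
        ref.append(r)
        labels.append(label)
    if not combined:
        raise ValueError("no frames to extract")
    combined = np.asarray(combined, dtype=float)
    stem = np.asarray(stem, dtype=float)
    ref = np.asarray(ref, dtype=float)
    bud = np.array([bud_area(c, s) for c, s in zip(combined, stem)])
    if timestamps is None:
        timestamps = pd.RangeIndex(len(labels))
    out = []
    for tissue, raw in (("bud", bud), ("stem", stem), ("reference", ref)):
        rel = correct_and_normalize(raw, ref, mode=correction)
        out.append(
            pd.DataFrame(
                {
                    "plant_id": plant_id,
                    "tissue": tissue,
                    "frame": labels,
                    "timestamp": np.asarray(timestamps),
                    "raw_area_px": raw,
                    "relative_area": rel,
                }
            )
        )
    return pd.concat(out, ignore_index=True)
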