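"""Rasterise synthetic dendrometer frames.

Each frame shows a stem silhouette (vertical trapezoid), the adjacent
node-2 bud (ellipse) and a fixed thermal-reference strip (rectangle) as
dark shapes on a light background, so that threshold-and-count extraction
can be exercised end to end. Shape scaling hits a target silhouette area:
stem widths scale linearly, bud semi-axes by the square root, the reference
strip by its width.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .config import GeometrySpec

__all__ = ["render_frame", "render_frames", "write_frames", "default_rois"]


def _stem_mask(geom: GeometrySpec, area: float) -> np.ndarray:
    scale = area / geom.stem_area0
    rr, cc = np.mgrid[0 : geom.frame_height, 0 : geom.frame_width]
    frac = np.clip((rr - geom.stem_top) / (geom.stem_bottom - geom.stem_top), 0.0, 1.0)
    width = (geom.stem_width_top + frac * (geom.stem_width_bottom - geom.stem_width_top)) * scale
    in_rows = (rr >= geom.stem_top) & (rr < geom.stem_bottom)
    return in_rows & (np.abs(cc - geom.stem_x_center) < width / 2.0)


def _bud_mask(geom: GeometrySpec, area: float) -> np.ndarray:
    if area <= 0:
        return np.zeros((geom.frame_height, geom.frame_width), dtype=bool)
    scale = np.sqrt(area / geom.bud_area0)
    a, b = geom.bud_semi_axes[0] * scale, geom.bud_semi_axes[1] * scale
    r0, c0 = geom.bud_center
    rr, cc = np.mgrid[0 : geom.frame_height, 0 : geom.frame_width]
    return ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0


def _ref_mask(geom: GeometrySpec, area: float) -> np.ndarray:
    # pixel-exact strip: full columns plus one partial column of rows
    r0, c0, r1, c1 = geom.ref_rect
    height = r1 - r0
    n = int(round(area))
    full_cols, extra_rows = divmod(n, height)
    if full_cols + (extra_rows > 0) > (c1 - c0):
        raise ValueError("reference area exceeds its rectangle")
    mask = np.zeros((geom.frame_height, geom.frame_width), dtype=bool)
    mask[r0:r1, c0 : c0 + full_cols] = True
    if extra_rows:
        mask[r0 : r0 + extra_rows, c0 + full_cols] = True
    return mask


def render_frame(
    stem_area: float,
    bud_area: float,
    ref_area: float,
    geom: GeometrySpec | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one grayscale uint8 frame with the three target areas (px)."""
    geom = geom or GeometrySpec()
    geom.validate()
    stem = _stem_mask(geom, stem_area)
    bud = _bud_mask(geom, bud_area)
    ref = _ref_mask(geom, ref_area)
    if (stem & bud).any() or (stem & ref).any() or (bud & ref).any():
        raise ValueError("silhouettes overlap at the requested areas")
    for mask, name in ((stem, "stem"), (bud, "bud")):
        if mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any():
            raise ValueError(f"{name} silhouette touches the frame edge")
    frame = np.full((geom.frame_height, geom.frame_width), geom.background_gray, dtype=float)
    frame[stem | bud | ref] = geom.foreground_gray
    if geom.pixel_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        frame = frame + rng.normal(0.0, geom.pixel_noise_sd, frame.shape)
    return np.clip(frame, 0, 255).astype(np.uint8)


def render_frames(
    series: pd.DataFrame,
    geom: GeometrySpec | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render a (T, H, W) uint8 stack from one plant's tidy area series.

    ``series`` needs columns ``tissue`` (bud/stem/reference), ``age_days``
    (or ``timestamp``) and ``area_px``; the three tissues must share the
    time axis.
    """
    geom = geom or GeometrySpec()
    key = "age_days" if "age_days" in series.columns else "timestamp"
    wide = series.pivot_table(index=key, columns="tissue", values="area_px", sort=True)
    missing = {"bud", "stem", "reference"} - set(wide.columns)
    if missing:
        raise ValueError(f"series missing tissues: {sorted(missing)}")
    if wide.isna().any().any():
        raise ValueError("tissues are not aligned on a common time axis")
    stack = np.empty((len(wide), geom.frame_height, geom.frame_width), dtype=np.uint8)
    for i, (_, row) in enumerate(wide.iterrows()):
        stack[i] = render_frame(row["stem"], row["bud"], row["reference"], geom, rng)
    return stack


def write_frames(stack: np.ndarray, out_dir, plant_id: str = "plant", fmt: str = "png") -> list[Path]:
    """Write a stack as ``out_dir/plant_id/frame_%06d.png`` (or .tif)."""
    out = Path(out_dir) / plant_id
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(stack):
        p = out / f"frame_{i:06d}.{fmt}"
        iio.imwrite(p, frame)
        paths.append(p)
    return paths


def default_rois(geom: GeometrySpec | None = None):
    """Rectangular ROI set separating stem, combined bud+stem and reference."""
    from .dendrometry import ROIRect, ROISet

    geom = geom or GeometrySpec()
    split = int((geom.stem_x_center + geom.bud_center[1]) / 2)
    ref_c0 = geom.ref_rect[1]
    return ROISet(
        combined_roi=ROIRect(0, 0, geom.frame_height, ref_c0 - 10),
        stem_roi=ROIRect(0, 0, geom.frame_height, split),
        reference_roi=ROIRect(0, ref_c0 - 5, geom.frame_height, geom.frame_width),
    )
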