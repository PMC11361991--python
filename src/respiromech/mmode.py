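"""Diaphragm curve extraction from M-mode-style images.

The diaphragm shows as the brightest band in each time column of an
M-mode image. The tracer smooths each column vertically (3-pixel moving
average), takes the per-column intensity argmax as the band center, and
enforces temporal continuity with a 5-column median filter; pixel rows
map to depth in cm through the image geometry. Columns with no contrast
fall back to interpolation from their traced neighbours and count
against the trace quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import median_filter, uniform_filter1d

from .synthetic import ImageSpec

__all__ = [
    "TracedCurve",
    "trace_mmode",
    "excursion_from_curve",
    "save_png",
    "load_png",
]


@dataclass(frozen=True)
class TracedCurve:
    """Depth of the diaphragm band per image column.

    ``quality`` is the fraction of columns traced directly (without the
    neighbour-interpolation fallback).
    """

    t_index: np.ndarray
    depth: np.ndarray
    quality: float

    def __post_init__(self) -> None:
        if self.t_index.shape != self.depth.shape:
            raise ValueError("t_index and depth must align")
        if not (0.0 <= self.quality <= 1.0):
            raise ValueError("quality must lie in [0, 1]")

    def to_csv(self, path_or_buf) -> None:
        pd.DataFrame({"column_index": self.t_index, "depth_cm": self.depth}).to_csv(
            path_or_buf, index=False
        )


def trace_mmode(image, spec: ImageSpec) -> TracedCurve:
    """Extract the bright-band depth curve from an M-mode image."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    if img.shape[0] != spec.pixels_depth:
        raise ValueError(
            f"image has {img.shape[0]} depth pixels, spec expects {spec.pixels_depth}"
        )
    n_cols = img.shape[1]
    smooth = uniform_filter1d(img, size=3, axis=0, mode="nearest")
    peaks = np.argmax(smooth, axis=0)
    rows = peaks.astype(float)
    # three-point parabolic vertex around the argmax: sub-pixel band center,
    # invariant to uniform intensity offsets
    cols = np.arange(n_cols)
    interior = (peaks > 0) & (peaks < img.shape[0] - 1)
    pi, ci = peaks[interior], cols[interior]
    lo, mid, hi = smooth[pi - 1, ci], smooth[pi, ci], smooth[pi + 1, ci]
    denom = lo - 2.0 * mid + hi
    safe = denom < 0
    rows[cols[interior][safe]] = pi[safe] + 0.5 * (lo[safe] - hi[safe]) / denom[safe]
    flat = np.ptp(smooth, axis=0) == 0.0  # no contrast: nothing to trace
    good = ~flat
    if not np.any(good):
        raise ValueError("no traceable column in image")
    if np.any(flat):
        idx = np.arange(n_cols)
        rows[flat] = np.interp(idx[flat], idx[good], rows[good])
    k = min(5, n_cols if n_cols % 2 == 1 else n_cols - 1)
    if k >= 3:
        rows = median_filter(rows, size=k, mode="nearest")
    depth = spec.depth_min + (rows + 0.5) * spec.pixel_size
    return TracedCurve(
        t_index=np.arange(n_cols),
        depth=depth,
        quality=float(np.count_nonzero(good)) / n_cols,
    )


def excursion_from_curve(curve: TracedCurve) -> float:
    """Peak-to-trough depth range of the traced curve, cm."""
    if curve.depth.size == 0:
        raise ValueError("empty curve")
    return float(np.max(curve.depth) - np.min(curve.depth))


def save_png(image: np.ndarray, path) -> None:
    """Write an 8-bit grayscale image to PNG."""
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="L").save(path)


def load_png(path) -> np.ndarray:
    """Read a grayscale PNG as a 2-D uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)
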