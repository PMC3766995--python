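"""Height-map preprocessing: background flattening and histogram equalization.

AFM height maps carry a global background slope (sample tilt relative to
the scanner plane).  ``flatten_first_order`` removes it by subtracting
an ordinary least-squares plane ``z = a + b*col + c*row`` fitted over
all pixels.  ``equalize_histogram`` then maps the flattened heights to
the full dynamic range of 256 gray levels by a rank-based (cumulative
count) transformation, so that downstream level-set analysis sees a
comparable gray-level distribution regardless of the absolute height
scale of the scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import HeightMap

__all__ = ["GrayImage", "flatten_first_order", "equalize_histogram"]


@dataclass
class GrayImage:
    """A 2-D grid of integer gray levels in [0, 255]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.size == 0:
            raise ValueError("gray image must be a non-empty 2-D grid")
        if not np.issubdtype(v.dtype, np.integer):
            if not np.allclose(v, np.round(v)):
                raise ValueError("gray levels must be integers")
            v = np.round(v).astype(np.int64)
        if v.min() < 0 or v.max() > 255:
            raise ValueError("gray levels must lie in [0, 255]")
        self.values = v.astype(np.uint8)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def flatten_first_order(hm: HeightMap, mode: str = "plane") -> HeightMap:
    """Remove the background slope from a height map.

    Parameters
    ----------
    hm
        Input height map (finite values; validated on construction).
    mode
        ``"plane"`` (default) subtracts a single global least-squares
        plane ``z = a + b*col + c*row``.  ``"line"`` subtracts an
        independent first-order line fit per scan row, mimicking the
        line-by-line leveling of AFM instrument software.  ``"none"``
        returns the input unchanged.

    The returned residual grid has zero mean (the fits include an
    intercept).
    """
    z = hm.values
    if mode == "none":
        return HeightMap(z.copy(), hm.pixel_size, hm.source_path)
    if mode == "plane":
        rows, cols = np.meshgrid(
            np.arange(z.shape[0], dtype=float),
            np.arange(z.shape[1], dtype=float),
            indexing="ij",
        )
        design = np.column_stack(
            [np.ones(z.size), cols.ravel(), rows.ravel()]
        )
        coef, *_ = np.linalg.lstsq(design, z.ravel(), rcond=None)
        residual = z - (design @ coef).reshape(z.shape)
    elif mode == "line":
        x = np.arange(z.shape[1], dtype=float)
        design = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(design, z.T, rcond=None)
        residual = z - (design @ coef).T
    else:
        raise ValueError(f"unknown flattening mode: {mode!r}")
    return HeightMap(residual, hm.pixel_size, hm.source_path)


def equalize_histogram(hm: HeightMap) -> GrayImage:
    """Rank-based histogram equalization to 256 gray levels.

    Each pixel with height ``v`` maps to ``min(floor(256 * C(v) / N), 255)``
    where ``C(v)`` is the number of pixels with height <= ``v`` and ``N``
    the pixel count.  The mapping is monotone non-decreasing in ``v``;
    ties (equal heights) always receive the same gray level.  A constant
    image maps to gray level 255 (``C(v) = N``).  Heights are ranked at
    full numeric precision; no pre-quantization is applied.
    """
    flat = hm.values.ravel()
    n = flat.size
    uniq, inverse, counts = np.unique(
        flat, return_inverse=True, return_counts=True
    )
    cum = np.cumsum(counts)  # C(v) for each distinct value
    levels = np.minimum((256 * cum) // n, 255).astype(np.uint8)
    return GrayImage(levels[inverse].reshape(hm.values.shape))
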