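"""Reduction of 256-level functional curves to 15 scalar descriptors.

The Euler-characteristic curve of tissue level sets is sigmoid-like
(a negative dip where dark cavities act as holes, then a positive bump
where only bright blobs survive), and the contour-length curve is
parabola-like.  Both are summarised by extremum values and positions,
the zero-crossing, a steepness measure, and areas under the curve:

===== ======================= =========================================
  #   name                    definition
===== ======================= =========================================
 1    euler_min               min of the Euler curve
 2    euler_argmin            its gray level (lowest level on ties)
 3    euler_max               max of the Euler curve
 4    euler_argmax            its gray level
 5    euler_zero_crossing     first level t > argmin with euler(t) >= 0
                              (255 if none)
 6    euler_max_slope         max forward difference of the smoothed
                              curve between argmin and argmax
 7    euler_max_slope_pos     its gray level
 8    euler_area_neg          sum of min(euler, 0)
 9    euler_area_pos          sum of max(euler, 0)
 10   euler_area_total        signed sum of the Euler curve
 11   contour_max             max of the contour-length curve
 12   contour_argmax          its gray level
 13   contour_fwhm            number of levels with contour >= max/2
 14   contour_area            sum of the contour curve
 15   contour_centroid        sum(t * P(t)) / sum(P(t))
===== ======================= =========================================

Identically-zero curves yield all-zero descriptors (degenerate
convention, so a featureless flat sample maps to the origin of feature
space).  The slope is measured on a moving-average smoothed curve
(window 5 by default) so that single-level noise does not dominate the
argmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .minkowski import MinkowskiCurve

__all__ = ["FEATURE_NAMES", "FeatureVector", "extract_features", "band_feature"]

FEATURE_NAMES: tuple[str, ...] = (
    "euler_min",
    "euler_argmin",
    "euler_max",
    "euler_argmax",
    "euler_zero_crossing",
    "euler_max_slope",
    "euler_max_slope_pos",
    "euler_area_neg",
    "euler_area_pos",
    "euler_area_total",
    "contour_max",
    "contour_argmax",
    "contour_fwhm",
    "contour_area",
    "contour_centroid",
)


@dataclass
class FeatureVector:
    """The 15 named scalar curve descriptors for one sample."""

    sample_id: str
    features: dict[str, float]
    label: str | None = field(default=None)

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.features)
        if missing:
            raise ValueError(f"missing features: {sorted(missing)}")
        values = np.array([self.features[k] for k in FEATURE_NAMES])
        if not np.all(np.isfinite(values)):
            raise ValueError("feature values must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.features[k] for k in FEATURE_NAMES], dtype=float)


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window) / window
    # normalized edge handling: divide by the actual kernel coverage
    num = np.convolve(x.astype(float), kernel, mode="same")
    den = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return num / den


def extract_features(
    curve: MinkowskiCurve, slope_window: int = 5
) -> FeatureVector:
    """Compute the 15 canonical descriptors of one curve pair.

    Ties in extrema resolve to the lowest gray level.  ``slope_window``
    is the moving-average width applied before the forward-difference
    steepness measure.
    """
    e = np.asarray(curve.euler, dtype=float)
    p = np.asarray(curve.contour_length, dtype=float)
    f: dict[str, float] = {}

    if np.all(e == 0):
        for name in FEATURE_NAMES[:10]:
            f[name] = 0.0
    else:
        argmin = int(np.argmin(e))
        argmax = int(np.argmax(e))
        f["euler_min"] = float(e[argmin])
        f["euler_argmin"] = float(argmin)
        f["euler_max"] = float(e[argmax])
        f["euler_argmax"] = float(argmax)

        after = np.nonzero(e[argmin + 1 :] >= 0)[0]
        f["euler_zero_crossing"] = (
            float(argmin + 1 + after[0]) if after.size else 255.0
        )

        if argmax > argmin:
            s = _smooth(e, slope_window)
            diffs = s[argmin + 1 : argmax + 1] - s[argmin:argmax]
            k = int(np.argmax(diffs))
            f["euler_max_slope"] = float(diffs[k])
            f["euler_max_slope_pos"] = float(argmin + k)
        else:
            f["euler_max_slope"] = 0.0
            f["euler_max_slope_pos"] = float(argmin)

        f["euler_area_neg"] = float(np.minimum(e, 0).sum())
        f["euler_area_pos"] = float(np.maximum(e, 0).sum())
        f["euler_area_total"] = float(e.sum())

    if np.all(p == 0):
        for name in FEATURE_NAMES[10:]:
            f[name] = 0.0
    else:
        argmax_p = int(np.argmax(p))
        pmax = float(p[argmax_p])
        f["contour_max"] = pmax
        f["contour_argmax"] = float(argmax_p)
        f["contour_fwhm"] = float(np.count_nonzero(p >= pmax / 2.0))
        total = float(p.sum())
        f["contour_area"] = total
        t = np.arange(256, dtype=float)
        f["contour_centroid"] = float((t * p).sum() / total)

    return FeatureVector(
        sample_id=curve.sample_id, features=f, label=curve.label
    )


def band_feature(curve: MinkowskiCurve, band: tuple[int, int]) -> float:
    """Mean Euler value over an inclusive gray-level band.

    This is the scalar used for single-feature classification over a
    band where the two groups' 1-sigma confidence intervals do not
    intersect.
    """
    lo, hi = int(band[0]), int(band[1])
    if not (0 <= lo <= hi <= 255):
        raise ValueError(f"band must satisfy 0 <= lo <= hi <= 255, got {band}")
    return float(np.asarray(curve.euler, dtype=float)[lo : hi + 1].mean())
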