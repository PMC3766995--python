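"""Per-group curve statistics: mean curves, 1-sigma bands, extreme-value
ratios and non-overlapping gray-level bands.

The 1-sigma band at each gray level is the per-level arithmetic mean
plus/minus one *sample* standard deviation (n-1 denominator) of the
group's curves — a dispersion band, not a standard error of the mean.
A gray-level band where the two groups' bands do not intersect marks a
region where a single scalar (the mean Euler value over the band)
already separates the groups well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .features import band_feature
from .minkowski import MinkowskiCurve

__all__ = [
    "GroupCurveStats",
    "group_stats",
    "compare_group_extremes",
    "find_nonoverlap_band",
    "band_feature_cv_accuracy",
]


@dataclass
class GroupCurveStats:
    """Per-gray-level mean and 1-sigma statistics of one labeled group."""

    label: str
    n_samples: int
    euler_mean: np.ndarray
    euler_std: np.ndarray
    contour_mean: np.ndarray
    contour_std: np.ndarray

    def __post_init__(self) -> None:
        for name in ("euler_mean", "euler_std", "contour_mean", "contour_std"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (256,):
                raise ValueError(f"{name} must have 256 entries")
            setattr(self, name, arr)
        if np.any(self.euler_std < 0) or np.any(self.contour_std < 0):
            raise ValueError("standard deviations must be non-negative")

    def extremes(self) -> dict[str, float]:
        """Extrema of the mean curves with positions (lowest level on ties)."""
        e = self.euler_mean
        return {
            "euler_min": float(e.min()),
            "euler_argmin": int(np.argmin(e)),
            "euler_max": float(e.max()),
            "euler_argmax": int(np.argmax(e)),
            "contour_max": float(self.contour_mean.max()),
            "contour_argmax": int(np.argmax(self.contour_mean)),
        }


def group_stats(
    curves: Sequence[MinkowskiCurve], label: str
) -> GroupCurveStats:
    """Mean and sample standard deviation per gray level for one group."""
    if len(curves) < 2:
        raise ValueError("group statistics require at least 2 curves")
    euler = np.stack([np.asarray(c.euler, dtype=float) for c in curves])
    contour = np.stack(
        [np.asarray(c.contour_length, dtype=float) for c in curves]
    )
    return GroupCurveStats(
        label=label,
        n_samples=len(curves),
        euler_mean=euler.mean(axis=0),
        euler_std=euler.std(axis=0, ddof=1),
        contour_mean=contour.mean(axis=0),
        contour_std=contour.std(axis=0, ddof=1),
    )


def compare_group_extremes(a: GroupCurveStats, b: GroupCurveStats) -> dict:
    """Signed ratios of the two mean Euler curves' extremes (a over b).

    Like-signed extremes give positive ratios; a zero extreme in the
    denominator is flagged as undefined.  Ratios are also reported
    rounded to two decimals.
    """
    ea, eb = a.extremes(), b.extremes()
    out: dict = {
        "group_a": a.label,
        "group_b": b.label,
        "min_a": ea["euler_min"],
        "min_b": eb["euler_min"],
        "max_a": ea["euler_max"],
        "max_b": eb["euler_max"],
    }
    for key, num, den in (
        ("min_ratio", ea["euler_min"], eb["euler_min"]),
        ("max_ratio", ea["euler_max"], eb["euler_max"]),
    ):
        if den == 0:
            out[key] = None
            out[key + "_undefined"] = True
        else:
            ratio = num / den
            out[key] = ratio
            out[key + "_rounded"] = round(ratio, 2)
    return out


def find_nonoverlap_band(
    a: GroupCurveStats, b: GroupCurveStats, functional: str = "euler"
) -> list[tuple[int, int]]:
    """Maximal gray-level intervals where the 1-sigma bands are disjoint.

    Returns sorted, disjoint, inclusive ``(lo, hi)`` intervals within
    [0, 255]; empty list when the bands intersect everywhere.
    """
    if functional == "euler":
        mean_a, std_a = a.euler_mean, a.euler_std
        mean_b, std_b = b.euler_mean, b.euler_std
    elif functional == "contour_length":
        mean_a, std_a = a.contour_mean, a.contour_std
        mean_b, std_b = b.contour_mean, b.contour_std
    else:
        raise ValueError(f"unknown functional: {functional!r}")
    lo = np.maximum(mean_a - std_a, mean_b - std_b)
    hi = np.minimum(mean_a + std_a, mean_b + std_b)
    disjoint = lo > hi
    intervals: list[tuple[int, int]] = []
    t = 0
    while t < 256:
        if disjoint[t]:
            start = t
            while t + 1 < 256 and disjoint[t + 1]:
                t += 1
            intervals.append((start, t))
        t += 1
    return intervals


def band_feature_cv_accuracy(
    curves: Sequence[MinkowskiCurve],
    labels: Sequence[str],
    band: tuple[int, int],
    n_folds: int = 10,
    seed: int = 0,
) -> float:
    """Stratified CV accuracy of a one-dimensional threshold classifier
    on the band-mean Euler feature.

    Per fold, the cut point and orientation maximizing training
    accuracy are chosen (midpoints between sorted training values);
    the held-out fold is then scored.  Returns the mean test accuracy.
    """
    from sklearn.model_selection import StratifiedKFold

    x = np.array([band_feature(c, band) for c in curves])
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("band-feature classification requires two classes")
    ybin = y == classes[1]

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in skf.split(x.reshape(-1, 1), ybin):
        cuts = np.unique(x[train])
        candidates = np.concatenate(
            [[cuts[0] - 1.0], (cuts[:-1] + cuts[1:]) / 2.0, [cuts[-1] + 1.0]]
        )
        best_acc, best_cut, best_sign = -1.0, candidates[0], True
        for cut in candidates:
            pred = x[train] > cut
            for sign in (True, False):
                acc = np.mean((pred == sign) == ybin[train])
                if acc > best_acc:
                    best_acc, best_cut, best_sign = acc, cut, sign
        pred_test = (x[test] > best_cut) == best_sign
        accs.append(float(np.mean(pred_test == ybin[test])))
    return float(np.mean(accs))
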