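"""Reading and writing of height maps, curve tables and feature tables.

Conventions used throughout the package:

* grids are row-major, origin at the top-left, 0-based indices:
  ``values[r][c]`` is image row ``r`` (from the top), column ``c``
  (from the left).  Readers never transpose or flip.
* raster inputs (PNG/TIFF) must be single-channel grayscale, 8 or 16
  bit; the raw integer samples are used as heights verbatim — the
  rank-based equalization downstream makes any linear rescaling
  irrelevant.
* text matrices are whitespace-delimited numeric rows; lines starting
  with ``#`` are comments (common in AFM ASCII exports).
* tabular outputs are plain comma-separated CSV with a header row and
  ``.`` as the decimal separator.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HeightMap",
    "FormatError",
    "read_height_map",
    "write_height_map",
    "write_curve_table",
    "read_curve_table",
    "write_feature_table",
    "read_feature_table",
]

_RASTER_EXTS = {".png", ".tif", ".tiff"}


class FormatError(ValueError):
    """Raised when an input file is structurally invalid."""


@dataclass
class HeightMap:
    """A 2-D grid of physical surface heights.

    Parameters
    ----------
    values
        2-D float array of heights (meters or raw instrument units).
    pixel_size
        Optional physical pixel edge length in micrometers.
    source_path
        Provenance string (file the map was read from, or a synthetic
        generator tag).
    """

    values: np.ndarray
    pixel_size: float | None = None
    source_path: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.size == 0:
            raise ValueError("height map must be a non-empty 2-D grid")
        if not np.all(np.isfinite(v)):
            raise ValueError("height map contains non-finite values")
        self.values = v

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _read_text_matrix(path: str) -> np.ndarray:
    rows: list[list[float]] = []
    width: int | None = None
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            try:
                row = [float(tok) for tok in tokens]
            except ValueError as exc:
                raise FormatError(
                    f"{path}: non-numeric token on line {lineno}"
                ) from exc
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise FormatError(
                    f"{path}: ragged row on line {lineno} "
                    f"(expected {width} values, got {len(row)})"
                )
            rows.append(row)
    if not rows:
        raise FormatError(f"{path}: no numeric rows found")
    return np.asarray(rows, dtype=float)


def _read_raster(path: str) -> np.ndarray:
    ext = os.path.splitext(path)[1].lower()
    if ext in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(path)
    else:
        from PIL import Image

        with Image.open(path) as img:
            if img.mode not in {"L", "I", "I;16", "I;16B", "F"}:
                raise FormatError(
                    f"{path}: expected single-channel grayscale raster, "
                    f"got mode {img.mode!r}"
                )
            arr = np.asarray(img)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise FormatError(
            f"{path}: expected single-channel grayscale raster, "
            f"got shape {arr.shape}"
        )
    return arr.astype(float)


def read_height_map(path: str, format_hint: str | None = None) -> HeightMap:
    """Read a height map from a raster image or a text matrix.

    ``format_hint`` may be ``"raster"`` or ``"text_matrix"``; when
    omitted the file extension decides (``.png/.tif/.tiff`` raster,
    anything else text).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format_hint is None:
        ext = os.path.splitext(path)[1].lower()
        format_hint = "raster" if ext in _RASTER_EXTS else "text_matrix"
    if format_hint == "raster":
        values = _read_raster(path)
    elif format_hint == "text_matrix":
        values = _read_text_matrix(path)
    else:
        raise ValueError(f"unknown format hint: {format_hint!r}")
    return HeightMap(values=values, source_path=str(path))


def write_height_map(hm: HeightMap, path: str, fmt: str | None = None) -> None:
    """Write a height map as a text matrix or a 16-bit grayscale raster.

    Text output uses ``%.10g`` so that a read/write round trip
    reproduces the grid to print precision.  Raster output linearly
    rescales to the full 16-bit range only when values fall outside
    ``[0, 65535]``; integer-valued in-range grids are stored verbatim.
    """
    if fmt is None:
        ext = os.path.splitext(path)[1].lower()
        fmt = "raster" if ext in _RASTER_EXTS else "text_matrix"
    if fmt == "text_matrix":
        header = "minkograde height map"
        np.savetxt(path, hm.values, fmt="%.10g", header=header)
    elif fmt == "raster":
        v = hm.values
        if v.min() < 0 or v.max() > 65535 or not np.allclose(v, np.round(v)):
            lo, hi = float(v.min()), float(v.max())
            scale = 65535.0 / (hi - lo) if hi > lo else 0.0
            v = (v - lo) * scale
        arr = np.round(v).astype(np.uint16)
        ext = os.path.splitext(path)[1].lower()
        if ext in {".tif", ".tiff"}:
            import tifffile

            tifffile.imwrite(path, arr)
        else:
            from PIL import Image

            Image.fromarray(arr).save(path)
    else:
        raise ValueError(f"unknown format: {fmt!r}")


# ---------------------------------------------------------------------------
# curve and feature tables
# ---------------------------------------------------------------------------

def write_curve_table(curves: Iterable, path: str) -> None:
    """Write Minkowski functional curves to CSV.

    Columns: ``sample_id, gray_level, area, contour_length, euler`` with
    256 rows per sample.  Reading the table back reproduces the integer
    functionals exactly.
    """
    frames = []
    for curve in curves:
        for name in ("area", "contour_length", "euler"):
            if len(getattr(curve, name)) != 256:
                raise ValueError(
                    f"curve {curve.sample_id!r}: {name} must have 256 entries"
                )
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": curve.sample_id,
                    "gray_level": np.arange(256),
                    "area": np.asarray(curve.area),
                    "contour_length": np.asarray(curve.contour_length),
                    "euler": np.asarray(curve.euler),
                }
            )
        )
    if not frames:
        raise ValueError("no curves to write")
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_curve_table(path: str) -> list:
    """Read a curve CSV written by :func:`write_curve_table`."""
    from .minkowski import MinkowskiCurve

    df = pd.read_csv(path)
    required = {"sample_id", "gray_level", "area", "contour_length", "euler"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    curves = []
    for sample_id, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("gray_level")
        if len(grp) != 256 or not np.array_equal(
            grp["gray_level"].to_numpy(), np.arange(256)
        ):
            raise FormatError(
                f"{path}: sample {sample_id!r} does not cover gray levels 0-255"
            )
        curves.append(
            MinkowskiCurve(
                sample_id=str(sample_id),
                area=grp["area"].to_numpy(),
                contour_length=grp["contour_length"].to_numpy(),
                euler=grp["euler"].to_numpy(),
            )
        )
    return curves


def write_feature_table(features: Sequence, path: str) -> None:
    """Write feature vectors to CSV (sample_id, label, 15 named columns)."""
    from .features import FEATURE_NAMES

    rows = []
    for fv in features:
        row = {"sample_id": fv.sample_id, "label": fv.label or ""}
        row.update({name: fv.features[name] for name in FEATURE_NAMES})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_feature_table(path: str) -> list:
    """Read a feature CSV written by :func:`write_feature_table`."""
    from .features import FEATURE_NAMES, FeatureVector

    df = pd.read_csv(path)
    missing = ({"sample_id"} | set(FEATURE_NAMES)) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        label = row.get("label", "")
        label = None if (pd.isna(label) or label == "") else str(label)
        out.append(
            FeatureVector(
                sample_id=str(row["sample_id"]),
                label=label,
                features={name: float(row[name]) for name in FEATURE_NAMES},
            )
        )
    return out


def write_json(obj: dict, path: str) -> None:
    """Deterministic JSON writer (sorted keys, stable float formatting)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
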