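"""Synthetic tissue-texture height maps for the two tumour grades.

The clinical AFM image set is not public, so the pipeline is exercised
on generated height maps that emulate the two morphologies the method
discriminates:

* **grade II (astrocytoma-like)** — a dense meshwork of fine fibres
  (the neuropil) with many regular nuclei-like bumps and small,
  sparse cavities;
* **grade IV (glioblastoma-like)** — a pulpy mass: few fibres, few
  recognisable nuclei, and irregular large-scale cavities left by
  necrosis and neuropil loss.

Each image is composed on a tilted plane background from (a) fibres
modelled as persistent (correlated) random-walk ridges of a given
thickness, (b) nuclei as smooth Gaussian bumps, (c) cavities as
depressions with randomized polar outlines, plus i.i.d. Gaussian
pixel noise.  The generator is a texture stand-in, not a biophysical
model: it reproduces the qualitative curve geometry (sigmoid Euler
curves, parabola-like contour curves) and the between-grade ordering
of the curve extremes, not absolute clinical magnitudes.

All structure counts scale with image area and all radii with image
edge length, so the class geometry is preserved when images are
generated below the native 512 x 512 size.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io import HeightMap

__all__ = ["TextureParams", "generate_tissue_image", "generate_dataset"]

GRADE_II = "gradeII"
GRADE_IV = "gradeIV"

# class defaults at the native 512 x 512 size; counts scale with area,
# radii and thicknesses with edge length
_DEFAULTS = {
    GRADE_II: dict(
        filament_count=70,
        filament_thickness=2.0,
        filament_height=1.0,
        nuclei_count=30,
        nucleus_radius=(5.0, 10.0),
        nucleus_height=1.4,
        cavity_count=12,
        cavity_radius=(5.0, 12.0),
        cavity_depth=1.6,
    ),
    GRADE_IV: dict(
        filament_count=12,
        filament_thickness=3.0,
        filament_height=0.6,
        nuclei_count=6,
        nucleus_radius=(6.0, 12.0),
        nucleus_height=1.0,
        cavity_count=16,
        cavity_radius=(20.0, 50.0),
        cavity_depth=2.0,
    ),
}


@dataclass
class TextureParams:
    """Parameters of one synthetic tissue texture.

    Heights are in arbitrary units (rank equalization downstream makes
    the absolute scale irrelevant); lengths are in pixels.
    """

    grade: str
    image_size: int = 512
    filament_count: int = 70
    filament_thickness: float = 2.0
    filament_height: float = 1.0
    nuclei_count: int = 30
    nucleus_radius: tuple[float, float] = (5.0, 10.0)
    nucleus_height: float = 1.4
    cavity_count: int = 12
    cavity_radius: tuple[float, float] = (5.0, 12.0)
    cavity_depth: float = 1.6
    cavity_irregularity: float = 0.35
    slope: tuple[float, float] = (0.004, -0.002)
    noise_sd: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grade not in (GRADE_II, GRADE_IV):
            raise ValueError(f"unknown grade: {self.grade!r}")
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")
        for name in ("filament_count", "nuclei_count", "cavity_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("nucleus_radius", "cavity_radius"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{name} must satisfy 1 <= lo <= hi")

    @classmethod
    def for_grade(
        cls, grade: str, image_size: int = 512, seed: int = 0, **overrides
    ) -> "TextureParams":
        """Class defaults, rescaled from the native 512 x 512 geometry."""
        base = dict(_DEFAULTS[grade])
        s = image_size / 512.0
        for key in ("filament_count", "nuclei_count", "cavity_count"):
            # keep at least one structure of each native kind, so small
            # images preserve the class character
            base[key] = max(round(base[key] * s * s), 1 if base[key] else 0)
        base["filament_thickness"] = max(base["filament_thickness"] * s, 1.0)
        for key in ("nucleus_radius", "cavity_radius"):
            lo, hi = base[key]
            base[key] = (max(lo * s, 1.5), max(hi * s, 2.5))
        base.update(overrides)
        return cls(grade=grade, image_size=image_size, seed=seed, **base)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def _stamp_patch(z: np.ndarray, r0: int, c0: int, patch: np.ndarray) -> None:
    """Add ``patch`` centered at (r0, c0), clipped at the borders."""
    half = patch.shape[0] // 2
    n = z.shape[0]
    r_lo, r_hi = max(r0 - half, 0), min(r0 + half + 1, n)
    c_lo, c_hi = max(c0 - half, 0), min(c0 + half + 1, z.shape[1])
    pr_lo, pc_lo = r_lo - (r0 - half), c_lo - (c0 - half)
    z[r_lo:r_hi, c_lo:c_hi] += patch[
        pr_lo : pr_lo + (r_hi - r_lo), pc_lo : pc_lo + (c_hi - c_lo)
    ]


def _filament_layer(rng: np.random.Generator, p: TextureParams) -> np.ndarray:
    n = p.image_size
    marks = np.zeros((n, n))
    # persistent random walk: heading diffuses slowly -> curved fibres
    # that form junctions where walks cross
    for _ in range(p.filament_count):
        r, c = rng.uniform(0, n, size=2)
        theta = rng.uniform(0, 2 * np.pi)
        steps = int(rng.uniform(0.5, 1.5) * n)
        for _ in range(steps):
            theta += rng.normal(0.0, 0.15)
            r += np.sin(theta)
            c += np.cos(theta)
            if not (0 <= r < n and 0 <= c < n):
                break
            marks[int(r), int(c)] = 1.0
    if marks.max() == 0:
        return marks
    layer = gaussian_filter(marks, sigma=p.filament_thickness / 2.0)
    return layer * (p.filament_height / layer.max())


def _nucleus_patch(radius: float, height: float) -> np.ndarray:
    half = int(np.ceil(3 * radius / 2))
    ax = np.arange(-half, half + 1, dtype=float)
    rr, cc = np.meshgrid(ax, ax, indexing="ij")
    sigma = radius / 2.0
    return height * np.exp(-(rr**2 + cc**2) / (2 * sigma**2))


def _cavity_patch(
    rng: np.random.Generator, r0: float, depth: float, irregularity: float
) -> np.ndarray:
    # irregular outline: radius modulated by a few random Fourier modes
    n_modes = 5
    amp = rng.uniform(-1, 1, size=n_modes) * irregularity / np.arange(
        1, n_modes + 1
    )
    phase = rng.uniform(0, 2 * np.pi, size=n_modes)
    half = int(np.ceil(r0 * (1 + irregularity) + 3))
    ax = np.arange(-half, half + 1, dtype=float)
    rr, cc = np.meshgrid(ax, ax, indexing="ij")
    dist = np.hypot(rr, cc)
    ang = np.arctan2(rr, cc)
    radius = r0 * (
        1.0
        + sum(
            amp[k] * np.cos((k + 1) * ang + phase[k]) for k in range(n_modes)
        )
    )
    mask = (dist <= radius).astype(float)
    profile = gaussian_filter(mask, sigma=max(r0 / 5.0, 1.0))
    if profile.max() > 0:
        profile /= profile.max()
    return -depth * profile


def generate_tissue_image(params: TextureParams) -> HeightMap:
    """Compose one synthetic height map; deterministic given the seed."""
    rng = np.random.default_rng(params.seed)
    n = params.image_size
    rows, cols = np.meshgrid(
        np.arange(n, dtype=float), np.arange(n, dtype=float), indexing="ij"
    )
    z = params.slope[0] * cols + params.slope[1] * rows

    z += _filament_layer(rng, params)

    for _ in range(params.nuclei_count):
        radius = rng.uniform(*params.nucleus_radius)
        patch = _nucleus_patch(radius, params.nucleus_height)
        _stamp_patch(
            z, int(rng.integers(n)), int(rng.integers(n)), patch
        )

    for _ in range(params.cavity_count):
        radius = rng.uniform(*params.cavity_radius)
        patch = _cavity_patch(
            rng, radius, params.cavity_depth, params.cavity_irregularity
        )
        _stamp_patch(
            z, int(rng.integers(n)), int(rng.integers(n)), patch
        )

    if params.noise_sd > 0:
        z = z + rng.normal(0.0, params.noise_sd, size=z.shape)

    return HeightMap(
        values=z,
        source_path=f"synthetic:{params.grade}:seed={params.seed}",
    )


def _jitter(rng: np.random.Generator, value, fraction: float = 0.2):
    if isinstance(value, tuple):
        lo = max(value[0] * rng.uniform(1 - fraction, 1 + fraction), 1.0)
        hi = max(value[1] * rng.uniform(1 - fraction, 1 + fraction), lo)
        return (lo, hi)
    return max(int(round(value * rng.uniform(1 - fraction, 1 + fraction))), 0)


def generate_dataset(
    n_gradeII: int,
    n_gradeIV: int,
    seed: int = 0,
    image_size: int = 512,
) -> tuple[list[tuple[HeightMap, str]], pd.DataFrame]:
    """Generate a labeled image set with per-image parameter jitter.

    Structure counts and radii are jittered by +/-20% around the class
    defaults to create within-class variance; every image draws its own
    seed from a spawned seed sequence, so the whole set is reproducible
    from the single top-level seed.

    Returns the ``(height_map, label)`` list and a manifest table
    (sample_id, label, seed, params JSON).
    """
    if n_gradeII < 0 or n_gradeIV < 0:
        raise ValueError("sample counts must be >= 0")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_gradeII + n_gradeIV)
    images: list[tuple[HeightMap, str]] = []
    manifest_rows = []
    specs = [(GRADE_II, i) for i in range(n_gradeII)] + [
        (GRADE_IV, i) for i in range(n_gradeIV)
    ]
    for child, (grade, idx) in zip(children, specs):
        state = child.generate_state(2) % (2**31)
        jit_rng = np.random.default_rng(int(state[0]))
        base = TextureParams.for_grade(grade, image_size=image_size)
        params = TextureParams(
            grade=grade,
            image_size=image_size,
            filament_count=_jitter(jit_rng, base.filament_count),
            filament_thickness=base.filament_thickness,
            filament_height=base.filament_height,
            nuclei_count=_jitter(jit_rng, base.nuclei_count),
            nucleus_radius=_jitter(jit_rng, base.nucleus_radius),
            nucleus_height=base.nucleus_height,
            cavity_count=_jitter(jit_rng, base.cavity_count),
            cavity_radius=_jitter(jit_rng, base.cavity_radius),
            cavity_depth=base.cavity_depth,
            cavity_irregularity=base.cavity_irregularity,
            slope=base.slope,
            noise_sd=base.noise_sd,
            seed=int(state[1]),
        )
        sample_id = f"{'II' if grade == GRADE_II else 'IV'}_{idx:03d}"
        images.append((generate_tissue_image(params), grade))
        manifest_rows.append(
            {
                "sample_id": sample_id,
                "label": grade,
                "seed": params.seed,
                "params": params.to_json(),
            }
        )
    return images, pd.DataFrame(manifest_rows)
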