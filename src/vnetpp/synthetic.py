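"""Seeded BraTS-like phantom generator.

Each phantom is an ellipsoidal "brain" with smooth per-modality texture and a
nested three-shell tumor (outer shell raw label 2, middle shell 1, inner core
4) placed entirely inside the brain.  Modality contrast is constructed so
that the label-2 shell is brightest on flair and the label-4 core brightest
on t1ce, giving a learnable multi-class, multi-modal signal; background
voxels are exactly zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .brats_io import MODALITIES, VolumeSet

__all__ = ["PhantomConfig", "generate_phantom_case", "write_cohort"]

#: additive intensity offsets per (tissue class, modality); rows are
#: healthy brain, label 1 (core), label 2 (edema-like), label 4 (enhancing)
_CONTRAST = {
    "t1":    {0: 1.0, 1: 1.6, 2: 0.7, 4: 1.3},
    "t1ce":  {0: 1.0, 1: 1.5, 2: 1.0, 4: 2.8},
    "t2":    {0: 1.0, 1: 0.6, 2: 2.0, 4: 1.3},
    "flair": {0: 1.0, 1: 1.5, 2: 2.5, 4: 1.3},
}

#: normalized tumor radii of the nested shells (inner core -> outer shell)
_SHELL_RADII = ((4, 0.5), (1, 0.78), (2, 1.0))


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (240, 240, 155)
    n_cases: int = 1
    tumor_fraction_range: tuple[float, float] = (0.02, 0.10)
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if len(self.shape) != 3 or min(self.shape) < 8:
            raise ValueError("shape must be a 3-tuple with all sides >= 8")
        lo, hi = self.tumor_fraction_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("tumor_fraction_range must lie inside (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_cases < 0:
            raise ValueError("n_cases must be nonnegative")


#: test-scale preset used throughout the test suite
TEST_SHAPE = (64, 64, 16)


def _ellipsoid_distance(shape, center, semi_axes):
    """Normalized ellipsoid radius field: <= 1 inside the ellipsoid."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d = sum(
        (((g - c) / a) ** 2).astype(np.float32)
        for g, c, a in zip(grids, center, semi_axes)
    )
    return np.sqrt(d)


def _smooth_texture(rng: np.random.Generator, shape, amplitude: float = 0.15):
    """Low-frequency multiplicative texture from an upsampled coarse field."""
    coarse_shape = tuple(max(2, s // 8) for s in shape)
    coarse = rng.standard_normal(coarse_shape, dtype=np.float32)
    zoom = [s / c for s, c in zip(shape, coarse_shape)]
    tex = ndimage.zoom(coarse, zoom, order=1)
    tex = tex[tuple(slice(0, s) for s in shape)]
    return (1.0 + amplitude * tex / max(np.abs(tex).max(), 1e-8)).astype(np.float32)


def generate_phantom_case(config: PhantomConfig, case_index: int) -> VolumeSet:
    """Deterministically synthesize one multi-modal phantom case."""
    rng = np.random.default_rng([config.seed, case_index])
    shape = tuple(config.shape)

    center = tuple(s / 2.0 + rng.uniform(-0.02, 0.02) * s for s in shape)
    brain_axes = tuple(rng.uniform(0.38, 0.44) * s for s in shape)
    brain = _ellipsoid_distance(shape, center, brain_axes) <= 1.0

    fraction = rng.uniform(*config.tumor_fraction_range)
    scale = fraction ** (1.0 / 3.0)
    if scale >= 0.9:
        raise ValueError(
            f"tumor fraction {fraction:.3f} too large to nest inside the brain"
        )
    tumor_axes = tuple(a * scale for a in brain_axes)
    # center offset in normalized brain coordinates; 1 - scale guarantees the
    # similar tumor ellipsoid stays strictly inside the brain ellipsoid
    max_off = 0.8 * (1.0 - scale)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    radius = max_off * rng.uniform(0.0, 1.0) ** (1.0 / 3.0)
    tumor_center = tuple(
        c + radius * d * a for c, d, a in zip(center, direction, brain_axes)
    )
    tumor_dist = _ellipsoid_distance(shape, tumor_center, tumor_axes)

    seg = np.zeros(shape, dtype=np.int16)
    for label, r in reversed(_SHELL_RADII):  # paint outer shell first
        seg[tumor_dist <= r] = label
    seg[~brain] = 0

    regions = {label: brain & (seg == label) for label in (0, 1, 2, 4)}
    modalities: dict[str, np.ndarray] = {}
    for mod in MODALITIES:
        tex = _smooth_texture(rng, shape)
        vol = np.zeros(shape, dtype=np.float32)
        for label, level in _CONTRAST[mod].items():
            vol[regions[label]] = level
        vol *= tex
        if config.noise_sd > 0:
            noise = rng.standard_normal(shape, dtype=np.float32)
            noise *= np.float32(config.noise_sd)
            vol += np.where(brain, noise, np.float32(0.0))
        vol[~brain] = 0.0
        np.maximum(vol, np.float32(1e-3), out=vol, where=brain)  # brain stays nonzero
        modalities[mod] = vol

    return VolumeSet(case_id=f"phantom_{case_index:03d}", modalities=modalities, seg=seg)


def write_cohort(config: PhantomConfig, out_dir: Path) -> dict:
    """Write ``config.n_cases`` phantom cases in the BraTS directory layout.

    Returns the manifest (also written as ``manifest.json``): case ids, the
    generator seed and per-case indices.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cases = []
    affine = np.eye(4)
    for idx in range(config.n_cases):
        vs = generate_phantom_case(config, idx)
        case_dir = out_dir / vs.case_id
        case_dir.mkdir(exist_ok=True)
        for mod in MODALITIES:
            img = nib.Nifti1Image(vs.modalities[mod], affine)
            nib.save(img, str(case_dir / f"{vs.case_id}_{mod}.nii.gz"))
        nib.save(
            nib.Nifti1Image(vs.seg.astype(np.int16), affine),
            str(case_dir / f"{vs.case_id}_seg.nii.gz"),
        )
        cases.append({"case_id": vs.case_id, "case_index": idx})
    manifest = {
        "seed": config.seed,
        "shape": list(config.shape),
        "noise_sd": config.noise_sd,
        "tumor_fraction_range": list(config.tumor_fraction_range),
        "cases": cases,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
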