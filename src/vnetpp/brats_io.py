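"""Reading, preprocessing and splitting of BraTS-style multi-modal cases.

A case is four co-registered 3-D modality volumes (t1, t1ce, t2, flair) plus
an optional integer segmentation volume with raw labels {0, 1, 2, 4}.
Preprocessing normalizes each modality per volume, extracts an axial slice
window, center-crops 240 -> 192 (24 pixels off each edge), stacks the
modalities into a 4-channel block and remaps labels to contiguous {0,1,2,3}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "MODALITIES",
    "RAW_LABELS",
    "VolumeSet",
    "SliceSample",
    "DatasetSplit",
    "read_case",
    "find_case_files",
    "normalize_volume",
    "preprocess_case",
    "remap_labels",
    "restore_labels",
    "split_cases",
    "center_crop",
]

MODALITIES = ("t1", "t1ce", "t2", "flair")
RAW_LABELS = (0, 1, 2, 4)

_REMAP = {0: 0, 1: 1, 2: 2, 4: 3}
_INVERSE_REMAP = {v: k for k, v in _REMAP.items()}

DEFAULT_SLICE_WINDOW = (30, 120)  # half-open axial window
DEFAULT_CROP = 192


@dataclass
class VolumeSet:
    """One case: four modality volumes plus an optional segmentation."""

    case_id: str
    modalities: dict[str, np.ndarray]
    seg: np.ndarray | None = None

    def __post_init__(self):
        missing = [m for m in MODALITIES if m not in self.modalities]
        if missing:
            raise ValueError(f"case {self.case_id}: missing modalities {missing}")
        shapes = {m: v.shape for m, v in self.modalities.items()}
        ref = shapes[MODALITIES[0]]
        if any(s != ref for s in shapes.values()):
            raise ValueError(f"case {self.case_id}: modality shape mismatch {shapes}")
        if self.seg is not None:
            if self.seg.shape != ref:
                raise ValueError(
                    f"case {self.case_id}: seg shape {self.seg.shape} != {ref}"
                )
            bad = np.setdiff1d(np.unique(self.seg), RAW_LABELS)
            if bad.size:
                raise ValueError(
                    f"case {self.case_id}: seg contains invalid labels {bad.tolist()}"
                )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.modalities[MODALITIES[0]].shape


@dataclass
class SliceSample:
    """One preprocessed axial slice: (side, side, 4) image + class-index mask."""

    image: np.ndarray
    mask: np.ndarray | None
    provenance: tuple[str, int]

    def __post_init__(self):
        if not np.all(np.isfinite(self.image)):
            raise ValueError("slice image contains non-finite values")


@dataclass
class DatasetSplit:
    train: list[str]
    test: list[str]
    seed: int


def find_case_files(case_dir: Path) -> tuple[dict[str, Path], Path | None]:
    """Locate modality-suffixed volume files in a case directory."""
    case_dir = Path(case_dir)
    paths: dict[str, Path] = {}
    for mod in MODALITIES:
        hits = sorted(case_dir.glob(f"*_{mod}.nii*"))
        if hits:
            paths[mod] = hits[0]
    seg_hits = sorted(case_dir.glob("*_seg.nii*"))
    return paths, (seg_hits[0] if seg_hits else None)


def read_case(
    paths: Mapping[str, Path],
    seg_path: Path | None = None,
    case_id: str | None = None,
) -> VolumeSet:
    """Load one case from per-modality volume file paths."""
    for mod in MODALITIES:
        if mod not in paths:
            raise FileNotFoundError(f"no file provided for modality '{mod}'")
        if not Path(paths[mod]).exists():
            raise FileNotFoundError(f"modality '{mod}' file not found: {paths[mod]}")
    modalities = {
        mod: np.asanyarray(nib.load(str(paths[mod])).dataobj, dtype=np.float32)
        for mod in MODALITIES
    }
    seg = None
    if seg_path is not None:
        if not Path(seg_path).exists():
            raise FileNotFoundError(f"segmentation file not found: {seg_path}")
        seg = np.asanyarray(nib.load(str(seg_path)).dataobj).astype(np.int16)
    if case_id is None:
        case_id = Path(paths[MODALITIES[0]]).parent.name
    return VolumeSet(case_id=case_id, modalities=modalities, seg=seg)


def normalize_volume(volume: np.ndarray) -> np.ndarray:
    """Z-score over nonzero (brain) voxels, clipped to [-5, 5]; background 0."""
    volume = np.asarray(volume, dtype=np.float32)
    if not np.all(np.isfinite(volume)):
        raise ValueError("volume contains non-finite values")
    mask = volume != 0
    if not mask.any():
        warnings.warn("all-zero volume passed to normalize_volume; returned unchanged")
        return volume.copy()
    vals = volume[mask]
    mean = vals.mean()
    sd = vals.std()
    out = np.zeros_like(volume)
    if sd < 1e-8:
        return out  # constant brain intensity: zero after centering
    out[mask] = np.clip((vals - mean) / sd, -5.0, 5.0)
    return out


def center_crop(slc: np.ndarray, crop_to: int) -> np.ndarray:
    """Symmetric edge crop of the two leading spatial axes."""
    h, w = slc.shape[:2]
    if crop_to > h or crop_to > w:
        raise ValueError(f"cannot crop {h}x{w} slice to {crop_to}")
    if (h - crop_to) % 2 or (w - crop_to) % 2:
        raise ValueError("crop margins must be symmetric (even difference)")
    oy, ox = (h - crop_to) // 2, (w - crop_to) // 2
    return slc[oy : oy + crop_to, ox : ox + crop_to]


def remap_labels(seg: np.ndarray) -> np.ndarray:
    """Raw BraTS labels {0,1,2,4} -> contiguous class indices {0,1,2,3}."""
    bad = np.setdiff1d(np.unique(seg), RAW_LABELS)
    if bad.size:
        raise ValueError(f"invalid raw labels {bad.tolist()}")
    out = np.asarray(seg).copy()
    out[out == 4] = 3
    return out.astype(np.int64)


def restore_labels(mask: np.ndarray) -> np.ndarray:
    """Inverse of :func:`remap_labels`: {0,1,2,3} -> {0,1,2,4}."""
    bad = np.setdiff1d(np.unique(mask), list(_INVERSE_REMAP))
    if bad.size:
        raise ValueError(f"invalid class indices {bad.tolist()}")
    out = np.asarray(mask).copy()
    out[out == 3] = 4
    return out.astype(np.int16)


def preprocess_case(
    vs: VolumeSet,
    slice_window: tuple[int, int] = DEFAULT_SLICE_WINDOW,
    crop_to: int = DEFAULT_CROP,
) -> list[SliceSample]:
    """Normalize, window, crop, stack and remap one case into slice samples."""
    lo, hi = slice_window
    n_axial = vs.shape[2]
    if not (0 <= lo < hi <= n_axial):
        raise ValueError(
            f"slice window [{lo}, {hi}) outside axial extent [0, {n_axial})"
        )
    normalized = {m: normalize_volume(vs.modalities[m]) for m in MODALITIES}
    mask_vol = remap_labels(vs.seg) if vs.seg is not None else None
    samples: list[SliceSample] = []
    for z in range(lo, hi):
        channels = [center_crop(normalized[m][:, :, z], crop_to) for m in MODALITIES]
        image = np.stack(channels, axis=-1).astype(np.float32)
        mask = center_crop(mask_vol[:, :, z], crop_to) if mask_vol is not None else None
        samples.append(SliceSample(image=image, mask=mask, provenance=(vs.case_id, z)))
    return samples


def split_cases(case_ids: list[str], train_fraction: float, seed: int) -> DatasetSplit:
    """Deterministic patient-level shuffle split."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    if len(case_ids) < 2:
        raise ValueError("need at least 2 cases to split")
    ids = sorted(case_ids)
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    n_train = int(round(train_fraction * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)  # both sides nonempty
    return DatasetSplit(train=ids[:n_train], test=ids[n_train:], seed=seed)
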