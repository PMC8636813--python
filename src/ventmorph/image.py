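"""Label-volume container and NIfTI readers/writers.

A :class:`LabelVolume` is the raw imaging object every geometric stage reads:
a 3D integer grid with a 4x4 affine mapping voxel indices to world mm.  Label
codes follow a fixed convention: 0 background, 1 brain parenchyma, 2 ventricle
(CSF), 3 cranium shell.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import VentmorphError

BACKGROUND = 0
BRAIN = 1
VENTRICLE = 2
CRANIUM_SHELL = 3

#: default T1-like intensity levels (arbitrary units, CSF < shell < brain)
INTENSITY_LEVELS = {BACKGROUND: 0, BRAIN: 600, VENTRICLE: 100, CRANIUM_SHELL: 300}


@dataclass
class LabelVolume:
    """3D integer label grid with spacing/affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise VentmorphError(f"label volume must be 3D, got shape {data.shape}")
        if not np.issubdtype(data.dtype, np.integer):
            rounded = np.rint(data)
            if not np.allclose(data, rounded, atol=1e-6):
                raise VentmorphError("label volume contains non-integer label values")
            data = rounded.astype(np.int16)
        self.data = data
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise VentmorphError("affine must be 4x4")
        if np.any(self.spacing <= 0):
            raise VentmorphError("voxel spacing must be positive")

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing in mm, from the affine column norms."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def count(self, label: int) -> int:
        return int(np.count_nonzero(self.data == label))

    def label_counts(self) -> dict[int, int]:
        values, counts = np.unique(self.data, return_counts=True)
        return {int(v): int(c) for v, c in zip(values, counts)}

    def world_coordinates(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world mm coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]


def read_label_volume(path: str | Path) -> LabelVolume:
    """Read a NIfTI-1/2 label image; integer dtype is enforced."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return LabelVolume(data=data, affine=np.asarray(img.affine))


def write_label_volume(volume: LabelVolume, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(volume.data.astype(np.int16), volume.affine)
    nib.save(img, str(path))
    return path


def read_intensity_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read an intensity NIfTI image; returns (data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), np.asarray(img.affine)


def write_intensity_volume(data: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.int16), np.asarray(affine, dtype=float))
    nib.save(img, str(path))
    return path
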