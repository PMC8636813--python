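"""Voxel-count volumetry and a minimal threshold segmenter.

Ventricular volume is exact voxel counting: ``count * voxel_volume / 1000``
in cm3.  The threshold segmenter exists only so the intensity -> mask ->
volume path can be exercised end-to-end on phantoms; clinical-grade
interactive segmentation is out of scope.  Connectivity is fixed at the
26-neighbourhood.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import VentmorphError
from .image import LabelVolume, VENTRICLE


@dataclass(frozen=True)
class VolumeReport:
    label: int
    voxel_count: int
    voxel_volume_mm3: float
    volume_cm3: float


def ventricular_volume(volume: LabelVolume, label: int = VENTRICLE) -> VolumeReport:
    """Volume of one label class by exact voxel counting.

    An absent label yields a zero-count report with a warning, not an error.
    """
    count = volume.count(label)
    if count == 0:
        warnings.warn(f"label {label} absent from volume; volume is 0", stacklevel=2)
    vox = volume.voxel_volume_mm3
    return VolumeReport(
        label=label,
        voxel_count=count,
        voxel_volume_mm3=vox,
        volume_cm3=count * vox / 1000.0,
    )


def segment_by_threshold(
    intensity: np.ndarray, threshold: float, seed: tuple[int, int, int]
) -> np.ndarray:
    """Voxels below ``threshold`` 26-connected to ``seed``; deterministic.

    Raises when the seed voxel itself is at or above the threshold.
    """
    intensity = np.asarray(intensity)
    seed = tuple(int(s) for s in seed)
    if intensity[seed] >= threshold:
        raise VentmorphError(
            f"seed intensity {intensity[seed]} is not below threshold {threshold}"
        )
    below = intensity < threshold
    labels, _ = ndimage.label(below, structure=np.ones((3, 3, 3), dtype=int))
    return labels == labels[seed]
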