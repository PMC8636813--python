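"""ACPC rigid realignment.

The canonical (ACPC) frame is RAS-like: +x right, +y anterior, +z superior,
with the anterior commissure (AC) at the origin, the posterior commissure (PC)
at ``(0, -d, 0)`` where ``d = |AC - PC|``, and the midsagittal plane at
``x = 0``.  Axial slices are perpendicular to z, coronal slices to y.  All
downstream "axial/coronal" language in the morphometry module resolves against
this frame.

Alignment is landmark-driven: AC, PC and one midsagittal point are explicit
inputs (clinical realignment is done manually at a workstation; automatic
AC/PC detection is out of scope).  Label images are resampled with
nearest-neighbour interpolation so they stay integer; intensity images use
trilinear interpolation.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import DegenerateLandmarksError, MissingLabelError, VentmorphError
from .image import LabelVolume

_COLLINEAR_TOL = 1e-9


@dataclass(frozen=True)
class LandmarkSet:
    """AC, PC and a midsagittal point, world coordinates in mm."""

    ac: np.ndarray
    pc: np.ndarray
    midsagittal: np.ndarray

    def __post_init__(self) -> None:
        for name in ("ac", "pc", "midsagittal"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            object.__setattr__(self, name, v)
        if np.linalg.norm(self.ac - self.pc) < _COLLINEAR_TOL:
            raise DegenerateLandmarksError("AC and PC coincide")

    @property
    def acpc_length_mm(self) -> float:
        return float(np.linalg.norm(self.ac - self.pc))

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "units": "mm",
            "ac": self.ac.tolist(),
            "pc": self.pc.tolist(),
            "midsagittal": self.midsagittal.tolist(),
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "LandmarkSet":
        payload = json.loads(Path(path).read_text())
        return cls(ac=payload["ac"], pc=payload["pc"], midsagittal=payload["midsagittal"])


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation, mapping world mm -> canonical mm."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise VentmorphError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise VentmorphError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(rotation=Rt, translation=-Rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self o other)(p) = self(other(p))."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {"rotation": self.rotation.tolist(), "translation": self.translation.tolist()}
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidTransform":
        payload = json.loads(Path(path).read_text())
        return cls(rotation=np.asarray(payload["rotation"]), translation=np.asarray(payload["translation"]))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))


def compute_acpc_transform(landmarks: LandmarkSet) -> RigidTransform:
    """Rigid map taking AC to the origin, AC->PC to -y, midsagittal point into x=0, z>0.

    Raises :class:`DegenerateLandmarksError` when the midsagittal point is
    collinear with the AC-PC line.
    """
    ac, pc, mid = landmarks.ac, landmarks.pc, landmarks.midsagittal
    ey = ac - pc
    ey = ey / np.linalg.norm(ey)
    v = mid - ac
    v_perp = v - (v @ ey) * ey
    norm_perp = np.linalg.norm(v_perp)
    if norm_perp < _COLLINEAR_TOL * max(1.0, np.linalg.norm(v)):
        raise DegenerateLandmarksError("midsagittal point is collinear with the AC-PC line")
    ez = v_perp / norm_perp
    ex = np.cross(ey, ez)
    R = np.vstack([ex, ey, ez])
    return RigidTransform(rotation=R, translation=-R @ ac)


@dataclass
class AlignedVolume:
    """Label grid resampled into the canonical ACPC frame.

    ``origin`` is the canonical-frame mm coordinate of the centre of voxel
    (0, 0, 0); voxel ``(i, j, k)`` sits at ``origin + (i, j, k) * spacing``.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    acpc_length_mm: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise VentmorphError("spacing must be positive")

    def coords(self, axis: int) -> np.ndarray:
        """Voxel-centre mm coordinates along one canonical axis."""
        return self.origin[axis] + np.arange(self.data.shape[axis]) * self.spacing[axis]

    def nearest_index(self, axis: int, mm: float) -> int:
        return int(np.argmin(np.abs(self.coords(axis) - mm)))

    def to_label_volume(self) -> LabelVolume:
        affine = np.eye(4)
        affine[:3, :3] = np.diag(self.spacing)
        affine[:3, 3] = self.origin
        return LabelVolume(data=self.data, affine=affine)

    @classmethod
    def from_label_volume(cls, volume: LabelVolume, acpc_length_mm: float | None = None) -> "AlignedVolume":
        """Interpret an axis-aligned label volume as already canonical."""
        lin = volume.affine[:3, :3]
        if not np.allclose(lin, np.diag(np.diag(lin)), atol=1e-6):
            raise VentmorphError("volume is not axis-aligned; run compute_acpc_transform/resample_labels")
        return cls(
            data=volume.data,
            spacing=np.diag(lin),
            origin=volume.affine[:3, 3],
            acpc_length_mm=acpc_length_mm,
        )


def _output_grid(
    volume: LabelVolume, transform: RigidTransform, spacing: np.ndarray, margin: int
) -> tuple[np.ndarray, np.ndarray]:
    """Canonical bounding grid (origin, shape) covering the transformed head."""
    head = volume.data > 0
    if not head.any():
        raise MissingLabelError("volume contains no non-background voxels")
    idx_lo, idx_hi = [], []
    for axis in range(3):
        proj = np.any(head, axis=tuple(a for a in range(3) if a != axis))
        nz = np.nonzero(proj)[0]
        idx_lo.append(nz[0])
        idx_hi.append(nz[-1])
    corners_ijk = np.array([[idx_lo[a] if bit & (1 << a) == 0 else idx_hi[a] for a in range(3)] for bit in range(8)])
    corners_world = volume.world_coordinates(corners_ijk)
    corners_canon = transform.apply(corners_world)
    # snap the output grid to the canonical lattice (centres at integer
    # multiples of the spacing): the AC lands on a voxel centre, and
    # resampling an already-aligned lattice is exact
    origin = np.floor((corners_canon.min(axis=0) - margin * spacing) / spacing) * spacing
    hi = corners_canon.max(axis=0) + margin * spacing
    shape = np.floor((hi - origin) / spacing).astype(int) + 1
    return origin, shape


def _sample_indices(
    volume: LabelVolume, transform: RigidTransform, origin: np.ndarray, shape: np.ndarray, spacing: np.ndarray
) -> np.ndarray:
    """Fractional input-voxel indices for every output voxel centre."""
    inv = transform.inverse()
    A_inv = np.linalg.inv(volume.affine)
    # canonical -> world -> voxel index, composed into one affine map
    M = A_inv[:3, :3] @ inv.rotation
    c = A_inv[:3, :3] @ inv.translation + A_inv[:3, 3]
    axes = [(origin[a] + np.arange(shape[a]) * spacing[a]).astype(np.float32) for a in range(3)]
    ijk = np.empty((3, *shape), dtype=np.float32)
    for a in range(3):
        ijk[a] = (
            M[a, 0] * axes[0][:, None, None]
            + M[a, 1] * axes[1][None, :, None]
            + M[a, 2] * axes[2][None, None, :]
            + c[a]
        )
    return ijk


def resample_labels(
    volume: LabelVolume,
    transform: RigidTransform,
    spacing: np.ndarray | None = None,
    *,
    margin: int = 1,
    acpc_length_mm: float | None = None,
) -> AlignedVolume:
    """Resample a label volume into the canonical frame (nearest-neighbour).

    The output grid covers the transformed head bounding box plus a
    ``margin``-voxel border; the label set is preserved or reduced, never
    extended.
    """
    spacing = np.asarray(volume.spacing if spacing is None else spacing, dtype=float).reshape(3)
    if np.any(spacing <= 0):
        raise VentmorphError("requested spacing must be positive")
    origin, shape = _output_grid(volume, transform, spacing, margin)
    ijk = _sample_indices(volume, transform, origin, shape, spacing)
    out = ndimage.map_coordinates(volume.data, ijk, order=0, mode="constant", cval=0)
    return AlignedVolume(data=out, spacing=spacing, origin=origin, acpc_length_mm=acpc_length_mm)


def resample_intensity(
    data: np.ndarray,
    affine: np.ndarray,
    transform: RigidTransform,
    spacing: np.ndarray | None = None,
    *,
    margin: int = 1,
) -> AlignedVolume:
    """Trilinear resampling for intensity images (same grid policy as labels)."""
    shell = LabelVolume(data=(np.asarray(data) != 0).astype(np.int16), affine=affine)
    spacing = np.asarray(shell.spacing if spacing is None else spacing, dtype=float).reshape(3)
    if np.any(spacing <= 0):
        raise VentmorphError("requested spacing must be positive")
    origin, shape = _output_grid(shell, transform, spacing, margin)
    ijk = _sample_indices(shell, transform, origin, shape, spacing)
    out = ndimage.map_coordinates(np.asarray(data, dtype=float), ijk, order=1, mode="constant", cval=0.0)
    return AlignedVolume(data=out, spacing=spacing, origin=origin)


def align_volume(
    volume: LabelVolume, landmarks: LandmarkSet, spacing: np.ndarray | None = None
) -> AlignedVolume:
    """Estimate the ACPC transform from landmarks and resample in one call."""
    tf = compute_acpc_transform(landmarks)
    return resample_labels(volume, tf, spacing, acpc_length_mm=landmarks.acpc_length_mm)
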