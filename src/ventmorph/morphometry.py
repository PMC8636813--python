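"""Linear ventricular indices measured in the canonical ACPC frame.

Six indices are computed from an :class:`~ventmorph.acpc.AlignedVolume`:

* Evans index (EI): maximal frontal-horn width / maximal internal cranial
  width, both searched over axial slices;
* bicaudate index (BCI): maximal ventricular width over axial-plane lines
  between PC and AC / brain width along the same line (the intercaudate line
  is approximated this way because no caudate segmentation is available);
* callosal angle (CA): angle between least-squares lines fitted to the two
  ventricular roofs on the coronal slice through PC;
* z-Evans index: maximal per-column ventricular height / maximal internal
  cranial height on the coronal slice through AC;
* brain-per-ventricle ratio (BVR) at AC and at PC: maximal brain thickness
  above the ventricles / maximal ventricular height on the level's coronal
  slice.

Conventions, applied uniformly: extents are distances between extreme voxel
*centres* times the spacing; ties in "maximal" searches break toward the
slice or column closest to AC; the cranium interior is recovered by filling
the head mask and removing the shell label, with the brain+ventricle mask as
a fallback (flagged in the measurement's ``method`` tag) when no shell label
exists.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage

from .acpc import AlignedVolume
from .errors import (
    DegenerateRoofError,
    InvalidGeometryError,
    MissingLabelError,
    MorphometryError,
    VentmorphError,
)
from .image import BRAIN, CRANIUM_SHELL, VENTRICLE
from .volumetry import ventricular_volume

_FLAT_SLOPE = 1e-6


@dataclass(frozen=True)
class IndexMeasurement:
    """One measured index with its component lengths and provenance."""

    value: float
    numerator_mm: float | None
    denominator_mm: float | None
    slice_mm: float | None
    method: str
    extras: dict = field(default_factory=dict)


@dataclass(frozen=True)
class MorphometricResult:
    """All six indices plus ventricular volume for one aligned scan."""

    ei: IndexMeasurement
    bci: IndexMeasurement
    ca: IndexMeasurement | None
    z_evans: IndexMeasurement
    bvr_ac: IndexMeasurement
    bvr_pc: IndexMeasurement
    ventricle_volume_cm3: float

    @property
    def bvr_pc_brain_mm(self) -> float:
        return float(self.bvr_pc.numerator_mm)

    @property
    def bvr_pc_ventricle_mm(self) -> float:
        return float(self.bvr_pc.denominator_mm)

    def to_dict(self) -> dict:
        def enc(m: IndexMeasurement | None) -> dict | None:
            if m is None:
                return None
            return {
                "value": m.value,
                "numerator_mm": m.numerator_mm,
                "denominator_mm": m.denominator_mm,
                "slice_mm": m.slice_mm,
                "method": m.method,
                **({"extras": m.extras} if m.extras else {}),
            }

        return {
            "ei": enc(self.ei),
            "bci": enc(self.bci),
            "callosal_angle": enc(self.ca),
            "z_evans": enc(self.z_evans),
            "bvr_ac": enc(self.bvr_ac),
            "bvr_pc": enc(self.bvr_pc),
            "ventricle_volume_cm3": self.ventricle_volume_cm3,
        }

    def to_row(self) -> dict:
        """Flat mapping for one CSV row (values, components in mm, volume in cm3)."""
        row: dict = {}
        for name in ("ei", "bci", "z_evans", "bvr_ac", "bvr_pc"):
            m: IndexMeasurement = getattr(self, name)
            row[name] = m.value
            row[f"{name}_numerator_mm"] = m.numerator_mm
            row[f"{name}_denominator_mm"] = m.denominator_mm
        row["ca_deg"] = self.ca.value if self.ca is not None else np.nan
        row["bvr_pc_brain_mm"] = self.bvr_pc_brain_mm
        row["bvr_pc_ventricle_mm"] = self.bvr_pc_ventricle_mm
        row["ventricular_volume_cm3"] = self.ventricle_volume_cm3
        return row


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _require_acpc(aligned: AlignedVolume) -> float:
    if aligned.acpc_length_mm is None:
        raise VentmorphError("AlignedVolume has no AC-PC length; align with landmarks first")
    return float(aligned.acpc_length_mm)


def _cranium_interior(aligned: AlignedVolume) -> tuple[np.ndarray, str]:
    shell = aligned.data == CRANIUM_SHELL
    if shell.any():
        filled = ndimage.binary_fill_holes(aligned.data > 0)
        return filled & ~shell, "cranium-interior"
    return (aligned.data == BRAIN) | (aligned.data == VENTRICLE), "brain-fallback"


def _extent_mm(indices: np.ndarray, spacing: float) -> float:
    """Distance between extreme voxel centres along one axis."""
    return float((indices.max() - indices.min()) * spacing)


def _max_extent_over_slices(
    plane_mask: np.ndarray, extent_spacing: float, slice_coords: np.ndarray
) -> tuple[float, float]:
    """Max extent along axis 0 of a (extent_axis, slice_axis) boolean array.

    Returns (extent_mm, coordinate of the maximising slice); ties break toward
    the slice with coordinate closest to zero (the AC).
    """
    n_slices = plane_mask.shape[1]
    best = -1.0
    best_coord = None
    for j in range(n_slices):
        idx = np.nonzero(plane_mask[:, j])[0]
        if idx.size == 0:
            continue
        ext = _extent_mm(idx, extent_spacing)
        coord = slice_coords[j]
        if ext > best or (ext == best and best_coord is not None and abs(coord) < abs(best_coord)):
            best, best_coord = ext, coord
    if best_coord is None:
        raise MissingLabelError("mask empty in every slice")
    return best, float(best_coord)


def _column_extents(slice_mask: np.ndarray, spacing: float, min_voxels: int = 1) -> dict[int, float]:
    """Per-column extent (axis 1) of a 2D boolean slice, keyed by column index.

    ``min_voxels`` sets the minimal support for a column to count as
    intersecting the mask; measurements that read a column's *top* use 3 so
    that isolated voxels from nearest-neighbour resampling of oblique walls
    cannot masquerade as a column.
    """
    out: dict[int, float] = {}
    for i in np.nonzero(slice_mask.any(axis=1))[0]:
        idx = np.nonzero(slice_mask[i])[0]
        if idx.size < min_voxels:
            continue
        out[int(i)] = _extent_mm(idx, spacing)
    return out


def _filtered_tops(slice_mask: np.ndarray, x: np.ndarray, min_voxels: int = 3) -> dict[int, float]:
    """Per-column topmost voxel index, median-filtered over a 3-column window.

    Nearest-neighbour resampling of oblique walls leaves partial columns
    whose top sits anywhere along the wall; the median over each column and
    its recorded neighbours rejects such outliers while distorting a genuine
    sloped roof by at most one column's drop.  The two hemispheres are
    filtered independently (a medial partial column must not validate its
    mirror image across the septum), and a boundary column is kept only when
    both its top and its voxel support are consistent with its inner
    neighbour.
    """
    all_cols = [int(i) for i in np.nonzero(slice_mask.any(axis=1))[0] if np.count_nonzero(slice_mask[i]) >= min_voxels]
    counts = {i: int(np.count_nonzero(slice_mask[i])) for i in all_cols}
    tops = {i: float(np.nonzero(slice_mask[i])[0].max()) for i in all_cols}
    filtered: dict[int, float] = {}
    for side in (lambda i: x[i] < 0, lambda i: x[i] >= 0):
        cols = [i for i in all_cols if side(i)]
        if len(cols) < 3:
            filtered.update({i: tops[i] for i in cols})
            continue
        for pos in range(1, len(cols) - 1):
            window = [tops[cols[pos - 1]], tops[cols[pos]], tops[cols[pos + 1]]]
            filtered[cols[pos]] = float(np.median(window))
        for edge, inner in ((cols[0], cols[1]), (cols[-1], cols[-2])):
            if (
                abs(tops[edge] - filtered.get(inner, tops[inner])) <= 2.5
                and counts[edge] >= 0.6 * counts[inner]
            ):
                filtered[edge] = tops[edge]
    return filtered


def _argmax_near_ac(candidates: dict[int, float], coords: np.ndarray) -> int:
    """Key with maximal value; ties break toward the coordinate nearest zero."""
    best_key, best_val = None, -np.inf
    for k, v in candidates.items():
        if v > best_val or (v == best_val and abs(coords[k]) < abs(coords[best_key])):
            best_key, best_val = k, v
    return best_key


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def frontal_horn_mask(aligned: AlignedVolume) -> np.ndarray:
    """Ventricle voxels anterior to the AC (y > 0)."""
    vent = aligned.data == VENTRICLE
    if not vent.any():
        raise MissingLabelError("no ventricle label in volume")
    y = aligned.coords(1)
    mask = vent & (y[None, :, None] > 0)
    if not mask.any():
        raise MissingLabelError("no frontal horn: ventricle entirely posterior to AC")
    return mask


def evans_index(aligned: AlignedVolume) -> IndexMeasurement:
    """EI: maximal frontal-horn width over maximal internal cranial width (axial)."""
    horns = frontal_horn_mask(aligned)
    sx = aligned.spacing[0]
    z = aligned.coords(2)
    num, z_at = _max_extent_over_slices(horns.any(axis=1), sx, z)
    interior, tag = _cranium_interior(aligned)
    if not interior.any():
        raise MissingLabelError("no cranium interior found")
    den, _ = _max_extent_over_slices(interior.any(axis=1), sx, z)
    if num <= 0 or den <= 0:
        raise InvalidGeometryError("degenerate extent (single-voxel width)")
    return IndexMeasurement(num / den, num, den, z_at, f"evans-index/{tag}")


def bicaudate_index(aligned: AlignedVolume) -> IndexMeasurement:
    """BCI on the ACPC axial plane (z = 0), searching lines between PC and AC."""
    d = _require_acpc(aligned)
    iz = aligned.nearest_index(2, 0.0)
    sl = aligned.data[:, :, iz]
    sx, sy = aligned.spacing[0], aligned.spacing[1]
    y = aligned.coords(1)
    rows = np.nonzero((y >= -d - sy / 2) & (y <= sy / 2))[0]
    vent = sl == VENTRICLE
    brain = (sl == BRAIN) | vent
    candidates: dict[int, float] = {}
    for j in rows:
        idx = np.nonzero(vent[:, j])[0]
        if idx.size:
            candidates[int(j)] = _extent_mm(idx, sx)
    if not candidates:
        raise MissingLabelError("ventricle absent from the ACPC axial plane")
    j = _argmax_near_ac(candidates, y)
    num = candidates[j]
    bidx = np.nonzero(brain[:, j])[0]
    if bidx.size == 0:
        raise MissingLabelError("brain absent on the intercaudate line")
    den = _extent_mm(bidx, sx)
    if num <= 0 or den <= 0:
        raise InvalidGeometryError("degenerate extent on the intercaudate line")
    value = num / den
    if value >= 1.0:
        raise InvalidGeometryError(f"BCI {value:.3f} >= 1: ventricle wider than brain")
    return IndexMeasurement(value, num, den, float(y[j]), "bicaudate-index")


def callosal_angle(aligned: AlignedVolume) -> IndexMeasurement:
    """CA from least-squares roof lines on the coronal slice through PC."""
    d = _require_acpc(aligned)
    iy = aligned.nearest_index(1, -d)
    sl = aligned.data[:, iy, :] == VENTRICLE
    if not sl.any():
        raise MissingLabelError("ventricle absent from the PC coronal slice")
    x = aligned.coords(0)
    z = aligned.coords(2)
    tops = _filtered_tops(sl, x)
    z0, sz = aligned.origin[2], aligned.spacing[2]
    slopes = []
    for side_sign in (-1, 1):
        cols = np.array([i for i in tops if np.sign(x[i]) == side_sign], dtype=int)
        if cols.size < 3:
            raise DegenerateRoofError(f"fewer than 3 roof columns on one side (got {cols.size})")
        roof_z = np.array([z0 + tops[i] * sz for i in cols])
        slope = np.polyfit(x[cols], roof_z, 1)[0]
        slopes.append(float(slope))
    b_left, b_right = slopes
    if abs(b_left) < _FLAT_SLOPE and abs(b_right) < _FLAT_SLOPE:
        raise DegenerateRoofError("degenerate flat roof")
    # unit roof directions oriented from the midline laterally
    cosang = (-1.0 - b_left * b_right) / np.sqrt((1 + b_left**2) * (1 + b_right**2))
    value = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return IndexMeasurement(
        value, None, None, float(-d), "callosal-angle/lsq-roof",
        extras={"slope_left": b_left, "slope_right": b_right},
    )


def z_evans_index(aligned: AlignedVolume) -> IndexMeasurement:
    """z-Evans: per-column ventricular height over cranial height at the AC slice."""
    iy = aligned.nearest_index(1, 0.0)
    vent = aligned.data[:, iy, :] == VENTRICLE
    if not vent.any():
        raise MissingLabelError("ventricle absent from the AC coronal slice")
    interior, tag = _cranium_interior(aligned)
    interior_sl = interior[:, iy, :]
    if not interior_sl.any():
        raise MissingLabelError("cranium interior absent from the AC coronal slice")
    sz = aligned.spacing[2]
    x = aligned.coords(0)
    vents = _column_extents(vent, sz)
    i = _argmax_near_ac(vents, x)
    num = vents[i]
    den = max(_column_extents(interior_sl, sz).values())
    if num <= 0 or den <= 0:
        raise InvalidGeometryError("degenerate z extent")
    return IndexMeasurement(num / den, num, den, float(x[i]), f"z-evans/{tag}")


def bvr(aligned: AlignedVolume, level: str) -> IndexMeasurement:
    """Brain-per-ventricle ratio at the AC or PC coronal level.

    V is the maximal per-column ventricular height among columns intersecting
    the ventricle; B is the maximal brain-top-minus-ventricle-top height over
    those same columns; the ratio is B / V.
    """
    level = level.upper()
    if level not in ("AC", "PC"):
        raise VentmorphError(f"level must be 'AC' or 'PC', got {level!r}")
    y_level = 0.0 if level == "AC" else -_require_acpc(aligned)
    iy = aligned.nearest_index(1, y_level)
    sl = aligned.data[:, iy, :]
    vent = sl == VENTRICLE
    if not vent.any():
        raise MissingLabelError(f"ventricle absent at the {level} coronal level")
    brain = (sl == BRAIN) | vent
    sz = aligned.spacing[2]
    x = aligned.coords(0)
    vents = _column_extents(vent, sz, min_voxels=3)
    if not vents:
        raise MissingLabelError(f"no supported ventricle column at the {level} coronal level")
    i_v = _argmax_near_ac(vents, x)
    V = vents[i_v]
    vent_tops = _filtered_tops(vent, x)
    brain_tops = _filtered_tops(brain, x)
    B = -np.inf
    for i in vent_tops:
        if i in brain_tops:
            B = max(B, (brain_tops[i] - vent_tops[i]) * sz)
    if V <= 0:
        raise InvalidGeometryError("degenerate ventricular height")
    if B <= 0:
        raise InvalidGeometryError("ventricle reaches the brain surface (B <= 0)")
    return IndexMeasurement(B / V, float(B), float(V), float(y_level), f"bvr-{level.lower()}")


def measure_all(aligned: AlignedVolume, *, skip_degenerate_ca: bool = False) -> MorphometricResult:
    """All indices plus voxel-count ventricular volume; deterministic.

    Member errors propagate with the failing index named; flat-roof phantoms
    may set ``skip_degenerate_ca`` to record the callosal angle as missing
    instead of failing.
    """
    ops: dict[str, Callable[[], IndexMeasurement]] = {
        "ei": lambda: evans_index(aligned),
        "bci": lambda: bicaudate_index(aligned),
        "ca": lambda: callosal_angle(aligned),
        "z_evans": lambda: z_evans_index(aligned),
        "bvr_ac": lambda: bvr(aligned, "AC"),
        "bvr_pc": lambda: bvr(aligned, "PC"),
    }
    results: dict[str, IndexMeasurement | None] = {}
    for name, op in ops.items():
        try:
            results[name] = op()
        except DegenerateRoofError:
            if name == "ca" and skip_degenerate_ca:
                results[name] = None
            else:
                raise
        except VentmorphError as exc:
            raise MorphometryError(f"{name}: {exc}") from exc
    report = ventricular_volume(aligned.to_label_volume(), VENTRICLE)
    return MorphometricResult(
        ei=results["ei"],
        bci=results["bci"],
        ca=results["ca"],
        z_evans=results["z_evans"],
        bvr_ac=results["bvr_ac"],
        bvr_pc=results["bvr_pc"],
        ventricle_volume_cm3=report.volume_cm3,
    )
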