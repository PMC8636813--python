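"""Synthetic head phantoms with analytically known morphometry.

The phantom is a deliberately simple head model whose measured extents are
controlled in closed form, so every downstream stage (alignment, index
measurement, volumetry) can be validated without any imaging data:

* cranium: an axis-aligned box or ellipsoid interior wrapped in a shell of
  finite thickness (label 3), centred on the midpoint of the AC-PC segment;
* brain: an axis-aligned box (label 1) strictly inside the cranium interior;
* ventricles: a bilaterally symmetric pair (label 2) strictly inside the
  brain.  Three shapes are supported: ``box`` and ``wedge_roof`` are prisms
  extruded along y with separate frontal-horn (y > 0) and body (y <= 0)
  widths; ``ellipsoid`` is a mirrored pair of true 3D ellipsoids.

The phantom frame *is* the canonical ACPC frame (AC at the origin, PC at
(0, -d, 0)); an optional rigid pose is applied only through the exported
affine and landmarks, which is exactly how a scanner acquisition differs from
the workstation-aligned frame.

Anatomical realism is out of scope: only the measured extents need to be
analytically controlled.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.spatial.transform import Rotation

from .acpc import LandmarkSet
from .errors import PhantomSpecError
from .image import BRAIN, CRANIUM_SHELL, INTENSITY_LEVELS, VENTRICLE, LabelVolume

VentricleShape = Literal["box", "ellipsoid", "wedge_roof"]
CraniumShape = Literal["box", "ellipsoid"]

#: fraction of the cranium half-widths used for the brain box inside an
#: ellipsoidal cranium (box corners must stay inside the ellipsoid)
_ELLIPSOID_BRAIN_FRACTION = 0.55


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters for one phantom; all lengths in mm."""

    cranium_halfwidths_mm: tuple[float, float, float] = (70.0, 85.0, 60.0)
    cranium_shape: CraniumShape = "box"
    ventricle_shape: VentricleShape = "wedge_roof"
    horn_width_mm: float = 53.0        # outer-to-outer frontal-horn x width
    body_width_mm: float = 32.0        # outer-to-outer ventricle x width at body level
    septum_gap_mm: float = 8.0         # midline gap between the two ventricles
    horn_zextent_mm: float = 50.0      # maximal ventricular height
    horn_anterior_extent_mm: float = 18.0   # ventricle reach anterior to AC
    posterior_extent_mm: float = 10.0  # prism reach posterior to PC (box/wedge)
    frontal_onset_mm: float = 2.0      # y where the frontal width takes over (keeps the
                                       # width discontinuity off the AC measurement plane)
    roof_slope_s: float = 0.7          # |dz/dx| of each roof (wedge_roof only)
    brain_above_ventricle_mm: float = 32.0  # brain-box top minus ventricle top
    brain_margin_mm: float = 3.0       # brain-box inset from a box cranium interior
    shell_thickness_mm: float = 4.0
    acpc_length_mm: float = 25.0
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    pose_rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    pose_translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    # ---- derived geometry -------------------------------------------------
    @property
    def brain_halfwidths_mm(self) -> np.ndarray:
        C = np.asarray(self.cranium_halfwidths_mm, dtype=float)
        if self.cranium_shape == "ellipsoid":
            return C * _ELLIPSOID_BRAIN_FRACTION
        return C - self.brain_margin_mm

    @property
    def ventricle_top_mm(self) -> float:
        """z of the ventricular roof peak (brain box is centred at z = 0)."""
        return float(self.brain_halfwidths_mm[2] - self.brain_above_ventricle_mm)

    @property
    def frontal_slot_mm(self) -> float:
        return (self.horn_width_mm - self.septum_gap_mm) / 2.0

    @property
    def body_slot_mm(self) -> float:
        return (self.body_width_mm - self.septum_gap_mm) / 2.0

    @property
    def landmarks(self) -> LandmarkSet:
        """Landmarks in the phantom (canonical) frame."""
        d = self.acpc_length_mm
        return LandmarkSet(ac=(0.0, 0.0, 0.0), pc=(0.0, -d, 0.0), midsagittal=(0.0, 0.0, 40.0))

    @property
    def pose_matrix(self) -> np.ndarray:
        """4x4 rigid pose applied at export (canonical -> world)."""
        M = np.eye(4)
        M[:3, :3] = Rotation.from_euler("xyz", self.pose_rotation_deg, degrees=True).as_matrix()
        M[:3, 3] = self.pose_translation_mm
        return M

    # ---- validation -------------------------------------------------------
    def validate(self) -> None:
        C = np.asarray(self.cranium_halfwidths_mm, dtype=float)
        B = self.brain_halfwidths_mm
        d = self.acpc_length_mm
        sp = np.asarray(self.spacing_mm, dtype=float)
        positives = {
            "cranium_halfwidths_mm": C.min(),
            "horn_width_mm": self.horn_width_mm,
            "body_width_mm": self.body_width_mm,
            "septum_gap_mm": self.septum_gap_mm,
            "horn_zextent_mm": self.horn_zextent_mm,
            "horn_anterior_extent_mm": self.horn_anterior_extent_mm,
            "posterior_extent_mm": self.posterior_extent_mm,
            "brain_above_ventricle_mm": self.brain_above_ventricle_mm,
            "shell_thickness_mm": self.shell_thickness_mm,
            "acpc_length_mm": d,
            "spacing_mm": sp.min(),
        }
        for name, value in positives.items():
            if not value > 0:
                raise PhantomSpecError(f"{name} must be positive (got {value})")
        if self.ventricle_shape == "wedge_roof" and self.roof_slope_s < 0:
            raise PhantomSpecError("wedge_roof requires roof_slope_s >= 0")
        if not 0.0 <= self.frontal_onset_mm < self.horn_anterior_extent_mm:
            raise PhantomSpecError("frontal_onset_mm must lie in [0, horn_anterior_extent_mm)")
        if np.any(B <= 0):
            raise PhantomSpecError("brain box collapses; enlarge cranium or shrink margin")
        if self.frontal_slot_mm <= 0 or self.body_slot_mm <= 0:
            raise PhantomSpecError("ventricle widths must exceed the septum gap")

        z_top = self.ventricle_top_mm
        h = self.horn_zextent_mm
        z_floor = z_top - h
        # ventricle strictly inside brain
        half_w = max(self.horn_width_mm, self.body_width_mm) / 2.0
        y_ant = self.horn_anterior_extent_mm
        y_post = self._posterior_limit()
        if not (half_w < B[0] and y_ant < B[1] - d / 2.0 and y_post > -d / 2.0 - B[1]):
            raise PhantomSpecError("ventricle is not strictly inside the brain (x/y)")
        if not (z_top < B[2] and z_floor > -B[2]):
            raise PhantomSpecError("ventricle is not strictly inside the brain (z)")
        # the ACPC axial plane must pass through the ventricle body
        if not (z_floor < 0.0 < z_top):
            raise PhantomSpecError("ACPC plane (z=0) does not intersect the ventricle body")
        if self.ventricle_shape == "wedge_roof":
            if self.roof_slope_s * self.frontal_slot_mm >= h:
                raise PhantomSpecError("wedge roof reaches the floor within the frontal horn")
            if self.roof_slope_s * self.body_slot_mm > z_top:
                raise PhantomSpecError("wedge roof dips below the ACPC plane at body level")
        # brain box strictly inside the cranium interior
        if self.cranium_shape == "box":
            if np.any(B >= C):
                raise PhantomSpecError("brain is not strictly inside the cranium")
        else:
            if float(np.sum((B / C) ** 2)) >= 1.0:
                raise PhantomSpecError("brain box corner pierces the ellipsoidal cranium")
        # voxel sampling must resolve every ventricle extent
        smallest = min(self.frontal_slot_mm, self.body_slot_mm, self.septum_gap_mm, h, y_ant)
        if sp.max() >= smallest:
            raise PhantomSpecError(
                f"spacing {sp.max()} mm is coarser than the smallest ventricle extent {smallest} mm"
            )

    def _posterior_limit(self) -> float:
        if self.ventricle_shape == "ellipsoid":
            return -self.acpc_length_mm - self.horn_anterior_extent_mm
        return -self.acpc_length_mm - self.posterior_extent_mm

    def scaled(self, k: float) -> "PhantomSpec":
        """All linear extents (and spacing, pose translation) multiplied by k."""
        return replace(
            self,
            cranium_halfwidths_mm=tuple(k * c for c in self.cranium_halfwidths_mm),
            horn_width_mm=k * self.horn_width_mm,
            body_width_mm=k * self.body_width_mm,
            septum_gap_mm=k * self.septum_gap_mm,
            horn_zextent_mm=k * self.horn_zextent_mm,
            horn_anterior_extent_mm=k * self.horn_anterior_extent_mm,
            posterior_extent_mm=k * self.posterior_extent_mm,
            frontal_onset_mm=k * self.frontal_onset_mm,
            brain_above_ventricle_mm=k * self.brain_above_ventricle_mm,
            brain_margin_mm=k * self.brain_margin_mm,
            shell_thickness_mm=k * self.shell_thickness_mm,
            acpc_length_mm=k * self.acpc_length_mm,
            spacing_mm=tuple(k * s for s in self.spacing_mm),
            pose_translation_mm=tuple(k * t for t in self.pose_translation_mm),
        )


@dataclass(frozen=True)
class AnalyticTruth:
    """Closed-form index values for a :class:`PhantomSpec` (pre-voxelization)."""

    ei: float
    ei_numerator_mm: float
    ei_denominator_mm: float
    bci: float
    bci_numerator_mm: float
    bci_denominator_mm: float
    ca_deg: float | None
    z_evans: float
    z_evans_numerator_mm: float
    z_evans_denominator_mm: float
    bvr_ac: float
    bvr_pc: float
    bvr_brain_mm: float
    bvr_ventricle_mm: float
    ventricle_volume_cm3: float


def analytic_truth(spec: PhantomSpec) -> AnalyticTruth:
    """Derive every index in closed form from the generative parameters."""
    spec.validate()
    C = np.asarray(spec.cranium_halfwidths_mm, dtype=float)
    B = spec.brain_halfwidths_mm
    d = spec.acpc_length_mm
    g = spec.septum_gap_mm
    h = spec.horn_zextent_mm
    z_top = spec.ventricle_top_mm
    s = spec.roof_slope_s
    shape = spec.ventricle_shape

    # cranium-interior extents; maxima over slices pass through the centre
    ei_den = 2.0 * C[0]
    if spec.cranium_shape == "box":
        z_den = 2.0 * C[2]
    else:  # coronal slice through AC sits d/2 anterior of the cranium centre
        z_den = 2.0 * C[2] * math.sqrt(max(0.0, 1.0 - (d / (2.0 * C[1])) ** 2))

    if shape == "ellipsoid":
        a = (spec.horn_width_mm - g) / 4.0
        by = spec.horn_anterior_extent_mm + d / 2.0
        c = h / 2.0
        cz = z_top - c
        k_y = math.sqrt(max(0.0, 1.0 - (d / (2.0 * by)) ** 2))
        k_z = math.sqrt(max(0.0, 1.0 - (cz / c) ** 2))
        ei_num = g + 2.0 * a * (1.0 + k_y)
        bci_num = g + 2.0 * a * (1.0 + k_z)
        z_num = 2.0 * c * k_y
        V = z_num
        Bmm = spec.brain_above_ventricle_mm + c
        ca = None
        volume_mm3 = 2.0 * (4.0 / 3.0) * math.pi * a * by * c
    else:
        w_f, w_b = spec.frontal_slot_mm, spec.body_slot_mm
        length_f = spec.horn_anterior_extent_mm - spec.frontal_onset_mm
        length_b = d + spec.posterior_extent_mm + spec.frontal_onset_mm
        # the anterior-of-AC search also sees the body cross-section within the
        # onset strip, so the attainable maximum is the wider of the two
        if spec.frontal_onset_mm > 0:
            ei_num = max(spec.horn_width_mm, spec.body_width_mm)
        else:
            ei_num = spec.horn_width_mm
        bci_num = spec.body_width_mm
        z_num = h
        V = h
        if shape == "wedge_roof":
            Bmm = spec.brain_above_ventricle_mm + s * w_b
            ca = 180.0 - 2.0 * math.degrees(math.atan(s)) if s > 0 else None
            area_f = 2.0 * (w_f * h - 0.5 * s * w_f**2)
            area_b = 2.0 * (w_b * h - 0.5 * s * w_b**2)
        else:
            Bmm = spec.brain_above_ventricle_mm
            ca = None
            area_f = 2.0 * w_f * h
            area_b = 2.0 * w_b * h
        volume_mm3 = area_f * length_f + area_b * length_b

    bci_den = 2.0 * B[0]
    truth = AnalyticTruth(
        ei=ei_num / ei_den,
        ei_numerator_mm=ei_num,
        ei_denominator_mm=ei_den,
        bci=bci_num / bci_den,
        bci_numerator_mm=bci_num,
        bci_denominator_mm=bci_den,
        ca_deg=ca,
        z_evans=z_num / z_den,
        z_evans_numerator_mm=z_num,
        z_evans_denominator_mm=z_den,
        bvr_ac=Bmm / V,
        bvr_pc=Bmm / V,  # AC and PC slices see the same cross-section by construction
        bvr_brain_mm=Bmm,
        bvr_ventricle_mm=V,
        ventricle_volume_cm3=volume_mm3 / 1000.0,
    )
    for name in ("ei", "bci", "z_evans"):
        v = getattr(truth, name)
        if not 0.0 < v < 1.0:
            raise PhantomSpecError(f"analytic {name} = {v:.3f} outside (0, 1)")
    return truth


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------


@dataclass
class Phantom:
    labels: LabelVolume
    intensity: np.ndarray
    landmarks: LandmarkSet
    truth: AnalyticTruth

    @property
    def affine(self) -> np.ndarray:
        return self.labels.affine


def _ventricle_mask(spec: PhantomSpec, X: np.ndarray, Y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    g2 = spec.septum_gap_mm / 2.0
    h = spec.horn_zextent_mm
    z_top = spec.ventricle_top_mm
    ax = np.abs(X)
    if spec.ventricle_shape == "ellipsoid":
        a = (spec.horn_width_mm - spec.septum_gap_mm) / 4.0
        by = spec.horn_anterior_extent_mm + spec.acpc_length_mm / 2.0
        c = h / 2.0
        cx, cy, cz = g2 + a, -spec.acpc_length_mm / 2.0, z_top - c
        return ((ax - cx) / a) ** 2 + ((Y - cy) / by) ** 2 + ((Z - cz) / c) ** 2 < 1.0
    frontal = Y > spec.frontal_onset_mm
    slot = np.where(frontal, spec.frontal_slot_mm, spec.body_slot_mm)
    in_y = (Y > spec._posterior_limit()) & (Y < spec.horn_anterior_extent_mm)
    in_x = (ax > g2) & (ax < g2 + slot)
    if spec.ventricle_shape == "wedge_roof":
        roof = z_top - spec.roof_slope_s * (ax - g2)
    else:
        roof = np.full_like(Z, z_top)
    in_z = (Z > z_top - h) & (Z < roof)
    return in_y & in_x & in_z


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Voxelize a spec into label + intensity volumes with analytic truth.

    The truth is computed in closed form from the spec *before* voxelization;
    the exported affine carries the rigid pose.
    """
    truth = analytic_truth(spec)  # also validates
    C = np.asarray(spec.cranium_halfwidths_mm, dtype=float)
    sp = np.asarray(spec.spacing_mm, dtype=float)
    d = spec.acpc_length_mm
    centre = np.array([0.0, -d / 2.0, 0.0])
    outer = C + spec.shell_thickness_mm

    # the voxel grid is axis-aligned in the *world* (scanner) frame; the head
    # sits in it at the spec's pose, exactly as an acquisition would
    pose = spec.pose_matrix
    corners = np.array(
        [centre + outer * np.array([sx, sy, sz]) for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
    )
    corners_world = corners @ pose[:3, :3].T + pose[:3, 3]
    lo = corners_world.min(axis=0) - 2.0
    hi = corners_world.max(axis=0) + 2.0
    # voxel centres sit on integer multiples of the spacing, so realignment
    # of an unrotated scan lands exactly on the source lattice
    first = np.ceil(lo / sp) * sp
    shape = np.floor((hi - first) / sp).astype(int) + 1
    axes = [first[a] + np.arange(shape[a]) * sp[a] for a in range(3)]
    # canonical coordinates of every world voxel centre (broadcast sums)
    Rin = pose[:3, :3].T
    tin = -Rin @ pose[:3, 3]
    X = Rin[0, 0] * axes[0][:, None, None] + Rin[0, 1] * axes[1][None, :, None] + Rin[0, 2] * axes[2][None, None, :] + tin[0]
    Y = Rin[1, 0] * axes[0][:, None, None] + Rin[1, 1] * axes[1][None, :, None] + Rin[1, 2] * axes[2][None, None, :] + tin[1]
    Z = Rin[2, 0] * axes[0][:, None, None] + Rin[2, 1] * axes[1][None, :, None] + Rin[2, 2] * axes[2][None, None, :] + tin[2]

    if spec.cranium_shape == "box":
        interior = (np.abs(X) < C[0]) & (np.abs(Y - centre[1]) < C[1]) & (np.abs(Z) < C[2])
        outer_m = (np.abs(X) < outer[0]) & (np.abs(Y - centre[1]) < outer[1]) & (np.abs(Z) < outer[2])
    else:
        interior = (X / C[0]) ** 2 + ((Y - centre[1]) / C[1]) ** 2 + (Z / C[2]) ** 2 < 1.0
        outer_m = (X / outer[0]) ** 2 + ((Y - centre[1]) / outer[1]) ** 2 + (Z / outer[2]) ** 2 < 1.0

    B = spec.brain_halfwidths_mm
    brain = (np.abs(X) < B[0]) & (np.abs(Y - centre[1]) < B[1]) & (np.abs(Z) < B[2])
    vent = _ventricle_mask(spec, X, Y, Z)

    labels = np.zeros(tuple(shape), dtype=np.int16)
    labels[outer_m & ~interior] = CRANIUM_SHELL
    labels[brain] = BRAIN
    labels[vent] = VENTRICLE

    intensity = np.zeros(tuple(shape), dtype=np.int16)
    for code, level in INTENSITY_LEVELS.items():
        if code:
            intensity[labels == code] = level

    affine = np.eye(4)
    affine[:3, :3] = np.diag(sp)
    affine[:3, 3] = first

    lm = spec.landmarks
    pose_R = pose[:3, :3]
    pose_t = pose[:3, 3]
    landmarks = LandmarkSet(
        ac=pose_R @ lm.ac + pose_t,
        pc=pose_R @ lm.pc + pose_t,
        midsagittal=pose_R @ lm.midsagittal + pose_t,
    )
    return Phantom(
        labels=LabelVolume(data=labels, affine=affine),
        intensity=intensity,
        landmarks=landmarks,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# randomized specs
# ---------------------------------------------------------------------------


def random_phantom_spec(rng: np.random.Generator, shape: VentricleShape | None = None) -> PhantomSpec:
    """Random phantom in the recovery regime (moderate roof slopes, wide bodies).

    Used to validate voxel measurements against the analytic truth; parameters
    are drawn so that every closed-form extent is attainable on a 1 mm grid.
    """
    if shape is None:
        shape = ("box", "wedge_roof")[int(rng.integers(2))]
    Cx = float(rng.uniform(55, 70))
    Cy = float(rng.uniform(72, 88))
    Cz = float(rng.uniform(50, 62))
    cranium: CraniumShape = "ellipsoid" if rng.random() < 0.4 else "box"
    g = float(rng.uniform(6, 10))
    horn_width = float(rng.uniform(0.30, 0.40)) * 2 * Cx
    min_body = g + (36.0 if shape == "wedge_roof" else 28.0)
    body_width = max(float(rng.uniform(0.62, 0.78)) * horn_width, min_body)
    h = float(rng.uniform(0.32, 0.45)) * 2 * Cz
    s = float(rng.uniform(0.5, 0.9)) if shape == "wedge_roof" else 0.0
    w_b = (body_width - g) / 2.0
    Bz = Cz * _ELLIPSOID_BRAIN_FRACTION if cranium == "ellipsoid" else Cz - 3.0
    z_lo = max(0.25 * h, s * w_b + 1.5, h - Bz + 2.0)
    z_hi = max(min(0.75 * h, Bz - 2.0), z_lo + 0.5)
    z_top = float(rng.uniform(z_lo, z_hi))
    spec = PhantomSpec(
        cranium_halfwidths_mm=(Cx, Cy, Cz),
        cranium_shape=cranium,
        ventricle_shape=shape,
        horn_width_mm=horn_width,
        body_width_mm=body_width,
        septum_gap_mm=g,
        horn_zextent_mm=h,
        horn_anterior_extent_mm=float(rng.uniform(14, 20)),
        roof_slope_s=s,
        brain_above_ventricle_mm=Bz - z_top,
    )
    spec.validate()
    return spec


def nph_like_spec(rng: np.random.Generator) -> PhantomSpec:
    """Hydrocephalic regime: wide ventricles, tall horns, steep (tight) roofs."""
    h = float(rng.uniform(46, 54))
    s = float(rng.uniform(1.6, 2.0))
    body = float(rng.uniform(30, 36))
    w_b = (body - 8.0) / 2.0
    w_f = (float(53.0) - 8.0) / 2.0
    s = min(s, 0.85 * h / w_f, 0.9 * (57.0 - 31.0) / w_b)
    return PhantomSpec(
        ventricle_shape="wedge_roof",
        horn_width_mm=float(rng.uniform(50, 56)),
        body_width_mm=body,
        horn_zextent_mm=h,
        roof_slope_s=s,
        brain_above_ventricle_mm=float(rng.uniform(29, 33)),
    )


def hc_like_spec(rng: np.random.Generator) -> PhantomSpec:
    """Healthy regime: narrow ventricles, short horns, shallow (open) roofs."""
    return PhantomSpec(
        ventricle_shape="wedge_roof",
        horn_width_mm=float(rng.uniform(36, 42)),
        body_width_mm=float(rng.uniform(22, 26)),
        horn_zextent_mm=float(rng.uniform(28, 34)),
        roof_slope_s=float(rng.uniform(0.6, 0.85)),
        brain_above_ventricle_mm=float(rng.uniform(37, 41)),
    )
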