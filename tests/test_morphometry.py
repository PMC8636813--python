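"""Index measurements on hand-built scenes and phantoms."""
from dataclasses import replace

import numpy as np
import pytest

from ventmorph import (
    AlignedVolume,
    PhantomSpec,
    bicaudate_index,
    bvr,
    callosal_angle,
    evans_index,
    frontal_horn_mask,
    make_phantom,
    measure_all,
    z_evans_index,
)
from ventmorph.errors import (
    DegenerateRoofError,
    InvalidGeometryError,
    MissingLabelError,
    MorphometryError,
)
from ventmorph.image import BRAIN, VENTRICLE

from conftest import build_aligned, fill_box


def test_frontal_horn_mask_splits_at_ac():
    al = build_aligned()
    fill_box(al, VENTRICLE, x=(-6, 6), y=(-10, 10), z=(-5, 5))
    mask = frontal_horn_mask(al)
    vent = al.data == VENTRICLE
    per_slice = vent[:, al.nearest_index(1, 0.5), :].sum()
    # box straddling AC with half its length anterior: half the voxels +/- one slice
    assert abs(int(mask.sum()) - int(vent.sum()) / 2) <= per_slice

    anterior = build_aligned()
    fill_box(anterior, VENTRICLE, x=(-6, 6), y=(2, 12), z=(-5, 5))
    assert frontal_horn_mask(anterior).sum() == (anterior.data == VENTRICLE).sum()

    posterior = build_aligned()
    fill_box(posterior, VENTRICLE, x=(-6, 6), y=(-15, -2), z=(-5, 5))
    with pytest.raises(MissingLabelError):
        frontal_horn_mask(posterior)


def test_bicaudate_picks_widest_line_toward_ac():
    """Ventricle widening toward AC: the maximising line is the AC line."""
    al = build_aligned(shape=(60, 60, 40), origin=(-30.0, -40.0, -20.0))
    fill_box(al, BRAIN, x=(-25, 25), y=(-35, 15), z=(-15, 15))
    y = al.coords(1)
    for j in np.nonzero((y >= -20) & (y <= 0))[0]:
        half = 4.0 + 0.4 * (20.0 + y[j])  # widest at y = 0
        sl = al.data[:, j, :]
        xm = np.abs(al.coords(0)) < half
        zm = np.abs(al.coords(2)) < 8
        sl[np.outer(xm, zm)] = VENTRICLE
    m = bicaudate_index(al)
    assert m.slice_mm == pytest.approx(0.0, abs=al.spacing[1])
    assert 0 < m.value < 1


def test_bicaudate_rejects_ventricle_wider_than_brain():
    al = build_aligned()
    fill_box(al, BRAIN, x=(-5, 5), y=(-25, 10), z=(-10, 10))
    fill_box(al, VENTRICLE, x=(-12, 12), y=(-25, 10), z=(-6, 6))
    with pytest.raises(InvalidGeometryError):
        bicaudate_index(al)


def test_flat_roof_is_degenerate():
    spec = PhantomSpec(ventricle_shape="box")
    ph = make_phantom(spec)
    al = AlignedVolume.from_label_volume(ph.labels, acpc_length_mm=spec.acpc_length_mm)
    with pytest.raises(DegenerateRoofError, match="flat roof"):
        callosal_angle(al)


def test_too_few_roof_columns_rejected():
    al = build_aligned()
    fill_box(al, VENTRICLE, x=(-2, 2), y=(-25, 5), z=(-5, 5))  # straddles midline, <3 per side
    with pytest.raises(DegenerateRoofError):
        callosal_angle(al)


def test_bvr_simple_heights():
    """B = 20 mm above a 40 mm ventricle column -> 0.5 at both levels."""
    al = build_aligned(shape=(40, 50, 80), origin=(-20.0, -35.0, -45.0))
    fill_box(al, BRAIN, x=(-18, 18), y=(-32, 12), z=(-44, 21))
    fill_box(al, VENTRICLE, x=(2, 14), y=(-32, 8), z=(-39.5, 0.5))
    for level in ("AC", "PC"):
        m = bvr(al, level)
        assert m.denominator_mm == pytest.approx(39.0, abs=1.0)  # centre-to-centre of 40 mm
        assert m.numerator_mm == pytest.approx(20.0, abs=1.5)
        assert m.value == pytest.approx(0.5, abs=0.04)


def test_bvr_rejects_ventricle_at_surface():
    al = build_aligned()
    fill_box(al, BRAIN, x=(-15, 15), y=(-25, 10), z=(-15, 10))
    fill_box(al, VENTRICLE, x=(2, 12), y=(-25, 8), z=(-10, 10))  # reaches the brain top
    with pytest.raises(InvalidGeometryError):
        bvr(al, "AC")


def test_measure_all_deterministic_and_names_failing_index(default_aligned):
    r1 = measure_all(default_aligned)
    r2 = measure_all(default_aligned)
    assert r1.to_row() == r2.to_row()
    empty = build_aligned()
    fill_box(empty, BRAIN, x=(-15, 15), y=(-25, 10), z=(-15, 15))
    with pytest.raises(MorphometryError, match="^ei"):
        measure_all(empty)


def test_default_phantom_measurements_match_truth(default_spec, default_phantom, default_aligned):
    truth = default_phantom.truth
    res = measure_all(default_aligned)
    sp = default_spec.spacing_mm[0]
    assert res.ei.value == pytest.approx(truth.ei, abs=2 * sp / truth.ei_denominator_mm)
    assert res.bci.value == pytest.approx(truth.bci, abs=2 * sp / truth.bci_denominator_mm)
    assert res.z_evans.value == pytest.approx(truth.z_evans, abs=2 * sp / truth.z_evans_denominator_mm)
    assert res.ca.value == pytest.approx(truth.ca_deg, abs=2.0)
    assert res.bvr_pc.value == pytest.approx(truth.bvr_pc, abs=2 * sp / truth.bvr_ventricle_mm)
    assert res.bvr_pc.value == pytest.approx(res.bvr_pc_brain_mm / res.bvr_pc_ventricle_mm, abs=1e-12)


def test_resolution_stability_of_evans_index():
    """Halving the voxel size changes EI by < 1% (off-lattice geometry)."""
    # half-extents keep their fractional part below one half-voxel at both
    # resolutions, so the centre-to-centre extents coincide on both grids
    base = PhantomSpec(
        cranium_halfwidths_mm=(44.3, 55.3, 38.3),
        horn_width_mm=32.6,
        body_width_mm=22.6,
        septum_gap_mm=6.6,
        horn_zextent_mm=31.7,
        horn_anterior_extent_mm=13.7,
        brain_above_ventricle_mm=20.3,
        roof_slope_s=0.55,
    )
    values = {}
    for sp in (1.0, 0.5):
        spec = replace(base, spacing_mm=(sp, sp, sp))
        ph = make_phantom(spec)
        al = AlignedVolume.from_label_volume(ph.labels, acpc_length_mm=spec.acpc_length_mm)
        values[sp] = evans_index(al).value
    assert abs(values[0.5] - values[1.0]) / values[0.5] < 0.01


def test_anisotropic_spacing_scales_z_measurements():
    """1x1x2 mm grid: z extents in mm remain correct (half as many voxels)."""
    spec = PhantomSpec(spacing_mm=(1.0, 1.0, 2.0))
    ph = make_phantom(spec)
    al = AlignedVolume.from_label_volume(ph.labels, acpc_length_mm=spec.acpc_length_mm)
    truth = ph.truth
    m = z_evans_index(al)
    assert m.numerator_mm == pytest.approx(truth.z_evans_numerator_mm, abs=2 * 2.0)
    assert m.value == pytest.approx(truth.z_evans, abs=2 * 2.0 / truth.z_evans_denominator_mm)
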