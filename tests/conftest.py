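import numpy as np
import pytest

from ventmorph import AlignedVolume, PhantomSpec, make_phantom
from ventmorph.image import BRAIN, CRANIUM_SHELL, VENTRICLE


@pytest.fixture(scope="session")
def default_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def default_phantom(default_spec):
    return make_phantom(default_spec)


@pytest.fixture(scope="session")
def default_aligned(default_spec, default_phantom):
    return AlignedVolume.from_label_volume(
        default_phantom.labels, acpc_length_mm=default_spec.acpc_length_mm
    )


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Half-size phantom at 1 mm spacing for fast I/O and CLI tests.

    Extents are deliberately off-lattice (fractional mm) so that voxelization
    does not sit exactly on face boundaries.
    """
    return PhantomSpec(
        cranium_halfwidths_mm=(35.3, 42.7, 30.3),
        horn_width_mm=26.8,
        body_width_mm=16.4,
        septum_gap_mm=4.2,
        horn_zextent_mm=25.3,
        horn_anterior_extent_mm=9.3,
        posterior_extent_mm=5.2,
        frontal_onset_mm=1.1,
        brain_above_ventricle_mm=16.2,
        brain_margin_mm=1.7,
        shell_thickness_mm=2.3,
        acpc_length_mm=12.7,
        spacing_mm=(1.0, 1.0, 1.0),
    )


def build_aligned(
    shape=(40, 40, 40),
    spacing=(1.0, 1.0, 1.0),
    origin=(-20.0, -30.0, -20.0),
    acpc_length=20.0,
):
    """Empty hand-built canonical volume for constructing tiny test scenes."""
    data = np.zeros(shape, dtype=np.int16)
    return AlignedVolume(
        data=data,
        spacing=np.asarray(spacing, dtype=float),
        origin=np.asarray(origin, dtype=float),
        acpc_length_mm=acpc_length,
    )


def fill_box(aligned, label, x=(None, None), y=(None, None), z=(None, None)):
    """Set ``label`` on voxels whose centre mm coordinates fall in the open boxes."""
    coords = [aligned.coords(a) for a in range(3)]

    def axis_mask(c, lo, hi):
        m = np.ones_like(c, dtype=bool)
        if lo is not None:
            m &= c > lo
        if hi is not None:
            m &= c < hi
        return m

    mx = axis_mask(coords[0], *x)[:, None, None]
    my = axis_mask(coords[1], *y)[None, :, None]
    mz = axis_mask(coords[2], *z)[None, None, :]
    aligned.data[mx & my & mz] = label
    return aligned
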