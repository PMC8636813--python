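"""Landmark-driven rigid realignment and label resampling."""
from dataclasses import replace

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ventmorph import (
    LandmarkSet,
    PhantomSpec,
    RigidTransform,
    align_volume,
    compute_acpc_transform,
    make_phantom,
    resample_labels,
)
from ventmorph.acpc import AlignedVolume
from ventmorph.errors import DegenerateLandmarksError, MissingLabelError, VentmorphError
from ventmorph.image import LabelVolume


def test_canonical_landmarks_give_identity():
    tf = compute_acpc_transform(LandmarkSet(ac=(0, 0, 0), pc=(0, -25, 0), midsagittal=(0, 0, 30)))
    np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(tf.translation, 0, atol=1e-12)


def test_translated_landmarks_give_pure_translation():
    tf = compute_acpc_transform(LandmarkSet(ac=(10, 5, 0), pc=(10, -20, 0), midsagittal=(10, 5, 30)))
    np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(tf.translation, (-10, -5, 0), atol=1e-12)


def test_prerotated_landmarks_recover_inverse_rotation():
    rng = np.random.default_rng(42)
    base = LandmarkSet(ac=(0, 0, 0), pc=(0, -25, 0), midsagittal=(0, 0, 30))
    for _ in range(5):
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-30, 30, 3)
        lm = LandmarkSet(ac=R @ base.ac + t, pc=R @ base.pc + t, midsagittal=R @ base.midsagittal + t)
        tf = compute_acpc_transform(lm)
        np.testing.assert_allclose(tf.rotation, R.T, atol=1e-9)
        # maps AC to origin, PC onto -y
        np.testing.assert_allclose(tf.apply(lm.ac), 0, atol=1e-9)
        np.testing.assert_allclose(tf.apply(lm.pc), (0, -25, 0), atol=1e-9)


def test_degenerate_landmarks_rejected():
    with pytest.raises(DegenerateLandmarksError):
        LandmarkSet(ac=(0, 0, 0), pc=(0, 0, 0), midsagittal=(0, 0, 30))
    with pytest.raises(DegenerateLandmarksError):
        compute_acpc_transform(LandmarkSet(ac=(0, 0, 0), pc=(0, -25, 0), midsagittal=(0, 7, 0)))


def test_rigid_transform_roundtrip_and_composition():
    rng = np.random.default_rng(7)
    pts = rng.uniform(-100, 100, (50, 3))
    a = RigidTransform(Rotation.random(random_state=rng).as_matrix(), rng.uniform(-20, 20, 3))
    b = RigidTransform(Rotation.random(random_state=rng).as_matrix(), rng.uniform(-20, 20, 3))
    np.testing.assert_allclose(a.inverse().apply(a.apply(pts)), pts, atol=1e-6)
    np.testing.assert_allclose(a.compose(b).apply(pts), a.apply(b.apply(pts)), atol=1e-6)
    # distances preserved
    d0 = np.linalg.norm(pts[0] - pts[1])
    d1 = np.linalg.norm(a.apply(pts[0]) - a.apply(pts[1]))
    assert d1 == pytest.approx(d0, abs=1e-9)


def test_identity_resample_preserves_label_counts(small_spec):
    ph = make_phantom(small_spec)
    out = resample_labels(ph.labels, RigidTransform.identity())
    ref = ph.labels.label_counts()
    got = out.to_label_volume().label_counts()
    # background depends on the output bounding grid; tissue classes are exact
    assert {k: v for k, v in got.items() if k} == {k: v for k, v in ref.items() if k}


def test_quarter_turn_pose_conserves_class_counts(small_spec):
    """90-degree posed scan, realigned: per-class voxel counts within 1%."""
    posed = replace(small_spec, pose_rotation_deg=(0.0, 0.0, 90.0))
    ph = make_phantom(posed)
    aligned = align_volume(ph.labels, ph.landmarks)
    ref = make_phantom(small_spec).labels.label_counts()
    got = aligned.to_label_volume().label_counts()
    for code, n in ref.items():
        if code == 0:
            continue  # background depends on the bounding grid
        assert got[code] == pytest.approx(n, rel=0.01)


def test_resample_rejects_bad_inputs(small_spec):
    ph = make_phantom(small_spec)
    with pytest.raises(VentmorphError):
        resample_labels(ph.labels, RigidTransform.identity(), np.array([1.0, -1.0, 1.0]))
    empty = LabelVolume(np.zeros((5, 5, 5), dtype=np.int16), np.eye(4))
    with pytest.raises(MissingLabelError):
        resample_labels(empty, RigidTransform.identity())


def test_aligned_volume_requires_axis_aligned_affine():
    aff = np.eye(4)
    aff[:3, :3] = Rotation.from_euler("z", 30, degrees=True).as_matrix()
    vol = LabelVolume(np.ones((4, 4, 4), dtype=np.int16), aff)
    with pytest.raises(VentmorphError):
        AlignedVolume.from_label_volume(vol)


def test_landmark_and_transform_json_roundtrip(tmp_path):
    lm = LandmarkSet(ac=(1.5, 2.0, -3.0), pc=(1.5, -23.0, -3.0), midsagittal=(1.5, 2.0, 40.0))
    lm2 = LandmarkSet.from_json(lm.to_json(tmp_path / "lm.json"))
    np.testing.assert_allclose(lm2.ac, lm.ac)
    tf = compute_acpc_transform(lm)
    tf2 = RigidTransform.from_json(tf.to_json(tmp_path / "tf.json"))
    np.testing.assert_allclose(tf2.rotation, tf.rotation)
    np.testing.assert_allclose(tf2.translation, tf.translation)
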