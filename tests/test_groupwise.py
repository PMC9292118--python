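"""Overlap metrics, principal-axes alignment, registration, template build."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import myotract as mt
from myotract.groupwise import (
    TemplateLevelPlan,
    build_template,
    overlap,
    principal_axis_align,
    register_pair,
    resample_to_grid,
)
from myotract.tensor_transform import SpatialTransform
from myotract.volumes import ImageVolume

# compact prolate phantom used for alignment/registration experiments:
# clearly dominant long axis and a basal taper that disambiguates the
# base-apex direction
PROLATE = dict(lv_inner_radius=3.0, lv_outer_radius=7.8, rv_wall_thickness=2.4,
               bundle_center=(0.0, 5.4), bundle_radius=2.5,
               z_extent=(-13.0, 13.0), taper=0.35)


def rigid(angles_deg, trans, scale=1.0):
    aff = np.eye(4)
    aff[:3, :3] = Rotation.from_euler("xyz", angles_deg,
                                      degrees=True).as_matrix() * scale
    aff[:3, 3] = trans
    return aff


@pytest.fixture(scope="module")
def prolate_subject():
    spec = mt.PhantomSpec(**PROLATE)
    field, tensors, dwi = mt.make_phantom(spec)
    m = mt.tensor_metrics(mt.fit_dti(dwi, spec.scheme(), field.mask))
    return {
        "anat": ImageVolume(dwi.data[..., 0], spec.affine),
        "fa": ImageVolume(m.fa, spec.affine),
        "mask": ImageVolume(field.mask.astype(float), spec.affine),
        "spec": spec,
    }


class TestOverlap:
    def test_identical_masks_are_perfect(self):
        m = np.zeros((5, 5, 5), bool)
        m[1:4, 1:4, 1:4] = True
        res = overlap(m, m)
        assert res.dice == 1.0 and res.jaccard == 1.0

    def test_disjoint_masks_are_zero(self):
        a = np.zeros((5, 5, 5), bool)
        b = np.zeros((5, 5, 5), bool)
        a[0, 0, 0] = True
        b[4, 4, 4] = True
        res = overlap(a, b)
        assert res.dice == 0.0 and res.jaccard == 0.0

    def test_hand_counted_example(self):
        a = np.zeros(6, bool).reshape(1, 2, 3)
        b = a.copy()
        a[0, 0, 0] = a[0, 0, 1] = True
        b[0, 0, 1] = b[0, 1, 0] = True
        res = overlap(a, b)
        assert res.dice == pytest.approx(0.5)
        assert res.jaccard == pytest.approx(1 / 3)

    def test_empty_union_convention(self):
        e = np.zeros((3, 3, 3), bool)
        res = overlap(e, e)
        assert res.dice == 1.0 and res.jaccard == 1.0

    def test_jaccard_dice_algebraic_identity(self):
        """J = D / (2 - D) exactly, checked on random mask pairs."""
        rng = np.random.default_rng(17)
        for _ in range(200):
            a = rng.random((6, 6, 6)) < rng.uniform(0.1, 0.9)
            b = rng.random((6, 6, 6)) < rng.uniform(0.1, 0.9)
            res = overlap(a, b)
            assert res.jaccard == pytest.approx(res.dice / (2 - res.dice),
                                                abs=1e-12)
            assert res.jaccard <= res.dice + 1e-12

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            overlap(np.zeros((3, 3, 3), bool), np.zeros((4, 4, 4), bool))


class TestPrincipalAxisAlign:
    def test_symmetric_aligned_mask_maps_to_identity_rotation(self):
        spec = mt.PhantomSpec(rv_enabled=False, bundle_enabled=False,
                              **{k: v for k, v in PROLATE.items()
                                 if k not in ("bundle_center", "bundle_radius",
                                              "rv_wall_thickness")})
        field = mt.make_helix_field(spec)
        t = principal_axis_align(ImageVolume(field.mask.astype(float),
                                             spec.affine))
        rot = t.affine[:3, :3]
        angle = np.degrees(np.arccos(np.clip((np.trace(rot) - 1) / 2, -1, 1)))
        assert angle < 1e-6

    def test_apply_and_recover_known_rotation(self, prolate_subject):
        """Pose the phantom by a known rotation; alignment must map the
        (rotated) intrinsic inertia axis back to +z."""
        t0 = principal_axis_align(prolate_subject["mask"])
        intrinsic_axis = t0.affine[:3, :3].T @ np.array([0.0, 0.0, 1.0])
        R = Rotation.from_euler("xyz", [20, -15, 10], degrees=True).as_matrix()
        pose = np.eye(4)
        pose[:3, :3] = R
        pose[:3, 3] = [1.0, -0.8, 0.5]
        # larger grid so the rotated shape is not cropped at the corners
        spec = mt.PhantomSpec(pose=pose, shape=(56, 56, 56), **PROLATE)
        field = mt.make_helix_field(spec)
        t = principal_axis_align(ImageVolume(field.mask.astype(float),
                                             spec.affine))
        z_image = t.affine[:3, :3] @ (R @ intrinsic_axis)
        angle = np.degrees(np.arccos(np.clip(z_image[2], -1, 1)))
        assert angle <= 0.5

    def test_sphere_is_deterministic(self):
        ii, jj, kk = np.meshgrid(*[np.arange(20)] * 3, indexing="ij")
        sphere = ((ii - 9.5) ** 2 + (jj - 9.5) ** 2 + (kk - 9.5) ** 2) < 49
        vol = ImageVolume(sphere.astype(float), np.eye(4))
        t1 = principal_axis_align(vol)
        t2 = principal_axis_align(vol)
        assert np.array_equal(t1.affine, t2.affine)
        assert np.allclose(np.abs(np.linalg.det(t1.affine[:3, :3])), 1.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            principal_axis_align(ImageVolume(np.zeros((4, 4, 4)), np.eye(4)))


class TestRegisterPair:
    def test_self_registration_is_identity(self, prolate_subject):
        s = prolate_subject
        t = register_pair([s["anat"], s["fa"]], [s["anat"], s["fa"]],
                          weights=[1.0, 0.5], model="rigid")
        assert np.abs(t.affine[:3, 3]).max() < 0.1 * 0.6  # 0.1 voxel
        rot = t.affine[:3, :3]
        assert np.abs(rot - np.eye(3)).max() < 1e-3

    def test_known_translation_recovered(self, prolate_subject):
        s = prolate_subject
        shift = SpatialTransform(affine=rigid([0, 0, 0], [1.8, -0.9, 0.6]))
        moved = [ImageVolume(resample_to_grid(v, shift, v.affine, v.shape3),
                             v.affine) for v in (s["anat"], s["fa"])]
        t = register_pair([s["anat"], s["fa"]], moved, weights=[1.0, 0.5],
                          model="rigid")
        err = np.abs(t.affine[:3, 3] - [1.8, -0.9, 0.6]).max()
        assert err < 0.25 * 0.6  # 0.25 voxel

    def test_known_scale_recovered(self, prolate_subject):
        s = prolate_subject
        sc = SpatialTransform(affine=np.diag([1.05, 1.05, 1.05, 1.0]))
        moved = [ImageVolume(resample_to_grid(v, sc, v.affine, v.shape3),
                             v.affine) for v in (s["anat"], s["fa"])]
        t = register_pair([s["anat"], s["fa"]], moved, weights=[1.0, 0.5],
                          model="affine")
        scales = np.linalg.norm(t.affine[:3, :3], axis=0)
        assert np.abs(scales - 1.05).max() < 0.0105  # within 1%

    def test_unknown_model_rejected(self, prolate_subject):
        s = prolate_subject
        with pytest.raises(ValueError, match="model"):
            register_pair([s["anat"]], [s["anat"]], model="syn")


class TestBuildTemplate:
    def test_identical_subjects_give_that_subject_back(self, prolate_subject):
        s = prolate_subject
        subj = (s["anat"], s["fa"], s["mask"])
        plan = TemplateLevelPlan(resolutions_mm=(2.4, 1.2),
                                 models=("rigid", "rigid"),
                                 iterations=(1, 1),
                                 modality_weights=(1.0, 0.5))
        tpl, transforms = build_template([subj, subj], plan)
        # transforms of identical subjects coincide after shape centering
        assert np.abs(transforms[0].affine - transforms[1].affine).max() < 1e-6
        # template mask closely matches the (aligned) subject mask
        warped = resample_to_grid(s["mask"], transforms[0],
                                  tpl["mask"].affine, tpl["mask"].shape3) >= 0.5
        res = overlap(warped, tpl["mask"].data >= 0.5)
        assert res.dice > 0.99

    def test_template_preserves_fa_distribution(self, prolate_subject):
        """On an identical-subject cohort the template FA distribution
        matches the per-subject distribution (quantile comparison)."""
        s = prolate_subject
        subj = (s["anat"], s["fa"], s["mask"])
        plan = TemplateLevelPlan(resolutions_mm=(1.2,), models=("rigid",),
                                 iterations=(1,), modality_weights=(1.0, 0.5))
        tpl, _ = build_template([subj, subj], plan)
        # compare away from the wall boundary, where resampling to the
        # coarser template grid mixes tissue with background
        from scipy.ndimage import binary_erosion
        tpl_core = binary_erosion(tpl["mask"].data >= 0.5)
        subj_core = binary_erosion(s["mask"].data >= 0.5, iterations=2)
        tpl_fa = tpl["fa"].data[tpl_core]
        subj_fa = s["fa"].data[subj_core]
        q = np.linspace(0.1, 0.9, 9)
        assert np.abs(np.quantile(tpl_fa, q) - np.quantile(subj_fa, q)).max() < 0.05

    def test_external_nonlinear_backend_contract(self, prolate_subject):
        """A pluggable nonlinear backend (here: zero displacement) slots in
        as the final level and leaves the rigid result unchanged."""
        s = prolate_subject
        subj = (s["anat"], s["fa"], s["mask"])
        calls = []

        def zero_backend(moving, fixed):
            calls.append(len(moving))
            ref = fixed[0]
            return SpatialTransform(
                displacement=np.zeros(ref.shape3 + (3,)),
                reference_affine=ref.affine)

        plan = TemplateLevelPlan(resolutions_mm=(2.4, 1.2),
                                 models=("rigid", "external-nonlinear"),
                                 iterations=(1, 1),
                                 modality_weights=(1.0, 0.5))
        tpl, transforms = build_template([subj, subj], plan,
                                         nonlinear_backend=zero_backend)
        assert calls == [2, 2]
        assert not transforms[0].is_affine
        warped = resample_to_grid(s["mask"], transforms[0],
                                  tpl["mask"].affine, tpl["mask"].shape3) >= 0.5
        assert overlap(warped, tpl["mask"].data >= 0.5).dice > 0.99

    def test_missing_nonlinear_backend_rejected(self, prolate_subject):
        s = prolate_subject
        subj = (s["anat"], s["fa"], s["mask"])
        plan = TemplateLevelPlan(resolutions_mm=(2.4,),
                                 models=("external-nonlinear",),
                                 iterations=(1,), modality_weights=(1.0, 0.5))
        with pytest.raises((ValueError, RuntimeError), match="backend"):
            build_template([subj, subj], plan)

    def test_single_subject_rejected(self, prolate_subject):
        s = prolate_subject
        plan = TemplateLevelPlan(resolutions_mm=(2.4,), models=("rigid",),
                                 iterations=(1,), modality_weights=(1.0, 0.5))
        with pytest.raises(ValueError, match="2 subjects"):
            build_template([(s["anat"], s["fa"], s["mask"])], plan)

    def test_plan_validation(self):
        with pytest.raises(ValueError, match="decreasing"):
            TemplateLevelPlan(resolutions_mm=(1.0, 1.0), models=("rigid",) * 2,
                              iterations=(1, 1))
        with pytest.raises(ValueError, match="weights"):
            TemplateLevelPlan(resolutions_mm=(1.0,), models=("rigid",),
                              iterations=(1,), modality_weights=(0.0,))
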