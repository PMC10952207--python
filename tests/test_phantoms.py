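import numpy as np
import pytest
from dataclasses import replace
from scipy import stats

from sarmorph.core import AffineTransform
from sarmorph.phantoms import (
    PhantomSpec,
    apply_transform_to_model,
    make_phantom,
    perturb_segmentation,
    reference_spec,
    resample_image,
    resample_model,
    subject_spec,
    synthesize_t1,
)
from sarmorph.registration import dice


class TestMakePhantom:
    def test_degenerate_shells_rejected(self, table):
        spec = replace(reference_spec(), semiaxes_mm=(20.0, 70.0, 70.0))
        with pytest.raises(ValueError, match="exceed"):
            make_phantom(spec, table, 2.0)

    def test_zero_thickness_gives_single_tissue(self, table):
        spec = replace(
            reference_spec(),
            shells_mm={k: 0.0 for k in reference_spec().shells_mm},
            cerebellum_semiaxes_mm=(0.1, 0.1, 0.1),
            ventricle_semiaxes_mm=(0.1, 0.1, 0.1),
        )
        m = make_phantom(spec, table, 4.0)
        present = np.unique(m.labels)
        assert len(present) == 2 and present[0] == 0  # air + one tissue

    def test_deterministic(self, table):
        a = make_phantom(reference_spec(), table, 4.0)
        b = make_phantom(reference_spec(), table, 4.0)
        assert np.array_equal(a.labels, b.labels)

    def test_volume_matches_analytic_ellipsoid(self, table):
        # oracle: exact ellipsoid volume 4/3 pi a b c
        spec = replace(reference_spec(), semiaxes_mm=(90.0, 70.0, 100.0))
        m = make_phantom(spec, table, 2.0)
        vol_mm3 = (m.labels != 0).sum() * m.voxel_volume_m3 * 1e9
        expected = 4.0 / 3.0 * np.pi * 90 * 70 * 100
        assert vol_mm3 == pytest.approx(expected, rel=0.02)

    def test_neck_slab_adds_muscle_and_plane(self, table):
        m = make_phantom(reference_spec(neck_slab=True), table, 4.0)
        assert (m.labels == 3).any()
        assert "neck_plane_z" in m.meta
        assert m.head_mask().sum() < (m.labels != 0).sum()

    def test_invalid_voxel_size(self, table):
        with pytest.raises(ValueError):
            make_phantom(reference_spec(), table, -1.0)

    def test_builtin_subjects_differ_from_reference(self, table):
        ref = make_phantom(reference_spec(), table, 4.0)
        for name in ("subject_a", "subject_b"):
            sub = make_phantom(subject_spec(name), table, 4.0)
            assert sub.shape != ref.shape or not np.array_equal(sub.labels, ref.labels)


class TestSynthesizeT1:
    def test_zero_noise_is_piecewise_constant(self, ref_model_4mm):
        img = synthesize_t1(ref_model_4mm, noise_sd=0.0)
        means = ref_model_4mm.tissue_table.map_property(ref_model_4mm.labels, "t1w_mean")
        assert np.array_equal(img.intensities, means)

    def test_seed_reproducibility(self, ref_model_4mm):
        a = synthesize_t1(ref_model_4mm, noise_sd=7.0, seed=5)
        b = synthesize_t1(ref_model_4mm, noise_sd=7.0, seed=5)
        assert np.array_equal(a.intensities, b.intensities)

    def test_noise_sd_law_of_large_numbers(self, table):
        # ~10^5-voxel single-tissue block; sample sd within 5% of requested
        from conftest import uniform_block_model

        m = uniform_block_model(table, shape=(50, 50, 50))
        img = synthesize_t1(m, noise_sd=10.0, seed=2)
        sd = img.intensities.std()
        assert sd == pytest.approx(10.0, rel=0.05)

    def test_air_mean_zero(self, ref_model_4mm):
        img = synthesize_t1(ref_model_4mm, noise_sd=4.0, seed=1)
        assert np.all(img.intensities[ref_model_4mm.labels == 0] == 0.0)


class TestPerturbSegmentation:
    def test_noop_identity(self, ref_model_4mm):
        out = perturb_segmentation(ref_model_4mm, [{"op": "boundary_flip", "p": 0.0}])
        assert np.array_equal(out.labels, ref_model_4mm.labels)

    def test_split_conserves_support(self, ref_model_4mm):
        out = perturb_segmentation(
            ref_model_4mm,
            [{"op": "split_tissue", "tissue": "skull", "inner": "cancellous_bone",
              "outer": "cortical_bone"}],
        )
        old = ref_model_4mm.labels == 4
        new = (out.labels == 9) | (out.labels == 10)
        assert np.array_equal(old, new)
        assert np.array_equal(out.labels == 0, ref_model_4mm.labels == 0)

    def test_insert_layer_at_interface(self, ref_model_4mm):
        out = perturb_segmentation(
            ref_model_4mm,
            [{"op": "insert_layer", "outer": "csf", "inner": "gray_matter",
              "new": "dura", "thickness": 1}],
        )
        dura = out.labels == 11
        assert dura.any()
        # new label carved exclusively out of the outer tissue of the interface
        assert np.all(ref_model_4mm.labels[dura] == 5)

    def test_unknown_interface_error(self, ref_model_4mm):
        with pytest.raises(ValueError):
            perturb_segmentation(
                ref_model_4mm,
                [{"op": "insert_layer", "outer": "muscle", "inner": "csf", "new": "dura"}],
            )

    def test_boundary_flip_rate_within_binomial_bounds(self, table):
        # two-tissue phantom: flipped-voxel count ~ Binomial(n_interface, p)
        spec = replace(
            reference_spec(),
            shells_mm={"skin": 0.0, "fat": 0.0, "skull": 0.0, "csf": 0.0, "gray_matter": 20.0},
            cerebellum_semiaxes_mm=(0.1, 0.1, 0.1),
            ventricle_semiaxes_mm=(0.1, 0.1, 0.1),
        )
        m = make_phantom(spec, table, 3.0)
        assert set(np.unique(m.labels)) == {0, 6, 7}
        p = 0.3
        out = perturb_segmentation(m, [{"op": "boundary_flip", "p": p}], seed=4)
        # interface voxels by definition: 6-neighbourhood contains a different tissue
        lab = m.labels
        iface = np.zeros_like(lab, dtype=bool)
        for ax in range(3):
            for sh in (1, -1):
                n = np.roll(lab, sh, axis=ax)
                edge = [slice(None)] * 3
                edge[ax] = 0 if sh == 1 else -1
                n[tuple(edge)] = 0
                iface |= (lab != 0) & (n != 0) & (n != lab)
        n_iface = int(iface.sum())
        flipped = int((out.labels != m.labels).sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], n_iface, p)
        assert lo <= flipped <= hi
        assert np.array_equal(out.labels == 0, m.labels == 0)  # support conserved

    def test_flip_determinism(self, ref_model_4mm):
        a = perturb_segmentation(ref_model_4mm, [{"op": "boundary_flip", "p": 0.4}], seed=9)
        b = perturb_segmentation(ref_model_4mm, [{"op": "boundary_flip", "p": 0.4}], seed=9)
        assert np.array_equal(a.labels, b.labels)


class TestApplyTransform:
    def test_identity_same_grid(self, ref_model_4mm):
        out = apply_transform_to_model(ref_model_4mm, AffineTransform.identity(), ref_model_4mm)
        assert np.array_equal(out.labels, ref_model_4mm.labels)

    def test_exact_voxel_translation_shifts_grid(self, ref_model_4mm):
        k = 2  # voxels along x
        vox = ref_model_4mm.voxel_size[0]
        M = np.eye(4)
        M[0, 3] = k * vox
        out = apply_transform_to_model(ref_model_4mm, AffineTransform(M), ref_model_4mm)
        assert np.array_equal(out.labels[k:], ref_model_4mm.labels[:-k])

    def test_random_affine_roundtrip_dice(self, table):
        m = make_phantom(reference_spec(), table, 2.0)
        M = np.eye(4)
        c, s = np.cos(np.deg2rad(7)), np.sin(np.deg2rad(7))
        M[:3, :3] = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]]) @ np.diag([1.05, 0.97, 1.02])
        M[:3, 3] = (3.0, -2.0, 4.0)
        T = AffineTransform(M)
        fwd = apply_transform_to_model(m, T, m)
        back = apply_transform_to_model(fwd, T.inverse(), m)
        rep = dice(m, back)
        for grp, val in rep.per_group.items():
            if np.isfinite(val):
                assert val >= 0.98, f"{grp}: {val}"


class TestResample:
    def test_same_size_identity(self, ref_model_4mm):
        out = resample_model(ref_model_4mm, 4.0)
        assert np.array_equal(out.labels, ref_model_4mm.labels)

    def test_uniform_image_any_factor(self, ref_model_4mm):
        from sarmorph.core import SyntheticImage

        img = SyntheticImage(np.full(ref_model_4mm.shape, 3.5), ref_model_4mm.affine)
        out = resample_image(img, 6.0)
        assert np.allclose(out.intensities, 3.5)

    def test_downsample_conserves_label_volume(self, table):
        spec = replace(
            reference_spec(),
            shells_mm={k: 0.0 for k in reference_spec().shells_mm},
            semiaxes_mm=(50.0, 50.0, 50.0),
            cerebellum_semiaxes_mm=(0.1, 0.1, 0.1),
            ventricle_semiaxes_mm=(0.1, 0.1, 0.1),
        )
        m = make_phantom(spec, table, 2.0)
        out = resample_model(m, 4.0)
        v0 = (m.labels != 0).sum() * m.voxel_volume_m3
        v1 = (out.labels != 0).sum() * out.voxel_volume_m3
        assert v1 == pytest.approx(v0, rel=0.05)

    def test_mass_conserved_under_resampling(self, ref_model_4mm):
        out = resample_model(ref_model_4mm, 8.0)
        assert out.head_mass_kg() == pytest.approx(ref_model_4mm.head_mass_kg(), rel=0.05)

    def test_invalid_size(self, ref_model_4mm):
        with pytest.raises(ValueError):
            resample_model(ref_model_4mm, 0.0)
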