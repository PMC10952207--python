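import numpy as np
import pytest
from dataclasses import replace

from sarmorph.coilfields import (
    ChannelFieldSet,
    CoilModel,
    combine_fields,
    efield_sq_difference,
    simulate_channel_fields,
)
from sarmorph.phantoms import make_phantom, reference_spec


class TestCoilModel:
    def test_default_geometry(self, coil):
        assert coil.n_channels == 8
        assert coil.diameter_mm == 300.0
        assert coil.frequency_hz == pytest.approx(297.2e6)
        az = np.asarray(coil.azimuths_rad)
        assert np.allclose(np.diff(az), np.pi / 4)

    def test_duplicate_azimuths_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            CoilModel(n_channels=2, azimuths_rad=(0.0, 0.0))

    def test_element_center_on_cylinder(self, coil):
        for c in range(coil.n_channels):
            p = coil.element_center_mm(c)
            assert np.hypot(p[0], p[1]) == pytest.approx(150.0)
            assert p[2] == 0.0


class TestSimulateChannelFields:
    def test_per_channel_deposited_power_is_one_watt(self, ref_fields_5mm, ref_model_5mm):
        power = ref_fields_5mm.deposited_power_w(ref_model_5mm)
        assert np.allclose(power, 1.0, rtol=1e-6)

    def test_all_air_model_errors(self, table, coil):
        from sarmorph.core import VoxelModel

        aff = np.diag([4.0, 4.0, 4.0, 1.0])
        m = VoxelModel(np.zeros((6, 6, 6), dtype=np.int16), aff, table)
        with pytest.raises(ValueError, match="normalise"):
            simulate_channel_fields(coil, m)

    def test_model_outside_cylinder_errors(self, table, coil):
        spec = replace(reference_spec(), semiaxes_mm=(160.0, 160.0, 80.0))
        m = make_phantom(spec, table, 8.0)
        with pytest.raises(ValueError, match="cylinder"):
            simulate_channel_fields(coil, m)

    def test_quarter_turn_channel_symmetry(self, table, coil):
        # oracle: a sphere is invariant under 90 deg rotation, which maps the
        # voxel grid onto itself exactly -> channel c must map onto c+2
        spec = replace(
            reference_spec(),
            semiaxes_mm=(70.0, 70.0, 70.0),
            cerebellum_semiaxes_mm=(0.1, 0.1, 0.1),
            ventricle_semiaxes_mm=(0.1, 0.1, 0.1),
        )
        m = make_phantom(spec, table, 5.0)
        f = simulate_channel_fields(coil, m)
        mask = m.labels != 0
        for c in (0, 3):
            a = np.abs(f.B1p[c + 2])
            b = np.rot90(np.abs(f.B1p[c]), k=1, axes=(0, 1))
            rel = np.sqrt(np.mean((a[mask] - b[mask]) ** 2) / np.mean(a[mask] ** 2))
            assert rel < 0.01

    def test_hdf5_roundtrip(self, ref_fields_5mm, tmp_path):
        p = tmp_path / "fields.h5"
        ref_fields_5mm.save(p)
        again = ChannelFieldSet.load(p)
        assert np.array_equal(again.E, ref_fields_5mm.E)
        assert np.array_equal(again.B1p, ref_fields_5mm.B1p)
        assert np.allclose(again.affine, ref_fields_5mm.affine)


class TestCombineFields:
    def test_one_hot_selects_channel(self, ref_fields_5mm):
        w = np.zeros(8, dtype=complex)
        w[3] = 1.0
        E, B = combine_fields(ref_fields_5mm, w)
        assert np.array_equal(E, ref_fields_5mm.E[3])
        assert np.array_equal(B, ref_fields_5mm.B1p[3])

    def test_linearity_scaling(self, ref_fields_5mm):
        w = np.zeros(8, dtype=complex)
        w[2] = 2.0
        E, B = combine_fields(ref_fields_5mm, w)
        assert np.array_equal(E, 2.0 * ref_fields_5mm.E[2])

    def test_negation_preserves_magnitude(self, ref_fields_5mm):
        rng = np.random.default_rng(0)
        w = rng.standard_normal(8) + 1j * rng.standard_normal(8)
        Ep, _ = combine_fields(ref_fields_5mm, w)
        En, _ = combine_fields(ref_fields_5mm, -w)
        assert np.allclose(En, -Ep)
        assert np.allclose(np.abs(En), np.abs(Ep))

    def test_length_mismatch_errors(self, ref_fields_5mm):
        with pytest.raises(ValueError, match="shim length"):
            combine_fields(ref_fields_5mm, np.ones(5))

    def test_deposited_power_is_bilinear_form(self, ref_fields_5mm, ref_model_5mm):
        # oracle: P(w) = w^H M w with M the pairwise power-correlation matrix
        sigma = ref_model_5mm.conductivity_map()
        dV = ref_model_5mm.voxel_volume_m3
        E = ref_fields_5mm.E
        M = 0.5 * dV * np.einsum("caxyz,xyz,daxyz->cd", np.conj(E), sigma, E)
        rng = np.random.default_rng(7)
        for _ in range(5):
            w = rng.standard_normal(8) + 1j * rng.standard_normal(8)
            Etot, _ = combine_fields(ref_fields_5mm, w)
            direct = 0.5 * dV * np.sum(sigma * np.sum(np.abs(Etot) ** 2, axis=0))
            bilinear = float(np.real(np.conj(w) @ M @ w))
            assert direct == pytest.approx(bilinear, rel=1e-9)

    def test_mean_random_shim_power_near_budget(self, ref_fields_5mm, ref_model_5mm):
        # E[w^H M w] = total_power when phases are independent uniform
        from sarmorph.shimming import generate_shims

        shims = generate_shims(400, 8, total_power_w=5.0, seed=3)
        sigma = ref_model_5mm.conductivity_map()
        dV = ref_model_5mm.voxel_volume_m3
        powers = []
        for w in shims.weights[:100]:
            Etot, _ = combine_fields(ref_fields_5mm, w)
            powers.append(0.5 * dV * np.sum(sigma * np.sum(np.abs(Etot) ** 2, axis=0)))
        assert np.mean(powers) == pytest.approx(5.0, rel=0.15)


class TestEfieldSqDifference:
    def test_identical_zero(self, ref_fields_5mm, ref_model_5mm):
        w = np.ones(8, dtype=complex)
        out = efield_sq_difference(ref_fields_5mm, ref_fields_5mm, ref_model_5mm,
                                   ref_model_5mm, w)
        assert not out["diff"].any()
        assert out["mean_abs_diff"] == 0.0

    def test_doubled_fields(self, ref_fields_5mm, ref_model_5mm):
        w = np.ones(8, dtype=complex)
        doubled = ref_fields_5mm.scaled(2.0)
        out = efield_sq_difference(doubled, ref_fields_5mm, ref_model_5mm, ref_model_5mm, w)
        Ea, _ = combine_fields(ref_fields_5mm, w)
        e2 = np.sum(np.abs(Ea) ** 2, axis=0)
        assert np.allclose(out["diff"], 3.0 * e2)

    def test_unmatched_region_localisation(self, table, coil):
        # two phantoms differing by one outer shell: the |E|^2 difference mean
        # concentrates in the unmatched voxels
        a = make_phantom(reference_spec(), table, 5.0)
        spec = replace(reference_spec(), semiaxes_mm=(64.0, 82.0, 74.0))
        b_small = make_phantom(spec, table, 5.0)
        # put b onto a's grid
        from sarmorph.core import AffineTransform
        from sarmorph.phantoms import apply_transform_to_model

        b = apply_transform_to_model(b_small, AffineTransform.identity(), a)
        fa = simulate_channel_fields(coil, a)
        fb = simulate_channel_fields(coil, b)
        w = np.exp(-1j * np.asarray(coil.azimuths_rad))
        out = efield_sq_difference(fa, fb, a, b, w, mask_mode="union")
        unmatched = a.tissue_mask() ^ b.tissue_mask()
        matched = a.tissue_mask() & b.tissue_mask()
        assert out["abs_diff"][unmatched].mean() > out["abs_diff"][matched].mean()

    def test_mask_modes(self, ref_fields_5mm, ref_model_5mm):
        w = np.ones(8, dtype=complex)
        for mode in ("union", "intersection"):
            out = efield_sq_difference(ref_fields_5mm, ref_fields_5mm, ref_model_5mm,
                                       ref_model_5mm, w, mask_mode=mode)
            assert out["mask"].sum() == ref_model_5mm.tissue_mask().sum()
        with pytest.raises(ValueError):
            efield_sq_difference(ref_fields_5mm, ref_fields_5mm, ref_model_5mm,
                                 ref_model_5mm, w, mask_mode="bogus")
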