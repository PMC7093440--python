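"""Phantom generator: determinism, geometry, ground-truth bookkeeping."""

import numpy as np
import pytest

from atlasquant.core import ImageGrid
from atlasquant.deform import jacobian_determinant
from atlasquant.dixon import compute_fat_fraction, voi_readout
from atlasquant.kinetics import extract_idif
from atlasquant.phantom import (
    DeformParams,
    Ellipsoid,
    PhantomSpec,
    TissueSpec,
    build_labelmap,
    build_true_field,
    default_frame_schedule,
    default_phantom_spec,
    make_reference,
    make_subject,
    random_deform_params,
    simulate_dynamic_pet,
)

SMALL_SHAPE = (24, 20, 48)


@pytest.fixture(scope="module")
def small_ref():
    return make_reference(default_phantom_spec(SMALL_SHAPE, mr_sigma=0.0, pet_noise_scale=0.0))


class TestReference:
    def test_determinism_under_fixed_seed(self):
        spec = default_phantom_spec(SMALL_SHAPE, seed=3)
        a = make_reference(spec)
        b = make_reference(spec)
        assert np.array_equal(a.water.values, b.water.values)
        assert np.array_equal(a.pet.values, b.pet.values)
        assert np.array_equal(a.true_labelmap.labels, b.true_labelmap.labels)

    def test_different_seed_changes_noise(self):
        a = make_reference(default_phantom_spec(SMALL_SHAPE, seed=3))
        b = make_reference(default_phantom_spec(SMALL_SHAPE, seed=4))
        assert not np.array_equal(a.water.values, b.water.values)

    def test_overlapping_primitives_name_the_pair(self):
        spec = default_phantom_spec(SMALL_SHAPE)
        bad = list(spec.tissues)
        clash = TissueSpec(
            "rogue",
            "lean",
            (Ellipsoid((0.65, 0.49, 0.385), (0.05, 0.05, 0.03)),),  # inside the liver
            ff=0.1,
            signal=1.0,
            K1=0.05,
            k2=0.2,
            k3=0.03,
            Vb=0.04,
        )
        bad_spec = PhantomSpec(grid=spec.grid, tissues=(*bad, clash), envelope=spec.envelope)
        with pytest.raises(ValueError, match="liver.*rogue"):
            build_labelmap(bad_spec)

    def test_fat_fraction_recovered_from_channels(self, small_ref):
        """Noiseless water/fat pairs reproduce the generating FF exactly."""
        ff = compute_fat_fraction(small_ref.water, small_ref.fat)
        for voi in small_ref.spec.voi_table():
            mask = small_ref.true_labelmap.mask(voi.label_id)
            truth = small_ref.truth.loc[voi.name, "ff_true"]
            assert voi_readout(ff, mask) == pytest.approx(truth, abs=1e-9)

    def test_noisy_fat_fraction_close_to_truth(self):
        ref = make_reference(default_phantom_spec(SMALL_SHAPE, mr_sigma=0.02))
        ff = compute_fat_fraction(ref.water, ref.fat)
        mask = ref.true_labelmap.mask(ref.spec.label_of("sat"))
        assert voi_readout(ff, mask) == pytest.approx(0.92, abs=0.02)

    def test_bone_scaffold_is_brightest_water_signal(self, small_ref):
        labels = small_ref.true_labelmap.labels
        bone = small_ref.water.values[labels == small_ref.spec.label_of("skeleton")]
        for voi in small_ref.spec.voi_table():
            if voi.name == "skeleton":
                continue
            other = small_ref.water.values[labels == voi.label_id]
            assert bone.mean() > other.mean()

    def test_truth_volume_is_voxel_count_times_voxel_volume(self, small_ref):
        t = small_ref.truth
        vv = small_ref.spec.grid.voxel_volume
        assert np.allclose(t["volume_l"], t["n_voxels"] * vv / 1e6)

    def test_aorta_carries_the_input_function(self, small_ref):
        """Noiseless aorta TAC = frame-averaged whole-blood curve (<2% off Cp)."""
        from atlasquant.kinetics import frame_average, whole_blood_from_plasma

        spec = small_ref.spec
        idif = extract_idif(small_ref.pet, small_ref.true_labelmap.mask(spec.label_of("aorta")))
        wb = whole_blood_from_plasma(small_ref.plasma, spec.hematocrit, spec.rbc_partition)
        expected = frame_average(wb, np.asarray(spec.frames.starts), spec.frames.ends)
        late = spec.frames.mids >= 10.0  # smooth part of the curve
        assert np.allclose(idif.values[late], expected[late], rtol=1e-9)
        cp_at_mids = np.interp(spec.frames.mids[late], small_ref.plasma.tac.times, wb.values)
        assert np.allclose(idif.values[late], cp_at_mids, rtol=0.02)


class TestSubjects:
    def test_identity_params_reproduce_reference_exactly(self, small_ref):
        subj = make_subject(small_ref, DeformParams(), seed=99)
        assert np.array_equal(subj.water.values, small_ref.water.values)
        assert np.array_equal(subj.pet.values, small_ref.pet.values)
        assert np.array_equal(subj.true_labelmap.labels, small_ref.true_labelmap.labels)
        assert subj.truth["volume_l"].equals(small_ref.truth["volume_l"])

    def test_isotropic_scaling_scales_large_tissue_volumes_cubically(self):
        ref = make_reference(
            default_phantom_spec((40, 32, 96), mr_sigma=0.0, pet_noise_scale=0.0)
        )
        subj = make_subject(ref, DeformParams(scale=(1.1, 1.1, 1.1)), seed=1)
        # voxelization quantises boundaries: assert on the largest depot and
        # on the whole labelled body, where surface effects are smallest
        ratio_sat = subj.truth.loc["sat", "n_voxels"] / ref.truth.loc["sat", "n_voxels"]
        assert ratio_sat == pytest.approx(1.331, rel=0.01)
        total = (subj.true_labelmap.labels > 0).sum() / (ref.true_labelmap.labels > 0).sum()
        assert total == pytest.approx(1.331, rel=0.01)

    def test_true_field_jacobian_matches_finite_difference_oracle(self):
        grid = ImageGrid((16, 14, 20), (3.0, 3.0, 3.0))
        params = DeformParams(
            scale=(1.05, 0.97, 1.02),
            translation_mm=(2.0, -1.0, 3.0),
            jiggle_amplitude_mm=4.0,
            jiggle_sigma_mm=18.0,
            jiggle_seed=7,
        )
        fld = build_true_field(grid, params)
        det = jacobian_determinant(fld).values

        # independent oracle: central differences via slicing
        m = fld.mapping
        sp = grid.spacing
        J = np.zeros((*[n - 2 for n in grid.shape], 3, 3))
        sl = (slice(1, -1),) * 3
        for i in range(3):
            J[..., i, 0] = (m[2:, 1:-1, 1:-1, i] - m[:-2, 1:-1, 1:-1, i]) / (2 * sp[0])
            J[..., i, 1] = (m[1:-1, 2:, 1:-1, i] - m[1:-1, :-2, 1:-1, i]) / (2 * sp[1])
            J[..., i, 2] = (m[1:-1, 1:-1, 2:, i] - m[1:-1, 1:-1, :-2, i]) / (2 * sp[2])
        oracle = np.linalg.det(J)
        assert np.max(np.abs(det[sl] - oracle)) < 1e-6

    def test_folding_deformation_rejected(self):
        grid = ImageGrid((12, 12, 12), (4.0, 4.0, 4.0))
        with pytest.raises(ValueError, match="Jacobian"):
            build_true_field(
                grid,
                DeformParams(jiggle_amplitude_mm=60.0, jiggle_sigma_mm=6.0, jiggle_seed=1),
            )

    def test_random_subject_is_deterministic_given_seeds(self, small_ref):
        params = random_deform_params(np.random.default_rng(5))
        a = make_subject(small_ref, params, seed=17)
        b = make_subject(small_ref, params, seed=17)
        assert np.array_equal(a.pet.values, b.pet.values)
        assert np.array_equal(a.water.values, b.water.values)


class TestSimulatedPet:
    def test_no_delivery_no_blood_means_zero_activity(self, small_ref):
        spec = small_ref.spec
        dead = tuple(
            TissueSpec(t.name, t.tissue_class, t.primitives, t.ff, t.signal, 0.0, t.k2, t.k3, 0.0, t.is_voi)
            for t in spec.tissues
        )
        dead_spec = PhantomSpec(
            grid=spec.grid, tissues=dead, envelope=spec.envelope, pet_noise_scale=0.0
        )
        labelmap = build_labelmap(dead_spec)
        pet = simulate_dynamic_pet(labelmap, dead_spec, small_ref.plasma)
        assert np.allclose(pet.values, 0.0)

    def test_noise_standard_deviation_follows_signal_over_duration(self, small_ref):
        """PET noise sd = scale * sqrt(signal / frame duration)."""
        spec = small_ref.spec
        noisy_spec = PhantomSpec(
            grid=spec.grid, tissues=spec.tissues, envelope=spec.envelope, pet_noise_scale=0.5
        )
        labelmap = small_ref.true_labelmap
        clean = simulate_dynamic_pet(labelmap, spec, small_ref.plasma, seed=5)
        noisy = simulate_dynamic_pet(labelmap, noisy_spec, small_ref.plasma, seed=5)
        body = labelmap.labels == spec.label_of("soft_tissue")
        last = -1
        resid = (noisy.values - clean.values)[body][:, last]
        signal = clean.values[body][0, last]
        predicted = 0.5 * np.sqrt(signal / np.asarray(spec.frames.durations)[last])
        assert np.std(resid) == pytest.approx(predicted, rel=0.1)
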