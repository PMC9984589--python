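"""Phantom generation, noise simulation and study round-trip I/O."""

import numpy as np
import pytest
from scipy import ndimage

from segrepeat import (
    NoiseModel,
    PhantomSpec,
    fit_affine,
    jaccard,
    make_phantom,
    read_study,
    simulate_repeats,
    volume_mm3,
    write_study,
)
from segrepeat.synthetic import LANDMARK_NAMES


class TestMakePhantom:
    def test_cylinder_volume_within_5_percent(self, cylinder_study, cylinder_spec):
        analytic = np.pi * cylinder_spec.max_radius_mm**2 * cylinder_spec.length_mm
        assert volume_mm3(cylinder_study.truth) == pytest.approx(analytic, rel=0.05)

    def test_determinism_bit_identical(self, cylinder_spec):
        a = make_phantom(cylinder_spec)
        b = make_phantom(cylinder_spec)
        np.testing.assert_array_equal(a.truth.voxels, b.truth.voxels)
        np.testing.assert_array_equal(a.landmarks.points, b.landmarks.points)
        np.testing.assert_array_equal(a.true_affine.matrix, b.true_affine.matrix)

    def test_truth_is_single_6connected_component(self, cylinder_study):
        _, n = ndimage.label(cylinder_study.truth.voxels)
        assert n == 1

    def test_wrapped_tube_single_component(self):
        spec = PhantomSpec(muscle_kind="wrapped_tube", length_mm=180,
                           max_radius_mm=15, taper=0.3, wrap_offset_mm=25, seed=3)
        study = make_phantom(spec)
        _, n = ndimage.label(study.truth.voxels)
        assert n == 1

    def test_taper_slices_never_exceed_mid_slice(self):
        spec = PhantomSpec(muscle_kind="tapered_tube", length_mm=100,
                           max_radius_mm=15, taper=0.9, seed=2)
        study = make_phantom(spec)
        areas = study.truth.voxels.sum(axis=(0, 1))
        nz = np.nonzero(areas)[0]
        mid_area = areas[nz[len(nz) // 2]]
        assert np.all(areas[nz] <= mid_area)

    def test_twelve_named_landmarks(self, cylinder_study):
        assert len(cylinder_study.landmarks) == 12
        assert cylinder_study.landmarks.names == LANDMARK_NAMES

    def test_true_affine_maps_atlas_onto_subject(self, cylinder_study):
        mapped = cylinder_study.true_affine.apply_points(
            cylinder_study.atlas_landmarks.points)
        np.testing.assert_allclose(mapped, cylinder_study.landmarks.points, atol=1e-9)

    def test_registration_recovers_true_affine(self, cylinder_study):
        fit = fit_affine(cylinder_study.atlas_landmarks, cylinder_study.landmarks)
        np.testing.assert_allclose(fit.matrix, cylinder_study.true_affine.matrix,
                                   atol=1e-8)
        np.testing.assert_allclose(fit.translation,
                                   cylinder_study.true_affine.translation, atol=1e-8)

    def test_attachments_on_centerline_ends(self, cylinder_study, cylinder_spec):
        ax = cylinder_study.true_axis
        assert ax.length_L == pytest.approx(cylinder_spec.length_mm, abs=1e-6)

    def test_grid_too_small_names_required_dims(self):
        spec = PhantomSpec(length_mm=100, max_radius_mm=15, grid=(20, 20, 10), seed=0)
        with pytest.raises(ValueError, match="needs at least"):
            make_phantom(spec)

    def test_explicit_clinical_grid_accepted(self):
        spec = PhantomSpec(length_mm=60, max_radius_mm=10, grid=(512, 512, 40),
                           pixel_mm=0.817, slice_mm=4.0, seed=1)
        study = make_phantom(spec)
        assert study.truth.voxels.shape == (512, 512, 40)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(length_mm=6.0, slice_mm=4.0)  # length <= 2 slices
        with pytest.raises(ValueError):
            PhantomSpec(taper=1.0)
        with pytest.raises(ValueError):
            PhantomSpec(muscle_kind="nope")


class TestSimulateRepeats:
    def test_zero_noise_identity(self, cylinder_study):
        noise = NoiseModel(0.0, 0.0, 8.0, 0.0, seed=1)
        reps = simulate_repeats(cylinder_study.truth, cylinder_study.true_axis, noise, 3)
        for r in reps:
            np.testing.assert_array_equal(r.voxels, cylinder_study.truth.voxels)

    def test_repeat_count_and_shared_grid(self, noisy_repeats, cylinder_study):
        assert len(noisy_repeats) == 3
        for r in noisy_repeats:
            assert r.same_grid(cylinder_study.truth)

    def test_repeats_are_deterministic(self, cylinder_study):
        noise = NoiseModel(0.5, 3.0, 8.0, 0.1, seed=99)
        a = simulate_repeats(cylinder_study.truth, cylinder_study.true_axis, noise, 2)
        b = simulate_repeats(cylinder_study.truth, cylinder_study.true_axis, noise, 2)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.voxels, rb.voxels)

    def test_repeats_single_connected_component(self, noisy_repeats):
        for r in noisy_repeats:
            _, n = ndimage.label(r.voxels)
            assert n == 1

    def test_extremity_noise_exceeds_belly_noise(self, cylinder_study, noisy_repeats):
        """Boundary error concentrates at the ends when extremity sigma is larger."""
        truth = cylinder_study.truth.voxels
        diff_per_slice = []
        for r in noisy_repeats:
            diff_per_slice.append((r.voxels != truth).sum(axis=(0, 1)))
        diff = np.mean(diff_per_slice, axis=0)
        nz = np.nonzero(truth.any(axis=(0, 1)))[0]
        ends = np.r_[nz[:3], nz[-3:]]
        belly = nz[len(nz) // 2 - 1:len(nz) // 2 + 2]
        assert diff[ends].mean() > 2 * diff[belly].mean()

    def test_monotone_degradation_with_belly_sigma(self):
        """Mean overlap strictly decreases as boundary noise grows (20 phantoms)."""
        mean_ji = []
        for sigma in (0.3, 1.0, 2.5):
            vals = []
            for s in range(20):
                spec = PhantomSpec(length_mm=60, max_radius_mm=10, seed=500 + s)
                study = make_phantom(spec)
                noise = NoiseModel(sigma, sigma, 6.0, 0.0, seed=700 + s)
                reps = simulate_repeats(study.truth, study.true_axis, noise, 2)
                vals.append(jaccard(reps[0], reps[1]))
            mean_ji.append(np.mean(vals))
        assert mean_ji[0] > mean_ji[1] > mean_ji[2]

    def test_dropout_removes_terminal_slices(self, cylinder_study):
        noise = NoiseModel(0.0, 0.0, 8.0, 1.0, seed=4)
        reps = simulate_repeats(cylinder_study.truth, cylinder_study.true_axis, noise, 2)
        truth_nz = np.nonzero(cylinder_study.truth.voxels.any(axis=(0, 1)))[0]
        for r in reps:
            rep_nz = np.nonzero(r.voxels.any(axis=(0, 1)))[0]
            assert truth_nz[0] not in rep_nz and truth_nz[-1] not in rep_nz

    def test_too_few_repeats_rejected(self, cylinder_study):
        with pytest.raises(ValueError):
            simulate_repeats(cylinder_study.truth, cylinder_study.true_axis,
                             NoiseModel(seed=0), 1)


class TestStudyIO:
    def test_round_trip(self, tmp_path, cylinder_study, noisy_repeats):
        import dataclasses

        study = dataclasses.replace(cylinder_study, repeats=list(noisy_repeats))
        manifest = write_study(study, tmp_path / "study")
        back = read_study(manifest)
        np.testing.assert_array_equal(back.truth.voxels, study.truth.voxels)
        assert len(back.repeats) == 3
        for a, b in zip(back.repeats, study.repeats):
            np.testing.assert_array_equal(a.voxels, b.voxels)
        np.testing.assert_allclose(back.landmarks.points, study.landmarks.points,
                                   atol=1e-9)
        np.testing.assert_allclose(back.true_affine.matrix, study.true_affine.matrix)
        assert back.spec == study.spec

    def test_regeneration_from_manifest_matches(self, tmp_path, cylinder_study):
        manifest = write_study(cylinder_study, tmp_path / "s")
        back = read_study(manifest)
        regenerated = make_phantom(back.spec)
        np.testing.assert_array_equal(regenerated.truth.voxels, back.truth.voxels)

    def test_refuses_nonempty_directory(self, tmp_path, cylinder_study):
        d = tmp_path / "occupied"
        d.mkdir()
        (d / "something.txt").write_text("x")
        with pytest.raises(FileExistsError):
            write_study(cylinder_study, d)
        write_study(cylinder_study, d, overwrite=True)  # explicit overwrite ok

    def test_unwritable_target_raises_io_error(self, tmp_path, cylinder_study):
        blocker = tmp_path / "not_a_dir"
        blocker.write_text("plain file")
        with pytest.raises(OSError):
            write_study(cylinder_study, blocker / "study")
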