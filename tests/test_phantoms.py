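"""Phantom construction, kinetics, characterization and training images."""

import numpy as np
import pytest

from modgan.errors import (GeometryError, InvalidParameterError, MappingError,
                           PlacementError, SamplingError)
from modgan.phantoms import (DEFAULT_UPTAKE, ActivityPhantom, NemaPhantomSpec,
                             TissueMap, characterize_image, insert_lesions,
                             make_brain_phantom, make_nema_phantom,
                             make_training_set, nema_region_masks,
                             two_compartment_ki, toy_brain_tissue_map)


class TestKinetics:
    @pytest.mark.parametrize("k1,k2,k3,expected", [
        (0.1, 0.1, 0.0, 0.0),     # no trapping -> no net uptake
        (0.1, 0.0, 0.1, 0.1),     # no efflux -> Ki = K1
        (0.1, 0.1, 0.1, 0.05),
        (0.3, 0.2, 0.1, 0.3 * 0.1 / 0.3),
    ])
    def test_net_influx_rate(self, k1, k2, k3, expected):
        assert two_compartment_ki(k1, k2, k3) == pytest.approx(expected)

    @pytest.mark.parametrize("k1,k2,k3", [(-0.1, 0.1, 0.1), (0.1, 0.0, 0.0)])
    def test_invalid_rates(self, k1, k2, k3):
        with pytest.raises(InvalidParameterError):
            two_compartment_ki(k1, k2, k3)


class TestBrainPhantom:
    def test_all_background_map_gives_zero_phantom(self):
        phantom = make_brain_phantom(TissueMap(np.zeros((8, 8), dtype=int)))
        assert not phantom.values.any()

    def test_single_label_map_gives_constant_image(self):
        phantom = make_brain_phantom(TissueMap(np.full((8, 8), 2)), {2: 1.7})
        assert np.all(phantom.values == 1.7)

    def test_gray_to_white_uptake_ratio_is_four(self, brain_map, brain_phantom):
        gm = brain_phantom.values[brain_map.labels == 1]
        wm = brain_phantom.values[brain_map.labels == 2]
        assert gm.mean() / wm.mean() == 4.0

    def test_missing_label_raises_mapping_error(self, brain_map):
        with pytest.raises(MappingError):
            make_brain_phantom(brain_map, {0: 0.0, 1: 4.0})

    def test_tissue_map_unmodified(self, brain_map):
        before = brain_map.labels.copy()
        make_brain_phantom(brain_map)
        assert np.array_equal(brain_map.labels, before)

    def test_total_activity_conserved(self, brain_map, brain_phantom):
        expected = sum(
            (brain_map.labels == lab).sum() * uptake
            for lab, uptake in DEFAULT_UPTAKE.items()
        )
        assert brain_phantom.total_activity() == pytest.approx(expected)

    def test_negative_values_rejected(self):
        with pytest.raises(InvalidParameterError):
            ActivityPhantom(np.array([[-1.0, 0.0]]))


class TestLesions:
    def test_zero_lesions_is_identity(self, brain_phantom):
        out = insert_lesions(brain_phantom, 0, seed=1)
        assert np.array_equal(out.values, brain_phantom.values)

    def test_seeded_determinism(self, brain_phantom):
        a = insert_lesions(brain_phantom, 3, uptake_factor=2.0, seed=7)
        b = insert_lesions(brain_phantom, 3, uptake_factor=2.0, seed=7)
        assert np.array_equal(a.values, b.values)

    def test_lesion_contrast_on_uniform_tissue(self):
        labels = np.full((64, 64), 2)
        phantom = make_brain_phantom(TissueMap(labels), {2: 1.0})
        out = insert_lesions(phantom, 1, radius_range_mm=(4, 4),
                             uptake_factor=2.0, allowed_labels={2}, seed=3)
        lesion = out.values > 1.0
        assert lesion.any()
        assert out.values[lesion].mean() / out.values[~lesion].mean() == 2.0

    def test_impossible_placement_raises(self, brain_phantom):
        with pytest.raises(PlacementError):
            insert_lesions(brain_phantom, 5, radius_range_mm=(60, 60), seed=0)


class TestNemaPhantom:
    def test_hot_sphere_to_background_ratio(self):
        spec = NemaPhantomSpec()
        phantom = make_nema_phantom(spec)
        masks = nema_region_masks(spec)
        hot = np.zeros_like(masks["background"])
        for mask in masks["spheres"][: spec.hot_sphere_count]:
            hot |= mask
        ratio = phantom.values[hot].mean() / phantom.values[masks["background"]].mean()
        assert ratio == 8.0

    def test_six_spheres_two_cold(self):
        spec = NemaPhantomSpec()
        masks = nema_region_masks(spec)
        phantom = make_nema_phantom(spec)
        assert len(masks["spheres"]) == 6
        assert tuple(spec.sphere_diameters_mm) == (10, 13, 17, 22, 28, 37)
        cold = [m for i, m in enumerate(masks["spheres"]) if i >= 4]
        assert all(phantom.values[m].max() == 0.0 for m in cold)
        assert phantom.values[masks["insert"]].max() == 0.0

    def test_unit_ratio_makes_hot_spheres_invisible(self):
        spec = NemaPhantomSpec(sphere_to_background_ratio=1.0)
        phantom = make_nema_phantom(spec)
        masks = nema_region_masks(spec)
        assert phantom.values[masks["spheres"][0]].mean() == \
            phantom.values[masks["background"]].mean()

    def test_sphere_outside_body_raises(self):
        with pytest.raises(GeometryError):
            make_nema_phantom(NemaPhantomSpec(body_radius_mm=60.0))

    def test_decreasing_diameters_rejected(self):
        with pytest.raises(GeometryError):
            NemaPhantomSpec(sphere_diameters_mm=(10, 9, 17, 22, 28, 37))


class TestCharacterization:
    def test_constant_image_is_degenerate(self):
        char = characterize_image(np.full((32, 32), 3.0))
        assert char.entropy == 0.0
        assert char.fractal_dimension == 0.0
        assert char.degenerate

    def test_mirror_symmetric_image_scores_one(self, rng):
        half = rng.random((32, 16))
        img = np.concatenate([half, half[:, ::-1]], axis=1)
        assert characterize_image(img).symmetry == 1.0

    def test_symmetry_invariant_to_mirroring(self, rng):
        img = rng.random((32, 32))
        assert characterize_image(img).symmetry == \
            pytest.approx(characterize_image(img[:, ::-1]).symmetry)

    def test_filled_square_has_plane_dimension(self):
        img = np.zeros((128, 128))
        img[:, :64] = 1.0
        fd = characterize_image(img).fractal_dimension
        assert fd == pytest.approx(2.0, abs=0.1)

    def test_entropy_invariant_to_intensity_offset(self, rng):
        img = rng.random((64, 64))
        a = characterize_image(img).entropy
        b = characterize_image(img + 5.0).entropy
        assert a == pytest.approx(b, abs=1e-12)


class TestTrainingSet:
    def test_seeded_determinism(self):
        a = make_training_set(5, seed=1, image_size=32, n_angles=24)
        b = make_training_set(5, seed=1, image_size=32, n_angles=24)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.target.values, pb.target.values)
            assert np.array_equal(pa.sinogram.values, pb.sinogram.values)

    def test_unreachable_metric_range_raises(self):
        with pytest.raises(SamplingError):
            make_training_set(2, seed=0, image_size=32, n_angles=12,
                              target_metrics={"entropy": (50.0, 60.0)})

    def test_inverse_crime_reconstruction_correlates(self):
        """FBP of each generated sinogram should recover its own target."""
        from modgan.classical import fbp
        from modgan.evaluation import ssim_index

        pairs = make_training_set(2, seed=4, image_size=128, n_angles=180)
        for p in pairs:
            rec = fbp(p.sinogram)
            truth = p.target.denormalize()
            score = ssim_index(rec.values, truth,
                               data_range=truth.max() - truth.min())
            assert score > 0.5

    def test_toy_brain_map_has_all_tissues(self, brain_map):
        assert set(np.unique(brain_map.labels)) == {0, 1, 2, 3, 4}
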