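import numpy as np
import pytest
from scipy import ndimage as ndi

import tauscape as ts
from tauscape.extraction import mean_kernel_width_vox, _component_structure
from tauscape.io import ValidationError
from tauscape.synthetic import detection_scores
from helpers_oracles import direct_gaussian_mean_difference, flood_fill_components

PARAMS = ts.ExtractionParams()


def _volume(data, pitch=8.3):
    if np.isscalar(pitch):
        pitch = (pitch,) * 3
    return ts.Volume3D(data=data, voxel_pitch_um=pitch)


class TestResample:
    def test_already_isotropic_is_identity(self, rng):
        vol = _volume(rng.uniform(0, 5, (6, 6, 6)))
        assert ts.resample_to_standard(vol, 8.3) is vol

    def test_constant_volume_stays_constant(self):
        vol = _volume(np.full((10, 12, 12), 7.0), pitch=(8.3, 6.5, 6.5))
        out = ts.resample_to_standard(vol, 8.3)
        assert out.voxel_pitch_um == (8.3, 8.3, 8.3)
        np.testing.assert_allclose(out.data, 7.0)

    def test_linear_ramp_matches_analytic_values(self):
        # value at physical coordinate x um is x/10 (ramp along x)
        nx = 40
        x_centers = (np.arange(nx) + 0.5) * 6.5
        data = np.broadcast_to(x_centers / 10.0, (4, 4, nx)).copy()
        vol = _volume(data, pitch=(8.3, 8.3, 6.5))
        out = ts.resample_to_standard(vol, 8.3)
        new_x = (np.arange(out.shape[2]) + 0.5) * 8.3
        interior = (new_x > x_centers[0]) & (new_x < x_centers[-1])
        np.testing.assert_allclose(
            out.data[2, 2, interior], new_x[interior] / 10.0, atol=1e-6
        )


class TestGaussianMeanDifference:
    def test_constant_input_maps_to_zero(self):
        out = ts.gaussian_mean_difference(_volume(np.full((12, 12, 12), 7.0)), PARAMS)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_mean_kernel_forced_odd(self):
        assert mean_kernel_width_vox(PARAMS) == 11  # 83/8.3 = 10 -> nearest odd
        with pytest.raises(ValidationError):
            mean_kernel_width_vox(PARAMS.replace(mean_extent_um=1.0))

    def test_impulse_response_matches_direct_convolution(self):
        data = np.zeros((21, 21, 21))
        data[10, 10, 10] = 1.0
        out = ts.gaussian_mean_difference(_volume(data), PARAMS).data
        ref = direct_gaussian_mean_difference(data, PARAMS.sigma_small_vox, 11)
        np.testing.assert_allclose(out, ref, atol=1e-6 * np.abs(ref).max())

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_volumes_match_direct_convolution(self, seed):
        data = np.random.default_rng(seed).uniform(0, 100, (15, 17, 21))
        out = ts.gaussian_mean_difference(_volume(data), PARAMS).data
        ref = direct_gaussian_mean_difference(data, PARAMS.sigma_small_vox, 11)
        np.testing.assert_allclose(out, ref, rtol=1e-6, atol=1e-6)

    def test_anisotropic_input_rejected(self):
        with pytest.raises(ValidationError, match="isotropic"):
            ts.gaussian_mean_difference(
                _volume(np.ones((4, 4, 4)), pitch=(8.3, 6.5, 6.5)), PARAMS
            )

    def test_kernel_fwhm_is_about_16_um(self):
        assert ts.gaussian_fwhm_um(0.83, 8.3) == pytest.approx(16.22, abs=0.01)


class TestBrainMask:
    def test_block_shrinks_by_one_face_layer_per_erosion(self):
        data = np.zeros((50, 50, 50))
        data[10:40, 10:40, 10:40] = 10.0
        mask = ts.compute_brain_mask(_volume(data), PARAMS)
        # threshold 1.5 x mean keeps the 30^3 block; 10 erosions -> 10^3 core
        expected = np.zeros_like(data, dtype=bool)
        expected[20:30, 20:30, 20:30] = True
        np.testing.assert_array_equal(mask.mask, expected)
        assert mask.n_voxels_inside == 1000

    def test_all_zero_volume_gives_empty_mask(self):
        mask = ts.compute_brain_mask(_volume(np.zeros((8, 8, 8))), PARAMS)
        assert mask.n_voxels_inside == 0

    def test_zero_iterations_returns_raw_threshold_mask(self):
        data = np.zeros((10, 10, 10))
        data[2:8, 2:8, 2:8] = 4.0
        p = PARAMS.replace(erosion_iterations=0)
        mask = ts.compute_brain_mask(_volume(data), p)
        np.testing.assert_array_equal(
            mask.mask, data > 1.5 * data.mean()
        )


def _spot_setup(candidate_voxels, shape=(5, 5, 5)):
    """Build diff/raw/mask so that exactly candidate_voxels are candidates."""
    diff = np.zeros(shape)
    for v in candidate_voxels:
        diff[v] = 5.0
    raw = np.ones(shape)
    mask = np.ones(shape, dtype=bool)
    mask[0, 0, 0] = False  # outside voxel, raw 1 -> threshold 2
    return ts.DifferenceVolume(data=diff, params=PARAMS), _volume(raw), ts.BrainMask(mask=mask)


class TestExtractSpots:
    def test_separated_blobs_are_two_spots_with_conservation(self):
        vox = [(1, 1, 1), (1, 1, 2), (3, 3, 3)]
        diff, raw, mask = _spot_setup(vox)
        table = ts.extract_spots(diff, raw, mask, PARAMS)
        assert len(table) == 2
        assert sum(s.volume_vox for s in table.spots) == len(vox)

    def test_face_touching_blobs_merge_under_both_connectivities(self):
        vox = [(2, 2, 2), (2, 2, 3)]
        for conn in (6, 26):
            diff, raw, mask = _spot_setup(vox)
            table = ts.extract_spots(diff, raw, mask, PARAMS.replace(connectivity=conn))
            assert len(table) == 1

    def test_corner_touching_blobs_split_under_6_merge_under_26(self):
        vox = [(2, 2, 2), (3, 3, 3)]
        diff, raw, mask = _spot_setup(vox)
        assert len(ts.extract_spots(diff, raw, mask, PARAMS)) == 2
        assert len(ts.extract_spots(
            diff, raw, mask, PARAMS.replace(connectivity=26))) == 1

    def test_single_voxel_centroid_sits_at_voxel_centre(self):
        diff, raw, mask = _spot_setup([(2, 2, 2)])
        spot = ts.extract_spots(diff, raw, mask, PARAMS).spots[0]
        assert spot.centroid_um == pytest.approx((2.5 * 8.3,) * 3)

    def test_empty_outside_mask_rejected(self):
        diff, raw, _ = _spot_setup([(2, 2, 2)])
        full = ts.BrainMask(mask=np.ones((5, 5, 5), dtype=bool))
        with pytest.raises(ValidationError, match="outside"):
            ts.extract_spots(diff, raw, full, PARAMS)

    def test_raising_threshold_never_adds_candidates(self, planted_sample):
        _, _, volume, _ = planted_sample
        diff = ts.gaussian_mean_difference(volume, PARAMS)
        mask = ts.compute_brain_mask(volume, PARAMS)
        counts = []
        for factor in (1.0, 2.0, 4.0, 8.0):
            p = PARAMS.replace(spot_threshold_factor=factor)
            table = ts.extract_spots(diff, volume, mask, p)
            counts.append(sum(s.volume_vox for s in table.spots))
        assert counts == sorted(counts, reverse=True)


class TestComponentLabellingOracle:
    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_labelling_agrees_with_flood_fill_on_random_grids(self, connectivity):
        rng = np.random.default_rng(42)
        for _ in range(200):
            grid = rng.uniform(size=(8, 8, 8)) < 0.35
            labels, n = ndi.label(grid, structure=_component_structure(connectivity))
            expected = flood_fill_components(grid, connectivity)
            assert n == len(expected)
            got = {
                frozenset(zip(*np.nonzero(labels == i))) for i in range(1, n + 1)
            }
            assert got == set(expected)


class TestPlantedRecovery:
    def test_planted_deposits_recovered_with_subvoxel_centroids(self, planted_sample):
        _, specs, volume, _ = planted_sample
        table = ts.extract_from_volume(volume)
        scores = detection_scores(table, specs)
        assert scores["n_recovered"] == 20
        assert scores["max_centroid_error_vox"] <= 1.0
        assert scores["f"] >= 0.95


class TestRunExtraction:
    def test_end_to_end_csv_matches_planted_count_and_is_deterministic(
        self, planted_sample, tmp_path
    ):
        _, specs, volume, _ = planted_sample
        vol_path = str(tmp_path / "vol.nrrd")
        ts.write_volume(volume, vol_path)
        out1 = tmp_path / "spots1.csv"
        out2 = tmp_path / "spots2.csv"
        table = ts.run_extraction(vol_path, str(out1))
        ts.run_extraction(vol_path, str(out2))
        scores = detection_scores(table, specs)
        assert scores["n_recovered"] == len(specs)
        assert out1.read_bytes() == out2.read_bytes()

    def test_zero_volume_yields_empty_csv_and_warning(self, tmp_path, caplog):
        vol_path = str(tmp_path / "zeros.nrrd")
        ts.write_volume(_volume(np.zeros((8, 8, 8))), vol_path)
        out = tmp_path / "spots.csv"
        with caplog.at_level("WARNING", logger="tauscape"):
            table = ts.run_extraction(vol_path, str(out))
        assert len(table) == 0
        assert ts.read_spot_table(str(out)).spots == []
        assert any("empty" in r.message or "no spots" in r.message
                   for r in caplog.records)
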