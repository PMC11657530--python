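"""Row preprocessing oracles, masking rules, spectral corrections, fusion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from fadefit.hsi_core import HyperCube, PixelBlock, SpectralAxis, to_pixel_block
from fadefit.preprocess import (
    BlockAutoscaler,
    PreprocessConfig,
    autoscale_block,
    combine_masks,
    fuse_blocks,
    km_self_absorption_correct,
    mask_fluorescence,
    mask_specular,
    row_profile_correct,
    savgol_deriv_rows,
    scale01_rows,
    snv_rows,
    to_pseudoabsorbance,
)
from fadefit.synthetic import SceneConfig, make_scene


def _block(matrix, block="F"):
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    index = np.column_stack([np.zeros(n, int), np.zeros(n, int), np.arange(n)])
    labels = [(block, 500.0 + 10.0 * j) for j in range(matrix.shape[1])]
    return PixelBlock(matrix, index, labels)


def savgol_brute(row, window, order):
    """Sliding local least-squares polynomial fit; derivative at each point.

    Edge points reuse the polynomial fitted to the first/last full window.
    """
    n = len(row)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = min(max(i - half, 0), n - window)
        xs = np.arange(lo, lo + window, dtype=float)
        coeffs = np.polyfit(xs, row[lo:lo + window], order)
        out[i] = np.polyval(np.polyder(coeffs), i)
    return out


class TestRowTransforms:
    def test_minmax_forced_by_formula(self):
        out = scale01_rows(_block([[2.0, 4.0, 6.0]]))
        np.testing.assert_allclose(out.matrix, [[0.0, 0.5, 1.0]])

    def test_minmax_constant_row_zeroed_and_flagged(self):
        out = scale01_rows(_block([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]]))
        np.testing.assert_array_equal(out.matrix[0], 0.0)
        assert 0 in out.flags

    def test_snv_hand_example(self):
        out = snv_rows(_block([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out.matrix, [[-1.0, 0.0, 1.0]])

    @settings(max_examples=30, derandomize=True)
    @given(arrays(float, (3, 8), elements=st.floats(-100, 100)))
    def test_snv_rows_have_zero_mean_unit_sd(self, mat):
        if np.any(mat.std(axis=1, ddof=1) == 0):
            return
        out = snv_rows(_block(mat))
        assert np.all(np.abs(out.matrix.mean(axis=1)) < 1e-12)
        assert np.all(np.abs(out.matrix.std(axis=1, ddof=1) - 1) < 1e-12)

    def test_savgol_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        mat = rng.normal(size=(5, 30))
        out = savgol_deriv_rows(_block(mat), order=3, window=7)
        expected = np.array([savgol_brute(r, 7, 3) for r in mat])
        np.testing.assert_allclose(out.matrix, expected, atol=1e-9)

    def test_savgol_reproduces_cubic_derivative(self):
        x = np.arange(40.0)
        row = 0.5 * x**3 - 2 * x**2 + 3 * x - 7
        out = savgol_deriv_rows(_block(row[None, :]), order=3, window=7)
        np.testing.assert_allclose(out.matrix[0], 1.5 * x**2 - 4 * x + 3,
                                   rtol=1e-9, atol=1e-6)

    def test_savgol_constant_row_gives_zero(self):
        out = savgol_deriv_rows(_block(np.full((1, 10), 3.3)))
        np.testing.assert_allclose(out.matrix, 0.0, atol=1e-12)

    def test_savgol_short_row_rejected(self):
        with pytest.raises(ValueError, match="window"):
            savgol_deriv_rows(_block(np.zeros((1, 5))), order=3, window=7)

    @settings(max_examples=30, derandomize=True)
    @given(arrays(float, (2, 6), elements=st.floats(-50, 50)),
           st.floats(0.1, 100))
    def test_closure_scale_invariance_and_idempotence(self, mat, scale):
        if np.any(np.abs(mat).sum(axis=1) == 0):
            return
        once = row_profile_correct(_block(mat))
        scaled = row_profile_correct(_block(scale * mat))
        np.testing.assert_allclose(scaled.matrix, once.matrix, atol=1e-12)
        twice = row_profile_correct(once)
        np.testing.assert_allclose(twice.matrix, once.matrix, atol=1e-12)
        np.testing.assert_allclose(np.abs(once.matrix).sum(axis=1), 1.0)


class TestAutoscale:
    def test_hand_computed_two_by_two(self):
        out, scaler = autoscale_block(_block([[0.0, 10.0], [2.0, 20.0]]))
        v = 1 / np.sqrt(2)
        np.testing.assert_allclose(out.matrix, [[-v, -v], [v, v]])

    def test_columns_standardized_and_constant_dropped(self):
        rng = np.random.default_rng(8)
        mat = rng.normal(size=(20, 4))
        mat[:, 2] = 7.0
        out, scaler = autoscale_block(_block(mat))
        assert out.matrix.shape[1] == 3
        np.testing.assert_allclose(out.matrix.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(out.matrix.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_inverse_transform_round_trips(self):
        rng = np.random.default_rng(9)
        mat = rng.normal(size=(10, 3))
        scaler = BlockAutoscaler().fit(mat)
        np.testing.assert_allclose(scaler.inverse_transform(scaler.transform(mat)),
                                   mat, atol=1e-12)


class TestMasks:
    def test_specular_strict_inequality(self, axis5):
        data = np.full((3, 3, 5), 0.5)
        data[0, 0, 2] = 1.2
        data[1, 1, 3] = 1.2
        data[2, 2, 0] = 1.0  # exactly 1.0 stays valid
        cube = HyperCube(data, axis5, "reflectance")
        mask = mask_specular(cube)
        assert (~mask).sum() == 2
        assert mask[2, 2]

    def test_no_values_above_one_masks_nothing(self, axis5):
        cube = HyperCube(np.full((2, 2, 5), 0.9), axis5, "reflectance")
        assert mask_specular(cube).all()

    def test_kmeans_recovers_planted_background(self, axis5):
        rng = np.random.default_rng(10)
        data = np.full((8, 8, 5), 0.1) + rng.normal(0, 0.01, (8, 8, 5))
        bright = np.zeros((8, 8), dtype=bool)
        bright[2:6, 2:6] = True
        data[bright] += 10.0
        cube = HyperCube(np.abs(data), axis5, "fluorescence")
        mask = mask_fluorescence(cube, k=2, seed=0)
        np.testing.assert_array_equal(mask, bright)

    def test_kmeans_deterministic_given_seed(self, axis5):
        rng = np.random.default_rng(11)
        data = rng.uniform(0, 5, (6, 6, 5))
        cube = HyperCube(data, axis5, "fluorescence")
        m1 = mask_fluorescence(cube, seed=42)
        m2 = mask_fluorescence(cube, seed=42)
        np.testing.assert_array_equal(m1, m2)

    def test_uniform_cube_is_degenerate(self, axis5):
        cube = HyperCube(np.full((4, 4, 5), 2.0), axis5, "fluorescence")
        with pytest.raises(ValueError, match="contrast"):
            mask_fluorescence(cube)

    def test_combine_is_logical_and(self):
        a = np.ones((4, 4), dtype=bool)
        b = a.copy()
        a[0, :3] = False
        b[1, :] = False
        combined = combine_masks([a, b])
        assert (~combined).sum() == 7
        np.testing.assert_array_equal(combine_masks([a, a]), a)

    def test_combine_shape_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            combine_masks([np.ones((2, 2), bool), np.ones((3, 3), bool)])


class TestSpectralCorrections:
    def test_km_identity_when_reflectance_is_one(self, axis5):
        F = HyperCube(np.random.default_rng(1).random((3, 3, 5)), axis5,
                      "fluorescence")
        R = HyperCube(np.ones((3, 3, 5)), axis5, "reflectance")
        out = km_self_absorption_correct(F, R)
        np.testing.assert_allclose(out.data, F.data, atol=1e-15)

    def test_km_monotone_in_absorption(self, axis5):
        F = HyperCube(np.ones((1, 2, 5)), axis5, "fluorescence")
        R = HyperCube(np.stack([np.full((1, 5), 0.8),
                                np.full((1, 5), 0.4)], axis=1), axis5,
                      "reflectance")
        out = km_self_absorption_correct(F, R)
        assert np.all(out.data[0, 1] > out.data[0, 0])

    def test_km_hand_computed_value(self, axis5):
        F = HyperCube(np.ones((1, 1, 5)), axis5, "fluorescence")
        R = HyperCube(np.full((1, 1, 5), 0.5), axis5, "reflectance")
        out = km_self_absorption_correct(F, R)
        np.testing.assert_allclose(out.data, 4.0 / 3.0)

    def test_km_axis_mismatch_rejected(self, axis5):
        F = HyperCube(np.ones((1, 1, 3)), SpectralAxis([1.0, 2.0, 3.0]),
                      "fluorescence")
        R = HyperCube(np.ones((1, 1, 5)), axis5, "reflectance")
        with pytest.raises(ValueError, match="axis"):
            km_self_absorption_correct(F, R)

    @pytest.mark.parametrize("r, expected", [(1.0, 0.0), (0.1, 1.0), (0.0, 4.0)])
    def test_pseudoabsorbance_log_identities(self, axis5, r, expected):
        cube = HyperCube(np.full((1, 1, 5), r), axis5, "reflectance")
        out = to_pseudoabsorbance(cube)
        np.testing.assert_allclose(out.data, expected)
        assert out.modality == "pseudoabsorbance"


class TestFusion:
    def test_widths_add_and_labels_ordered(self):
        rng = np.random.default_rng(13)
        F = _block(rng.normal(size=(10, 4)), "F")
        R = _block(rng.normal(size=(10, 3)), "R")
        fused = fuse_blocks(F, R)
        assert fused.matrix.shape == (10, 7)
        assert [b for b, _ in fused.variable_labels] == ["F"] * 4 + ["R"] * 3
        assert fused.n_f == 4

    def test_fused_columns_are_autoscaled(self):
        rng = np.random.default_rng(14)
        fused = fuse_blocks(_block(rng.normal(2, 5, (30, 4)), "F"),
                            _block(rng.normal(-1, 0.1, (30, 3)), "R"))
        np.testing.assert_allclose(fused.matrix.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(fused.matrix.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_spatial_index_mismatch_rejected(self):
        rng = np.random.default_rng(15)
        F = _block(rng.normal(size=(5, 3)), "F")
        R = _block(rng.normal(size=(5, 3)), "R")
        R.spatial_index = R.spatial_index[::-1].copy()
        with pytest.raises(ValueError, match="spatial_index"):
            fuse_blocks(F, R)


class TestPreprocessConfig:
    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            PreprocessConfig(savgol_window=6)

    def test_config_file_round_trip(self, tmp_path):
        path = tmp_path / "pp.cfg"
        path.write_text("specular_threshold = 0.95\nkmeans_seed = 7\n"
                        "# comment\nsavgol_window = 9\n")
        cfg = PreprocessConfig.from_file(path)
        assert cfg.specular_threshold == 0.95
        assert cfg.kmeans_seed == 7
        assert cfg.savgol_window == 9

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "pp.cfg"
        path.write_text("bogus = 1\n")
        with pytest.raises(KeyError):
            PreprocessConfig.from_file(path)
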