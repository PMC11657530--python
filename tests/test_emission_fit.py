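"""Skew-normal model evaluation, staged fitting, and degradation maps."""

import numpy as np
import pytest
from scipy.special import erf

from fadefit.emission_fit import (
    CompositeModel,
    FLAG_DYE_FREE,
    FLAG_MASKED,
    FitConfig,
    ParamSpec,
    SkewNormalParams,
    derive_fit_config,
    fit_composite,
    fit_pixelwise,
    fit_single,
    skew_normal,
)
from fadefit.hsi_core import HyperCube, SpectralAxis


@pytest.fixture
def cluster_endpoint_models(wool_shape):
    """Composite models at the three degradation states of the worked case."""
    return [
        CompositeModel(SkewNormalParams(a_w, 580, 95, 550, 10),
                       SkewNormalParams(1.0, lm, 70, 630, 20))
        for a_w, lm in ((0.05, 692.0), (0.175, 663.5), (0.3, 635.0))
    ]


class TestSkewNormal:
    def test_zero_amplitude_is_identically_zero(self, emission_grid):
        params = SkewNormalParams(0.0, 692, 70, 630, 20)
        np.testing.assert_array_equal(skew_normal(emission_grid, params), 0.0)

    def test_symmetry_limit_for_huge_shape_parameter(self):
        params = SkewNormalParams(1.0, 692, 70, 630, 1e6)
        lam = np.array([692.0 - 30, 692.0 + 30])
        lo, hi = skew_normal(lam, params)
        assert hi / lo == pytest.approx(1.0, abs=1e-4)

    def test_direct_closed_form_value(self):
        params = SkewNormalParams(1.0, 692, 70, 630, 20)
        val = skew_normal(np.array([692.0]), params)[0]
        assert val == pytest.approx(0.5 * (1 + erf(62 / (20 * np.sqrt(2)))),
                                    abs=1e-12)

    def test_nonnegative_and_vanishing_far_away(self):
        params = SkewNormalParams(2.0, 692, 70, 630, 20)
        lam = np.linspace(-2000, 4000, 500)
        vals = skew_normal(lam, params)
        assert np.all(vals >= 0)
        assert vals[0] < 1e-12 and vals[-1] < 1e-12

    @pytest.mark.parametrize("bad", [dict(A=-1), dict(sigma=0), dict(s=-2)])
    def test_invalid_parameters_rejected(self, bad):
        kwargs = dict(A=1.0, lambda_max=692, sigma=70, p=630, s=20)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            SkewNormalParams(**kwargs)


class TestFitSingle:
    def test_noiseless_wool_recovery(self, emission_grid, wool_shape):
        y = skew_normal(emission_grid, wool_shape)
        params, diag = fit_single(emission_grid, y)
        assert diag.converged
        rel = np.abs(params.as_array() - wool_shape.as_array()) / \
            np.abs(wool_shape.as_array())
        assert np.all(rel < 1e-4)

    def test_all_zero_spectrum_flagged_degenerate(self, emission_grid):
        params, diag = fit_single(emission_grid, np.zeros_like(emission_grid))
        assert params.A == 0.0
        assert diag.flag == FLAG_DYE_FREE

    def test_noisy_recovery_median_peak_error_below_1nm(self, emission_grid,
                                                        wool_shape):
        """1%-of-peak Gaussian noise, 100 seeds: median lambda_max error < 1 nm."""
        y0 = skew_normal(emission_grid, wool_shape)
        rng = np.random.default_rng(100)
        errs = []
        for _ in range(100):
            y = y0 + rng.normal(0, 0.01 * y0.max(), y0.size)
            params, diag = fit_single(emission_grid, y)
            errs.append(abs(params.lambda_max - wool_shape.lambda_max))
        assert np.median(errs) < 1.0


class TestFitComposite:
    def test_noiseless_endpoint_recovery(self, emission_grid, wool_shape):
        truth = CompositeModel(SkewNormalParams(0.05, 580, 95, 550, 10),
                               SkewNormalParams(1.0, 692, 70, 630, 20))
        model, diag = fit_composite(emission_grid, truth(emission_grid), wool_shape)
        assert diag.converged
        assert model.amplitude_ratio == pytest.approx(0.05, rel=0.02)
        assert model.ic.lambda_max == pytest.approx(692.0, abs=0.5)

    def test_wool_shape_is_frozen(self, emission_grid, wool_shape):
        truth = CompositeModel(SkewNormalParams(0.2, 580, 95, 550, 10),
                               SkewNormalParams(1.0, 660, 70, 630, 20))
        model, _ = fit_composite(emission_grid, truth(emission_grid), wool_shape)
        assert model.wool.lambda_max == wool_shape.lambda_max
        assert model.wool.sigma == wool_shape.sigma

    def test_pure_wool_spectrum_flagged_dye_free(self, emission_grid, wool_shape):
        y = 0.3 * skew_normal(emission_grid, wool_shape)
        model, diag = fit_composite(emission_grid, y, wool_shape)
        assert diag.flag == FLAG_DYE_FREE

    def test_missing_wool_shape_is_an_error(self, emission_grid):
        with pytest.raises(ValueError, match="wool shape"):
            fit_composite(emission_grid, np.ones_like(emission_grid), None)


class TestDeriveFitConfig:
    def test_peak_initial_and_bounds_from_cluster_values(self,
                                                         cluster_endpoint_models):
        cfg = derive_fit_config(cluster_endpoint_models)
        spec = cfg.params["lambda_max_ic"]
        assert spec.init == pytest.approx((692 + 663.5 + 635) / 3)
        assert spec.lower <= 635 and spec.upper >= 692

    def test_all_bounds_bracket_initials(self, cluster_endpoint_models):
        cfg = derive_fit_config(cluster_endpoint_models)
        for spec in cfg.params.values():
            assert spec.lower <= spec.init <= spec.upper

    def test_single_cluster_floor_margins(self, cluster_endpoint_models):
        cfg = derive_fit_config(cluster_endpoint_models[:1])
        spec = cfg.params["lambda_max_ic"]
        assert spec.lower == pytest.approx(682.0)
        assert spec.upper == pytest.approx(702.0)
        a_w = cfg.params["A_w"]
        assert a_w.lower == pytest.approx(max(0.05 - 0.5 * 0.05, 0.0))

    def test_no_fits_is_an_error(self):
        with pytest.raises(ValueError):
            derive_fit_config([])

    def test_inverted_paramspec_impossible(self):
        with pytest.raises(ValueError):
            ParamSpec(init=5.0, lower=6.0, upper=7.0)


class TestFitPixelwise:
    def _uniform_cube(self, emission_grid, spectrum, shape=(3, 3)):
        data = np.broadcast_to(spectrum, shape + spectrum.shape).copy()
        return HyperCube(data, SpectralAxis(emission_grid), "fluorescence")

    def test_constant_cube_gives_constant_maps(self, emission_grid, wool_shape,
                                               cluster_endpoint_models):
        truth = cluster_endpoint_models[1]
        cube = self._uniform_cube(emission_grid, truth(emission_grid))
        cfg = derive_fit_config(cluster_endpoint_models)
        maps = fit_pixelwise(cube, wool_shape, cfg)
        single, _ = fit_composite(emission_grid, truth(emission_grid),
                                  wool_shape, cfg)
        np.testing.assert_allclose(maps.peak_map, single.ic.lambda_max, atol=1e-8)
        np.testing.assert_allclose(maps.ratio_map, single.amplitude_ratio,
                                   rtol=1e-8)
        assert maps.convergence_rate == 1.0

    def test_fully_masked_cube_gives_all_nan(self, emission_grid, wool_shape,
                                             cluster_endpoint_models):
        cube = self._uniform_cube(emission_grid, np.ones_like(emission_grid))
        cube.mask[:] = False
        maps = fit_pixelwise(cube, wool_shape,
                             derive_fit_config(cluster_endpoint_models))
        assert np.isnan(maps.ratio_map).all() and np.isnan(maps.peak_map).all()
        assert (maps.flag_map == FLAG_MASKED).all()

    def test_dye_free_pixel_nan_in_ratio_only(self, emission_grid, wool_shape,
                                              cluster_endpoint_models):
        wool_only = 0.2 * skew_normal(emission_grid, wool_shape)
        cube = self._uniform_cube(emission_grid, wool_only, shape=(1, 1))
        maps = fit_pixelwise(cube, wool_shape,
                             derive_fit_config(cluster_endpoint_models))
        assert maps.flag_map[0, 0] == FLAG_DYE_FREE
        assert np.isnan(maps.ratio_map[0, 0])

    def test_visit_order_independence(self, emission_grid, wool_shape,
                                      cluster_endpoint_models):
        """Masking half the pixels leaves the other half's fits unchanged."""
        rng = np.random.default_rng(60)
        spectra = [CompositeModel(SkewNormalParams(a, 580, 95, 550, 10),
                                  SkewNormalParams(1.0, lm, 70, 630, 20))
                   for a, lm in zip(rng.uniform(0.05, 0.3, 4),
                                    rng.uniform(640, 690, 4))]
        data = np.stack([m(emission_grid) for m in spectra]).reshape(2, 2, -1)
        cube = HyperCube(data, SpectralAxis(emission_grid), "fluorescence")
        cfg = derive_fit_config(cluster_endpoint_models)
        full = fit_pixelwise(cube, wool_shape, cfg)
        cube.mask[0, :] = False
        partial = fit_pixelwise(cube, wool_shape, cfg)
        np.testing.assert_array_equal(partial.peak_map[1], full.peak_map[1])
        np.testing.assert_array_equal(partial.ratio_map[1], full.ratio_map[1])
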