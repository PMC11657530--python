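"""Synthetic reflectance/fluorescence cube pairs with known ground truth.

Real dyed-wool cubes are not distributable, so every pipeline stage is
validated on generated scenes that emulate their salient features:

* fiber-like spatial structure — overlapping sinuous bands on a dark
  background;
* a dye absorption band (Gaussian in pseudoabsorbance, centred at 630 nm)
  that fades linearly with the per-pixel degradation level d in [0, 1];
* a dye emission band that blue-shifts with degradation (peak 692 nm when
  intact to 635 nm when fully degraded) while the wool/dye amplitude ratio
  rises from 0.05 to 0.3;
* a fixed wool substrate emission (skew-normal, 580/95/550/10 nm);
* self-absorption: the emitted composite spectrum is attenuated by the
  Kubelka-Munk escape factor (1 + R)/2, so
  :func:`~fadefit.preprocess.km_self_absorption_correct` restores the true
  composite exactly on noiseless scenes (generator/corrector duality);
* planted specular outlier pixels (one reflectance band set to 1.2) and
  additive Gaussian sensor noise.

The generator is fully deterministic given its seed (geometry and noise use
separate derived streams) and returns a :class:`GroundTruth` with the
per-pixel degradation field, true dye parameters, true amplitude-ratio map
and all planted artifacts, so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import erf

from fadefit.emission_fit import SkewNormalParams, skew_normal
from fadefit.hsi_core import HyperCube, SpectralAxis

__all__ = ["SceneConfig", "GroundTruth", "make_scene", "make_threelevel_scene"]

# endpoint parameters of the worked case (intact vs fully degraded dye)
IC_INTACT = SkewNormalParams(A=1.0, lambda_max=692.0, sigma=70.0, p=630.0, s=20.0)
IC_DEGRADED = SkewNormalParams(A=1.0, lambda_max=635.0, sigma=70.0, p=630.0, s=20.0)
WOOL_SHAPE = SkewNormalParams(A=1.0, lambda_max=580.0, sigma=95.0, p=550.0, s=10.0)
RATIO_ENDPOINTS = (0.05, 0.3)


@dataclass
class SceneConfig:
    """Everything that determines a scene; the seed fixes all randomness."""

    shape: tuple[int, int] = (64, 64)
    wavelength_range: tuple[float, float] = (400.0, 1000.0)
    n_bands: int = 75
    n_fibers: int = 8
    fiber_width: int = 3
    degradation_mode: str = "uniform"      # uniform | radial | per-fiber
    degradation_value: float = 0.0         # d for uniform mode
    ic_intact: SkewNormalParams = IC_INTACT
    ic_degraded: SkewNormalParams = IC_DEGRADED
    wool_params: SkewNormalParams = WOOL_SHAPE
    ratio_endpoints: tuple[float, float] = RATIO_ENDPOINTS
    absorption_center_nm: float = 630.0
    absorption_width_nm: float = 30.0
    absorption_peak: float = 0.8
    absorption_baseline: float = 0.05
    second_band: bool = False              # optional 570 nm vibrational band
    second_band_center_nm: float = 570.0
    second_band_peak_frac: float = 0.6
    background_emission: float = 5e-3
    background_absorbance: float = 0.02
    noise_sd: float = 0.02                 # fraction of the peak measured signal
    n_specular: int = 10
    specular_value: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.degradation_value <= 1.0:
            raise ValueError("degradation must lie in [0, 1]")
        if self.degradation_mode not in ("uniform", "radial", "per-fiber"):
            raise ValueError(f"unknown degradation_mode {self.degradation_mode!r}")
        if self.noise_sd < 0 or self.n_specular < 0:
            raise ValueError("noise_sd and n_specular must be non-negative")

    def axis(self) -> SpectralAxis:
        return SpectralAxis(np.linspace(*self.wavelength_range, self.n_bands))


@dataclass
class GroundTruth:
    """Per-pixel truth the generator guarantees consistent with the cubes."""

    d_map: np.ndarray                       # degradation level, NaN off-fiber
    fiber_mask: np.ndarray                  # bool, True on fibers
    ic_peak_map: np.ndarray                 # true lambda_max_ic (nm), NaN off-fiber
    true_ratio_map: np.ndarray              # true A_w / A_ic, NaN off-fiber
    true_emission: np.ndarray               # noiseless composite cube (rows x cols x bands)
    specular_index: np.ndarray              # (n, 2) planted specular pixel coords
    wool_shape: SkewNormalParams
    zone_map: np.ndarray | None = None      # three-level scenes: zone id 0/1/2
    ic_param_maps: dict = field(default_factory=dict)


def _fiber_geometry(cfg: SceneConfig, rng: np.random.Generator
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Sinuous horizontal fibers; returns (mask, fiber id map, -1 off-fiber)."""
    rows, cols = cfg.shape
    mask = np.zeros(cfg.shape, dtype=bool)
    fiber_id = np.full(cfg.shape, -1, dtype=int)
    x = np.arange(cols)
    for i in range(cfg.n_fibers):
        base = rng.uniform(0, rows)
        amp = rng.uniform(0.02, 0.08) * rows
        period = rng.uniform(0.5, 2.0)
        phase = rng.uniform(0, 2 * np.pi)
        centre = base + amp * np.sin(2 * np.pi * period * x / cols + phase)
        half = cfg.fiber_width / 2.0
        for c in range(cols):
            r_lo = max(int(np.floor(centre[c] - half)), 0)
            r_hi = min(int(np.ceil(centre[c] + half)), rows - 1)
            if r_lo <= r_hi:
                mask[r_lo:r_hi + 1, c] = True
                fiber_id[r_lo:r_hi + 1, c] = i  # later fibers lie on top
    return mask, fiber_id


def _degradation_field(cfg: SceneConfig, fiber_id: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    rows, cols = cfg.shape
    if cfg.degradation_mode == "uniform":
        d = np.full(cfg.shape, cfg.degradation_value)
    elif cfg.degradation_mode == "radial":
        rr, cc = np.mgrid[0:rows, 0:cols]
        radius = np.hypot(rr - (rows - 1) / 2, cc - (cols - 1) / 2)
        d = radius / radius.max()
    else:  # per-fiber
        levels = rng.uniform(0.0, 1.0, size=max(fiber_id.max() + 1, 1))
        d = np.where(fiber_id >= 0, levels[np.clip(fiber_id, 0, None)], 0.0)
    return np.clip(d, 0.0, 1.0)


def _interp_ic(cfg: SceneConfig, d: np.ndarray) -> dict[str, np.ndarray]:
    """Linear interpolation of the dye parameters between the endpoints."""
    a, b = cfg.ic_intact, cfg.ic_degraded
    return {
        "lambda_max": a.lambda_max + d * (b.lambda_max - a.lambda_max),
        "sigma": a.sigma + d * (b.sigma - a.sigma),
        "p": a.p + d * (b.p - a.p),
        "s": a.s + d * (b.s - a.s),
    }


def _render(cfg: SceneConfig, fiber_mask: np.ndarray, d_full: np.ndarray,
            noise_rng: np.random.Generator, mode_tag: str
            ) -> tuple[HyperCube, HyperCube, GroundTruth]:
    """Render the cube pair for a given fiber mask and degradation field."""
    axis = cfg.axis()
    lam = axis.wavelengths
    rows, cols = cfg.shape
    n_bands = len(axis)
    d_map = np.where(fiber_mask, d_full, np.nan)

    # reflectance from a pseudoabsorbance model: band depth scales with 1 - d
    band = np.exp(-((lam - cfg.absorption_center_nm) ** 2)
                  / (2.0 * cfg.absorption_width_nm ** 2))
    if cfg.second_band:
        band = band + cfg.second_band_peak_frac * np.exp(
            -((lam - cfg.second_band_center_nm) ** 2)
            / (2.0 * cfg.absorption_width_nm ** 2))
    A_pseudo = np.full((rows, cols, n_bands), cfg.background_absorbance)
    strength = (1.0 - d_full) * cfg.absorption_peak
    A_pseudo[fiber_mask] = cfg.absorption_baseline + \
        strength[fiber_mask, None] * band[None, :]
    R_data = np.power(10.0, -A_pseudo)

    # true emission: ratio(d) * wool + dye(d), vectorized over fiber pixels
    r0, r1 = cfg.ratio_endpoints
    wool_unit = skew_normal(lam, replace(cfg.wool_params, A=1.0))
    d_f = d_full[fiber_mask]                                  # (n_fiber,)
    icp = _interp_ic(cfg, d_f)
    gauss = np.exp(-((lam[None, :] - icp["lambda_max"][:, None]) ** 2)
                   / (2.0 * icp["sigma"][:, None] ** 2))
    asym = 0.5 * (1.0 + erf((lam[None, :] - icp["p"][:, None])
                            / (icp["s"][:, None] * np.sqrt(2.0))))
    ratio = r0 + d_f * (r1 - r0)
    fiber_emission = ratio[:, None] * wool_unit[None, :] + gauss * asym

    true_emission = np.full((rows, cols, n_bands), cfg.background_emission)
    true_emission[fiber_mask] = fiber_emission
    ic_peak_map = np.full(cfg.shape, np.nan)
    ic_peak_map[fiber_mask] = icp["lambda_max"]
    true_ratio_map = np.full(cfg.shape, np.nan)
    true_ratio_map[fiber_mask] = ratio
    ic_param_maps = {"A_ic": np.where(fiber_mask, 1.0, np.nan)}
    for key in ("lambda_max", "sigma", "p", "s"):
        m = np.full(cfg.shape, np.nan)
        m[fiber_mask] = icp[key]
        ic_param_maps[key] = m

    # self-absorption then sensor noise
    F_data = true_emission * (1.0 + R_data) / 2.0
    peak_signal = float(F_data.max())
    if cfg.noise_sd > 0:
        F_data = np.clip(
            F_data + noise_rng.normal(0.0, cfg.noise_sd * peak_signal, F_data.shape),
            0.0, None)
        R_data = np.clip(
            R_data + noise_rng.normal(0.0, cfg.noise_sd * 0.05, R_data.shape),
            1e-4, 0.999)

    specular_index = np.empty((0, 2), dtype=int)
    if cfg.n_specular > 0:
        flat = noise_rng.choice(rows * cols, size=cfg.n_specular, replace=False)
        specular_index = np.column_stack(np.unravel_index(flat, cfg.shape))
        bands = noise_rng.integers(0, n_bands, size=cfg.n_specular)
        R_data[specular_index[:, 0], specular_index[:, 1], bands] = cfg.specular_value

    meta = {"synthetic": True, "seed": cfg.seed, "degradation_mode": mode_tag}
    R_cube = HyperCube(R_data, axis, "reflectance", None, dict(meta))
    F_cube = HyperCube(F_data, axis, "fluorescence", None, dict(meta))
    truth = GroundTruth(d_map, fiber_mask, ic_peak_map, true_ratio_map,
                        true_emission, specular_index, cfg.wool_params,
                        ic_param_maps=ic_param_maps)
    return R_cube, F_cube, truth


def make_scene(cfg: SceneConfig) -> tuple[HyperCube, HyperCube, GroundTruth]:
    """Render one co-registered (R_cube, F_cube) pair plus its ground truth.

    Per fiber pixel with degradation d: the dye parameters interpolate the
    intact/degraded endpoints linearly, the wool amplitude is set so the
    wool/dye ratio interpolates ``ratio_endpoints``, the pseudoabsorbance
    band scales with (1 - d), and the measured fluorescence equals the true
    composite times the Kubelka-Munk escape factor (1 + R)/2 plus noise.
    """
    geom_rng = np.random.default_rng(cfg.seed)
    noise_rng = np.random.default_rng(cfg.seed + 1)
    fiber_mask, fiber_id = _fiber_geometry(cfg, geom_rng)
    d_full = _degradation_field(cfg, fiber_id, geom_rng)
    return _render(cfg, fiber_mask, d_full, noise_rng, cfg.degradation_mode)


def make_threelevel_scene(cfg: SceneConfig) -> tuple[HyperCube, HyperCube, GroundTruth]:
    """Scene with three vertical zones at d = 0.0, 0.5, 1.0.

    Mirrors the well-preserved / intermediate / highly-degraded cluster
    structure; the zone id map (0, 1, 2 left to right) is returned in the
    ground truth so end-to-end segmentation recovery can be scored.
    """
    geom_rng = np.random.default_rng(cfg.seed)
    noise_rng = np.random.default_rng(cfg.seed + 1)
    rows, cols = cfg.shape
    zone_map = np.broadcast_to(np.minimum(np.arange(cols) * 3 // cols, 2),
                               cfg.shape).copy()
    fiber_mask, _ = _fiber_geometry(cfg, geom_rng)
    d_full = np.array([0.0, 0.5, 1.0])[zone_map]
    R_cube, F_cube, truth = _render(cfg, fiber_mask, d_full, noise_rng, "three-level")
    truth.zone_map = zone_map
    return R_cube, F_cube, truth
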