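"""Two-component skew-normal emission model and pixel-wise degradation maps.

The corrected fluorescence emission of a dyed wool fiber is modelled as the
superposition of the dye (indigo carmine, IC) emission and the wool substrate
emission, each an asymmetric (skew) normal band:

    f(lambda) = A * exp(-(lambda - lambda_max)^2 / (2 sigma^2))
                  * 1/2 * (1 + erf((lambda - p) / (s * sqrt(2))))

with amplitude A, mean wavelength lambda_max (nm), standard deviation sigma
(nm), and an error-function asymmetry factor with location p (nm) and shape
s (nm).  Because of the asymmetry factor the wavelength of maximum emission
differs slightly from lambda_max; the degradation maps report the fitted
lambda_max (the model's peak parameter), not the argmax of the curve.

The fitting protocol is two-staged:

1. the undyed-wool average spectrum is fitted as a single skew normal,
   freezing the wool *shape* (lambda_max_w, sigma_w, p_w, s_w);
2. dyed spectra are fitted as wool + IC with the wool shape fixed and six
   free parameters (A_w, A_ic, lambda_max_ic, sigma_ic, p_ic, s_ic) — first
   on cluster-average spectra to derive initial values and bounds, then
   pixel by pixel over the whole corrected fluorescence block.

Two degradation maps result: the wool/IC amplitude ratio A_w / A_ic (dye
fading increases it) and the IC peak wavelength (degradation blue-shifts it).

All fits are bounded trust-region nonlinear least squares
(:func:`scipy.optimize.least_squares`, method ``trf``); pixel fits are
independent, so results do not depend on visit order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.special import erf

from fadefit.hsi_core import HyperCube

logger = logging.getLogger(__name__)

__all__ = [
    "SkewNormalParams",
    "CompositeModel",
    "ParamSpec",
    "FitConfig",
    "DegradationMaps",
    "skew_normal",
    "fit_single",
    "fit_composite",
    "derive_fit_config",
    "fit_pixelwise",
    "COMPOSITE_PARAM_NAMES",
    "FLAG_OK",
    "FLAG_NOT_CONVERGED",
    "FLAG_DYE_FREE",
    "FLAG_MASKED",
]

COMPOSITE_PARAM_NAMES = ("A_w", "A_ic", "lambda_max_ic", "sigma_ic", "p_ic", "s_ic")
WAVELENGTH_PARAMS = {"lambda_max_ic", "sigma_ic", "p_ic", "s_ic"}

# per-pixel diagnostic flags
FLAG_MASKED = -1
FLAG_OK = 0
FLAG_NOT_CONVERGED = 1
FLAG_DYE_FREE = 2

DYE_FREE_FRACTION = 1e-6  # A_ic below this fraction of its upper bound -> no dye


@dataclass(frozen=True)
class SkewNormalParams:
    """One emission component: amplitude, peak, width and asymmetry.

    A >= 0 (intensity units); lambda_max, sigma, p, s in nm; sigma > 0, s > 0.
    """

    A: float
    lambda_max: float
    sigma: float
    p: float
    s: float

    def __post_init__(self) -> None:
        if self.A < 0:
            raise ValueError("amplitude A must be >= 0")
        if self.sigma <= 0 or self.s <= 0:
            raise ValueError("sigma and s must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.lambda_max, self.sigma, self.p, self.s])

    @classmethod
    def from_array(cls, x: np.ndarray) -> "SkewNormalParams":
        return cls(*(float(v) for v in x))


@dataclass(frozen=True)
class CompositeModel:
    """Wool + IC superposition; evaluation is the sum of both components."""

    wool: SkewNormalParams
    ic: SkewNormalParams

    def __call__(self, lam: np.ndarray) -> np.ndarray:
        return skew_normal(lam, self.wool) + skew_normal(lam, self.ic)

    @property
    def amplitude_ratio(self) -> float:
        """Wool/IC amplitude ratio A_w / A_ic — increases as the dye fades."""
        return self.wool.A / self.ic.A


def skew_normal(lam: np.ndarray, params: SkewNormalParams) -> np.ndarray:
    """Evaluate the skew-normal emission profile on a wavelength grid."""
    lam = np.asarray(lam, dtype=float)
    gauss = np.exp(-((lam - params.lambda_max) ** 2) / (2.0 * params.sigma ** 2))
    asym = 0.5 * (1.0 + erf((lam - params.p) / (params.s * np.sqrt(2.0))))
    return params.A * gauss * asym


def _skew_normal_raw(lam: np.ndarray, A: float, lmax: float, sigma: float,
                     p: float, s: float) -> np.ndarray:
    gauss = np.exp(-((lam - lmax) ** 2) / (2.0 * sigma ** 2))
    return A * gauss * 0.5 * (1.0 + erf((lam - p) / (s * np.sqrt(2.0))))


@dataclass(frozen=True)
class ParamSpec:
    """Initial value and box bounds for one free parameter."""

    init: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower <= self.init <= self.upper:
            raise ValueError(
                f"require lower <= init <= upper, got {self.lower}, {self.init}, {self.upper}"
            )


@dataclass
class FitConfig:
    """Per-parameter initial values/bounds plus optimizer settings."""

    params: dict[str, ParamSpec]
    ftol: float = 1e-10
    xtol: float = 1e-10
    gtol: float = 1e-10
    max_nfev: int = 200

    def vector(self, names: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        x0 = np.array([self.params[n].init for n in names])
        lo = np.array([self.params[n].lower for n in names])
        hi = np.array([self.params[n].upper for n in names])
        return x0, lo, hi


@dataclass
class FitDiagnostics:
    residual_norm: float
    n_iterations: int
    converged: bool
    flag: int = FLAG_OK
    message: str = ""


@dataclass
class DegradationMaps:
    """Per-pixel degradation maps with fit diagnostics.

    ratio_map : A_w / A_ic (dimensionless), NaN where masked, non-converged
        or dye-free.
    peak_map : fitted IC peak wavelength lambda_max_ic (nm), NaN where masked
        or non-converged.
    residual_map, n_iter_map, flag_map : per-pixel diagnostics (flag codes:
        -1 masked, 0 ok, 1 not converged, 2 dye-free).
    """

    ratio_map: np.ndarray
    peak_map: np.ndarray
    residual_map: np.ndarray
    n_iter_map: np.ndarray
    flag_map: np.ndarray
    param_maps: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def convergence_rate(self) -> float:
        attempted = (self.flag_map != FLAG_MASKED).sum()
        if attempted == 0:
            return float("nan")
        ok = np.isin(self.flag_map, (FLAG_OK, FLAG_DYE_FREE)).sum()
        return float(ok) / float(attempted)


# ---------------------------------------------------------------------------
# Single-component fit (undyed wool)
# ---------------------------------------------------------------------------

_SINGLE_NAMES = ("A", "lambda_max", "sigma", "p", "s")


def _default_single_bounds(grid: np.ndarray, y: np.ndarray) -> dict[str, ParamSpec]:
    lo, hi = float(grid.min()), float(grid.max())
    span = hi - lo
    amax = float(max(y.max(), 0.0))
    return {
        "A": ParamSpec(max(amax, 1e-12), 0.0, max(10.0 * amax, 1.0)),
        "lambda_max": ParamSpec(float(grid[np.argmax(y)]), lo - span, hi + span),
        "sigma": ParamSpec(span / 4.0, 1.0, 3.0 * span),
        "p": ParamSpec(lo + span / 4.0, lo - span, hi + span),
        "s": ParamSpec(span / 10.0, 0.5, span),
    }


def fit_single(
    grid: np.ndarray,
    y: np.ndarray,
    init: SkewNormalParams | None = None,
    bounds: dict[str, ParamSpec] | None = None,
    config: FitConfig | None = None,
) -> tuple[SkewNormalParams, FitDiagnostics]:
    """Fit one skew-normal band to a spectrum by bounded least squares.

    Used for the undyed-wool reference spectrum.  Non-convergence yields a
    flagged result, never an exception.  An (almost) all-zero spectrum is
    flagged degenerate with A fitted to ~0.
    """
    grid = np.asarray(grid, dtype=float)
    y = np.asarray(y, dtype=float)
    if grid.shape != y.shape:
        raise ValueError("grid and spectrum must have equal length")
    if not np.all(np.isfinite(y)):
        raise ValueError("spectrum must be finite")
    specs = dict(_default_single_bounds(grid, y))
    if bounds:
        specs.update(bounds)
    if init is not None:
        arr = init.as_array()
        for name, v in zip(_SINGLE_NAMES, arr):
            sp = specs[name]
            specs[name] = ParamSpec(float(np.clip(v, sp.lower, sp.upper)), sp.lower, sp.upper)
    cfg = FitConfig(specs) if config is None else FitConfig(
        specs, config.ftol, config.xtol, config.gtol, config.max_nfev)
    x0, lo, hi = cfg.vector(_SINGLE_NAMES)

    if np.allclose(y, 0.0):
        params = SkewNormalParams(0.0, x0[1], x0[2], x0[3], x0[4])
        return params, FitDiagnostics(0.0, 0, True, FLAG_DYE_FREE, "all-zero spectrum")

    def residuals(x):
        return _skew_normal_raw(grid, *x) - y

    res = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                        ftol=cfg.ftol, xtol=cfg.xtol, gtol=cfg.gtol,
                        max_nfev=cfg.max_nfev if config is not None else 2000)
    params = SkewNormalParams.from_array(res.x)
    diag = FitDiagnostics(float(np.linalg.norm(res.fun)), int(res.nfev),
                          bool(res.success), FLAG_OK if res.success else FLAG_NOT_CONVERGED,
                          res.message)
    return params, diag


# ---------------------------------------------------------------------------
# Composite (wool + IC) fit with frozen wool shape
# ---------------------------------------------------------------------------

def _composite_residual_factory(grid: np.ndarray, y: np.ndarray,
                                wool_shape: SkewNormalParams):
    gauss_w = np.exp(-((grid - wool_shape.lambda_max) ** 2) / (2.0 * wool_shape.sigma ** 2))
    asym_w = 0.5 * (1.0 + erf((grid - wool_shape.p) / (wool_shape.s * np.sqrt(2.0))))
    wool_unit = gauss_w * asym_w  # wool profile at unit amplitude

    def residuals(x):
        a_w, a_ic, lmax, sigma, p, s = x
        return a_w * wool_unit + _skew_normal_raw(grid, a_ic, lmax, sigma, p, s) - y

    return residuals, wool_unit


def default_composite_config(grid: np.ndarray, y: np.ndarray) -> FitConfig:
    """Generic initial values/bounds for a composite fit of one spectrum.

    Used for the cluster-average fits, before :func:`derive_fit_config`
    tightens them for the pixel-by-pixel stage.
    """
    lo, hi = float(grid.min()), float(grid.max())
    span = hi - lo
    amax = float(max(y.max(), 1e-12))
    return FitConfig({
        "A_w": ParamSpec(0.1 * amax, 0.0, 10.0 * amax),
        "A_ic": ParamSpec(amax, 0.0, 10.0 * amax),
        "lambda_max_ic": ParamSpec(float(grid[np.argmax(y)]), lo - span / 2, hi + span / 2),
        "sigma_ic": ParamSpec(span / 4.0, 1.0, 2.0 * span),
        "p_ic": ParamSpec(lo + span / 3.0, lo - span, hi + span),
        "s_ic": ParamSpec(span / 12.0, 0.5, span),
    }, ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=2000)


def fit_composite(
    grid: np.ndarray,
    y: np.ndarray,
    wool_shape: SkewNormalParams | None,
    config: FitConfig | None = None,
) -> tuple[CompositeModel, FitDiagnostics]:
    """Fit wool + IC with the wool shape frozen and six free parameters.

    ``wool_shape`` carries the previously fitted lambda_max_w, sigma_w, p_w,
    s_w (its amplitude field is ignored — A_w is always free).  A fitted
    A_ic pinned at (or within a tiny fraction of) its lower bound flags the
    pixel as dye-free.
    """
    if wool_shape is None:
        raise ValueError("wool shape must be fixed first (fit the undyed wool spectrum)")
    grid = np.asarray(grid, dtype=float)
    y = np.asarray(y, dtype=float)
    if grid.shape != y.shape:
        raise ValueError("grid and spectrum must have equal length")
    cfg = config or default_composite_config(grid, y)
    x0, lo, hi = cfg.vector(COMPOSITE_PARAM_NAMES)
    residuals, _ = _composite_residual_factory(grid, y, wool_shape)
    res = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                        ftol=cfg.ftol, xtol=cfg.xtol, gtol=cfg.gtol,
                        max_nfev=cfg.max_nfev)
    a_w, a_ic, lmax, sigma, p, s = res.x
    model = CompositeModel(
        wool=replace(wool_shape, A=float(a_w)),
        ic=SkewNormalParams(float(a_ic), float(lmax), float(sigma), float(p), float(s)),
    )
    flag = FLAG_OK if res.success else FLAG_NOT_CONVERGED
    a_ic_hi = cfg.params["A_ic"].upper
    # dye-free guard: amplitude pinned at its lower bound, or the fitted dye
    # band contributes negligibly on the grid (optimizer may park an unneeded
    # component outside the observed range instead of zeroing its amplitude)
    ic_contribution = float(skew_normal(grid, model.ic).max())
    signal_scale = float(max(np.abs(y).max(), 1e-300))
    if (a_ic <= cfg.params["A_ic"].lower + DYE_FREE_FRACTION * a_ic_hi
            or ic_contribution <= 1e-3 * signal_scale):
        flag = FLAG_DYE_FREE
    diag = FitDiagnostics(float(np.linalg.norm(res.fun)), int(res.nfev),
                          bool(res.success), flag, res.message)
    return model, diag


# ---------------------------------------------------------------------------
# Pixel-wise configuration derived from cluster fits
# ---------------------------------------------------------------------------

def derive_fit_config(
    cluster_fits: list[CompositeModel],
    margin: float = 0.2,
    wavelength_floor_nm: float = 10.0,
    amplitude_floor_frac: float = 0.5,
    optimizer: dict | None = None,
) -> FitConfig:
    """Build pixel-wise initial values and bounds from the cluster fits.

    Per free parameter: initial = mean of the cluster-fit values; bounds =
    [min, max] over cluster fits expanded by ``margin`` of the span on each
    side, with a floor of +/- ``wavelength_floor_nm`` on wavelength-like
    parameters and +/- ``amplitude_floor_frac`` x initial on amplitudes.
    Amplitude lower bounds are clipped at 0, width/shape lower bounds at
    small positive values so the model stays defined.
    """
    if not cluster_fits:
        raise ValueError("no converged cluster fits to derive a configuration from")
    values = {
        "A_w": [m.wool.A for m in cluster_fits],
        "A_ic": [m.ic.A for m in cluster_fits],
        "lambda_max_ic": [m.ic.lambda_max for m in cluster_fits],
        "sigma_ic": [m.ic.sigma for m in cluster_fits],
        "p_ic": [m.ic.p for m in cluster_fits],
        "s_ic": [m.ic.s for m in cluster_fits],
    }
    hard_floor = {"A_w": 0.0, "A_ic": 0.0, "sigma_ic": 1.0, "s_ic": 0.5}
    specs: dict[str, ParamSpec] = {}
    for name, vals in values.items():
        vals = np.asarray(vals, dtype=float)
        vmin, vmax, vmean = float(vals.min()), float(vals.max()), float(vals.mean())
        expand = margin * (vmax - vmin)
        if name in WAVELENGTH_PARAMS:
            expand = max(expand, wavelength_floor_nm)
        else:
            expand = max(expand, amplitude_floor_frac * abs(vmean))
        lo, hi = vmin - expand, vmax + expand
        if name in hard_floor:
            lo = max(lo, hard_floor[name])
        assert lo <= vmean <= hi, "bound expansion must bracket the initial value"
        specs[name] = ParamSpec(vmean, lo, hi)
    opt = {"ftol": 1e-8, "xtol": 1e-8, "gtol": 1e-8, "max_nfev": 200}
    opt.update(optimizer or {})
    return FitConfig(specs, **opt)


# ---------------------------------------------------------------------------
# Pixel-by-pixel fitting
# ---------------------------------------------------------------------------

def fit_pixelwise(
    F_true: HyperCube,
    wool_shape: SkewNormalParams,
    config: FitConfig,
) -> DegradationMaps:
    """Composite fit at every unmasked pixel of the corrected fluorescence cube.

    Pixel fits share one configuration and are mutually independent, so the
    result is identical for any visit order or partitioning.  Failures are
    recorded per pixel (never fatal): non-converged pixels carry NaN in both
    maps; dye-free pixels (A_ic at its lower bound) carry NaN in the ratio
    map only.
    """
    rows, cols, _ = F_true.shape
    grid = F_true.axis.wavelengths
    shape = (rows, cols)
    ratio = np.full(shape, np.nan)
    peak = np.full(shape, np.nan)
    resid = np.full(shape, np.nan)
    n_iter = np.zeros(shape, dtype=int)
    flags = np.full(shape, FLAG_MASKED, dtype=int)
    param_maps = {n: np.full(shape, np.nan) for n in COMPOSITE_PARAM_NAMES}

    rr, cc = np.nonzero(F_true.mask)
    for r, c in zip(rr, cc):
        model, diag = fit_composite(grid, F_true.data[r, c, :], wool_shape, config)
        flags[r, c] = diag.flag
        resid[r, c] = diag.residual_norm
        n_iter[r, c] = diag.n_iterations
        if diag.flag == FLAG_NOT_CONVERGED:
            continue
        peak[r, c] = model.ic.lambda_max
        for name, val in zip(COMPOSITE_PARAM_NAMES,
                             (model.wool.A, model.ic.A, model.ic.lambda_max,
                              model.ic.sigma, model.ic.p, model.ic.s)):
            param_maps[name][r, c] = val
        if diag.flag == FLAG_DYE_FREE:
            continue  # ratio undefined without dye
        ratio[r, c] = model.wool.A / model.ic.A

    maps = DegradationMaps(ratio, peak, resid, n_iter, flags, param_maps)
    logger.info("fit_pixelwise: %d pixels fitted, convergence rate %.4f",
                rr.size, maps.convergence_rate)
    return maps
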