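"""End-to-end orchestration: preprocess -> fuse -> segment -> fit -> maps.

:func:`run_pipeline` executes the stages in acquisition-processing order on
co-registered reflectance/fluorescence cube pairs:

1. stitch the per-sample cubes onto one canvas and crop both modalities to
   the informative range (default 500-800 nm);
2. mask specular glints (reflectance > 1) and non-fluorescent background
   (k-means), combine masks across modalities;
3. Kubelka-Munk self-absorption correction of the fluorescence; reflectance
   to pseudoabsorbance;
4. row preprocessing (F: 0-1 scaling, SNV, Savitzky-Golay first derivative;
   R: closure) and low-level fusion after separate block autoscaling;
5. PCA of the fused block, PC1 threshold segmentation, cluster mean spectra;
6. two-stage emission fitting: wool reference -> cluster composites ->
   derived pixel-wise bounds -> pixel-by-pixel maps.

The stages are also exposed individually (:func:`preprocess_stage`,
:func:`segment_stage`, :func:`fit_stage`) with on-disk persistence, so a run
can resume from any stage.  The only stochastic ingredient is the k-means
seed, which the configuration fixes: a rerun with identical config and
inputs reproduces every product exactly.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from fadefit.emission_fit import (
    CompositeModel,
    DegradationMaps,
    FLAG_NOT_CONVERGED,
    FitConfig,
    SkewNormalParams,
    default_composite_config,
    derive_fit_config,
    fit_composite,
    fit_pixelwise,
    fit_single,
)
from fadefit.fuse_segment import (
    PC1Segmenter,
    SegmentationResult,
    cluster_mean_spectra,
    segment_block,
)
from fadefit.hsi_core import (
    HyperCube,
    StitchLayout,
    _write_envi_array,
    crop_spectral,
    read_cube,
    stitch,
    to_pixel_block,
    write_cube,
)
from fadefit.preprocess import (
    FusedBlock,
    PreprocessConfig,
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

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "RunReport",
    "PipelineResult",
    "run_pipeline",
    "preprocess_stage",
    "segment_stage",
    "fit_stage",
]


@dataclass
class RunConfig:
    """Inputs and knobs of one pipeline run.

    Cubes may be given in memory (``r_cubes``/``f_cubes``) or as ENVI base
    paths (``r_paths``/``f_paths``), in matching stitch order.  Exactly one
    wool reference source must be set: either previously fitted wool shape
    parameters or the path/cube of an undyed-wool fluorescence measurement.
    """

    r_cubes: list[HyperCube] | None = None
    f_cubes: list[HyperCube] | None = None
    r_paths: list[str] | None = None
    f_paths: list[str] | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    segmentation_mode: str = "auto"
    manual_thresholds: tuple[float, float] | None = None
    wool_params: SkewNormalParams | None = None
    wool_cube: HyperCube | None = None
    wool_cube_path: str | None = None
    fit_margin: float = 0.2
    fit_overrides: dict = field(default_factory=dict)  # FitConfig optimizer keys
    output_dir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        has_mem = self.r_cubes is not None and self.f_cubes is not None
        has_path = self.r_paths is not None and self.f_paths is not None
        if not (has_mem or has_path):
            raise ValueError("provide r/f cubes or r/f paths")
        if has_path:
            for p in list(self.r_paths) + list(self.f_paths):
                if not Path(str(p) + ".hdr").exists():
                    raise FileNotFoundError(f"input cube not found: {p}")
        wool_sources = sum(x is not None for x in
                           (self.wool_params, self.wool_cube, self.wool_cube_path))
        if wool_sources != 1:
            raise ValueError("exactly one wool reference source must be given")
        if self.segmentation_mode == "manual" and self.manual_thresholds is None:
            raise ValueError("manual segmentation requires thresholds")


@dataclass
class RunReport:
    """Machine-readable account of one run; every number is recomputable."""

    version: str
    config_echo: dict
    timings_s: dict[str, float]
    pixel_accounting: dict[str, int]
    explained_variance_ratio: list[float]
    thresholds: tuple[float, float]
    wool_fit: dict
    cluster_fits: dict
    fit_bounds: dict
    convergence_rate: float
    cluster_counts: dict[str, int]

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dict__"):
        return obj.__dict__
    return str(obj)


@dataclass
class PreprocessProducts:
    """Stage 1-4 outputs: corrected cubes, masks, fused block, layout."""

    f_true: HyperCube
    pseudoabsorbance: HyperCube
    fused: FusedBlock
    layout: StitchLayout
    mask_specular: np.ndarray
    mask_nonfluorescent: np.ndarray
    timings: dict[str, float] = field(default_factory=dict)


@dataclass
class PipelineResult:
    """In-memory products of a full run (the report plus all intermediates)."""

    report: RunReport
    f_true: HyperCube
    pseudoabsorbance: HyperCube
    fused: FusedBlock
    segmentation: SegmentationResult
    wool_shape: SkewNormalParams
    cluster_models: dict[str, CompositeModel]
    fit_config: FitConfig
    maps: DegradationMaps
    layout: StitchLayout


def _params_dict(p: SkewNormalParams) -> dict:
    return {"A": p.A, "lambda_max": p.lambda_max, "sigma": p.sigma, "p": p.p, "s": p.s}


def fit_wool_reference(wool_cube: HyperCube, cfg: PreprocessConfig
                       ) -> tuple[SkewNormalParams, dict]:
    """Average the undyed-wool cube's unmasked spectra and fit one skew normal."""
    cube = crop_spectral(wool_cube, cfg.crop_lo, cfg.crop_hi)
    mean_spectrum = cube.data[cube.mask].mean(axis=0)
    params, diag = fit_single(cube.axis.wavelengths, mean_spectrum)
    if not diag.converged:
        raise RuntimeError(f"wool reference fit did not converge: {diag.message}")
    return params, {"params": _params_dict(params), "residual_norm": diag.residual_norm}


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def preprocess_stage(config: RunConfig) -> PreprocessProducts:
    """Stages 1-4: stitch, crop, mask, correct, row-preprocess, fuse."""
    cfg = config.preprocess
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if config.r_cubes is not None:
        r_cubes, f_cubes = list(config.r_cubes), list(config.f_cubes)
    else:
        r_cubes = [read_cube(p, "reflectance") for p in config.r_paths]
        f_cubes = [read_cube(p, "fluorescence") for p in config.f_paths]
    if len(r_cubes) != len(f_cubes):
        raise ValueError("need one fluorescence cube per reflectance cube")
    R, layout = stitch(r_cubes)
    F, _ = stitch(f_cubes, layout)
    R = crop_spectral(R, cfg.crop_lo, cfg.crop_hi)
    F = crop_spectral(F, cfg.crop_lo, cfg.crop_hi)
    timings["stitch_crop"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    m_spec = mask_specular(R, cfg.specular_threshold)
    m_fluo = mask_fluorescence(F, cfg.kmeans_k, cfg.kmeans_seed)
    mask = combine_masks([m_spec, m_fluo, R.mask, F.mask])
    R.mask = mask.copy()
    F.mask = mask.copy()
    timings["masking"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    f_true = km_self_absorption_correct(F, R)
    a_cube = to_pseudoabsorbance(R)
    timings["corrections"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    f_block = to_pixel_block(f_true, block="F")
    f_block = savgol_deriv_rows(snv_rows(scale01_rows(f_block)),
                                cfg.savgol_order, cfg.savgol_window)
    r_block = row_profile_correct(to_pixel_block(a_cube, block="R"),
                                  cfg.row_profile_norm)
    fused = fuse_blocks(f_block, r_block)
    timings["fusion"] = time.perf_counter() - t0

    return PreprocessProducts(f_true, a_cube, fused, layout, m_spec, m_fluo, timings)


def segment_stage(products: PreprocessProducts, config: RunConfig
                  ) -> tuple[SegmentationResult, PC1Segmenter]:
    """Stage 5: PCA, PC1 thresholds, label map, cluster mean spectra."""
    t0 = time.perf_counter()
    segmenter = PC1Segmenter(n_components=2, mode=config.segmentation_mode,
                             manual_thresholds=config.manual_thresholds)
    seg = segment_block(products.fused, products.f_true.data.shape[:2], segmenter)
    seg.cluster_spectra = cluster_mean_spectra(seg.label_map, products.f_true,
                                               products.pseudoabsorbance)
    products.timings["segmentation"] = time.perf_counter() - t0
    return seg, segmenter


def fit_stage(products: PreprocessProducts, seg: SegmentationResult,
              config: RunConfig) -> tuple[SkewNormalParams, dict, dict,
                                          FitConfig, DegradationMaps, dict]:
    """Stage 6: wool reference, cluster composites, pixel-wise maps."""
    t0 = time.perf_counter()
    cfg = config.preprocess
    if config.wool_params is not None:
        wool_shape = config.wool_params
        wool_report = {"params": _params_dict(wool_shape), "source": "stored"}
    else:
        wool_cube = config.wool_cube
        if wool_cube is None:
            wool_cube = read_cube(config.wool_cube_path, "fluorescence")
        wool_shape, wool_report = fit_wool_reference(wool_cube, cfg)
        wool_report["source"] = "undyed-wool cube"

    grid = products.f_true.axis.wavelengths
    cluster_models: dict[str, CompositeModel] = {}
    cluster_report: dict[str, dict] = {}
    for name, spectra in seg.cluster_spectra.items():
        y = spectra["fluorescence"]
        model, diag = fit_composite(grid, y, wool_shape,
                                    default_composite_config(grid, y))
        if diag.flag == FLAG_NOT_CONVERGED:
            logger.warning("cluster %s composite fit did not converge", name)
            continue
        cluster_models[name] = model
        cluster_report[name] = {
            "A_w": model.wool.A,
            "ic": _params_dict(model.ic),
            "amplitude_ratio": model.amplitude_ratio,
            "residual_norm": diag.residual_norm,
        }
    fit_cfg = derive_fit_config(list(cluster_models.values()),
                                margin=config.fit_margin,
                                optimizer=config.fit_overrides)
    maps = fit_pixelwise(products.f_true, wool_shape, fit_cfg)
    products.timings["emission_fit"] = time.perf_counter() - t0
    return wool_shape, wool_report, cluster_report, fit_cfg, maps, cluster_models


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full degradation-mapping pipeline; see the module docstring."""
    config.validate()
    products = preprocess_stage(config)
    seg, segmenter = segment_stage(products, config)
    wool_shape, wool_report, cluster_report, fit_cfg, maps, cluster_models = \
        fit_stage(products, seg, config)

    mask = products.f_true.mask
    total = int(mask.size)
    specular_bad = ~products.mask_specular
    nonfluor_bad = ~products.mask_nonfluorescent
    n_spec_only = int((specular_bad & ~nonfluor_bad).sum())
    n_nonfluor_only = int((nonfluor_bad & ~specular_bad).sum())
    n_both = int((specular_bad & nonfluor_bad).sum())
    n_failed = int((maps.flag_map == FLAG_NOT_CONVERGED).sum())
    n_fitted = int((maps.flag_map >= 0).sum()) - n_failed
    accounting = {
        "total": total,
        "masked_specular": n_spec_only,
        "masked_nonfluorescent": n_nonfluor_only,
        "masked_both": n_both,
        "fitted": n_fitted,
        "failed": n_failed,
    }
    assert sum(v for k, v in accounting.items() if k != "total") == total

    from fadefit import __version__
    report = RunReport(
        version=__version__,
        config_echo={
            "preprocess": vars(config.preprocess),
            "segmentation_mode": config.segmentation_mode,
            "fit_margin": config.fit_margin,
            "seed": config.seed,
        },
        timings_s={k: round(v, 4) for k, v in products.timings.items()},
        pixel_accounting=accounting,
        explained_variance_ratio=[float(v) for v in
                                  segmenter.pca_.explained_variance_ratio],
        thresholds=seg.thresholds,
        wool_fit=wool_report,
        cluster_fits=cluster_report,
        fit_bounds={k: vars(v) for k, v in fit_cfg.params.items()},
        convergence_rate=maps.convergence_rate,
        cluster_counts=seg.counts(),
    )
    result = PipelineResult(report, products.f_true, products.pseudoabsorbance,
                            products.fused, seg, wool_shape, cluster_models,
                            fit_cfg, maps, products.layout)
    if config.output_dir:
        out_dir = Path(config.output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_outputs(result, out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir: Path) -> None:
    """Persist every stage product: ENVI images, PNGs, CSVs and the report."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    seg = result.segmentation
    axis = result.f_true.axis

    write_cube(result.f_true, out_dir / "fluorescence_corrected")
    write_cube(result.pseudoabsorbance, out_dir / "pseudoabsorbance")
    for name, arr in (("score_map", seg.score_map),
                      ("label_map", seg.label_map.astype(float)),
                      ("ratio_map", result.maps.ratio_map),
                      ("peak_map", result.maps.peak_map)):
        _write_envi_array(np.ascontiguousarray(arr, dtype=np.float64),
                          out_dir / name, {"description": "{" + name + "}"})
    plt.imsave(out_dir / "segmentation_rgb.png", seg.rgb)
    for name, arr, cmap in (("ratio_map", result.maps.ratio_map, "viridis"),
                            ("peak_map", result.maps.peak_map, "plasma"),
                            ("score_map", seg.score_map, "coolwarm")):
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(arr, cmap=cmap)
        fig.colorbar(im, ax=ax, label=name)
        ax.set_axis_off()
        fig.savefig(out_dir / f"{name}.png", dpi=120, bbox_inches="tight")
        plt.close(fig)

    rows = {"wavelength_nm": axis.wavelengths}
    for cname, spectra in seg.cluster_spectra.items():
        rows[f"fluorescence_{cname}"] = spectra["fluorescence"]
        rows[f"pseudoabsorbance_{cname}"] = spectra["pseudoabsorbance"]
    pd.DataFrame(rows).to_csv(out_dir / "cluster_mean_spectra.csv", index=False)

    rr, cc = np.nonzero(result.maps.flag_map >= 0)
    pd.DataFrame({
        "row": rr, "col": cc,
        "residual": result.maps.residual_map[rr, cc],
        "iterations": result.maps.n_iter_map[rr, cc],
        "flag": result.maps.flag_map[rr, cc],
    }).to_csv(out_dir / "fit_diagnostics.csv", index=False)

    (out_dir / "layout.json").write_text(result.layout.to_json())
    (out_dir / "report.json").write_text(result.report.to_json())
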