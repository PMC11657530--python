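"""Masking, self-absorption correction, row preprocessing and low-level fusion.

The preprocessing chain mirrors standard chemometric practice for paired
fluorescence (F) and reflectance (R) hyperspectral blocks:

* non-informative pixels are masked — k-means on the fluorescence spectra
  finds non-fluorescent background, and reflectance values above 1 flag
  specular glints (a reflectance factor cannot exceed the white standard
  except by specular reflection);
* the measured fluorescence is corrected for self-absorption with a
  Kubelka-Munk escape factor built from the co-registered diffuse
  reflectance: light emitted inside an opaque scattering sample is partly
  re-absorbed before escaping, and the mean escape probability for a layer
  with reflectance R is (1 + R)/2, so the true emission is estimated as
  F_true = F_measured / ((1 + R)/2).  The factor is 1 where R = 1 (no
  absorption) and the correction grows as R decreases;
* reflectance is converted to pseudoabsorbance A = -log10(R), the
  absorbance-like transform for scattering samples;
* row (per-spectrum) preprocessing: for F, 0-1 intensity scaling, then SNV,
  then a first Savitzky-Golay derivative (order 3, window 7); for R
  (pseudoabsorbance), a closure row-profile correction removing global
  multiplicative intensity effects;
* finally the two blocks are autoscaled separately (per-variable centre and
  unit variance) and concatenated along the variable axis — low-level data
  fusion — yielding the F&R block that feeds PCA segmentation.

Row/column transforms are exposed as scikit-learn style transformers
(``fit``/``transform``, ``get_params``), so they compose with sklearn
pipelines; the module-level functions are thin wrappers operating on
:class:`~fadefit.hsi_core.PixelBlock` objects.  Standard deviations use the
n-1 denominator everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_array, check_is_fitted

from fadefit.hsi_core import HyperCube, PixelBlock

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "FusedBlock",
    "MinMaxRowScaler",
    "SNVRowScaler",
    "SavitzkyGolayDerivative",
    "RowClosure",
    "BlockAutoscaler",
    "mask_fluorescence",
    "mask_specular",
    "combine_masks",
    "km_self_absorption_correct",
    "to_pseudoabsorbance",
    "scale01_rows",
    "snv_rows",
    "savgol_deriv_rows",
    "row_profile_correct",
    "autoscale_block",
    "fuse_blocks",
]

REFLECTANCE_FLOOR = 1e-4


@dataclass
class PreprocessConfig:
    """Tunable knobs of the preprocessing stage (key = value config file)."""

    specular_threshold: float = 1.0
    kmeans_k: int = 2
    kmeans_seed: int = 0
    savgol_order: int = 3
    savgol_window: int = 7
    crop_lo: float = 500.0
    crop_hi: float = 800.0
    row_profile_norm: str = "l1"  # closure; "l2" offered as alternative

    def __post_init__(self) -> None:
        if self.savgol_window % 2 == 0 or self.savgol_window <= self.savgol_order:
            raise ValueError("savgol_window must be odd and > savgol_order")
        if self.kmeans_k < 2:
            raise ValueError("kmeans_k must be >= 2")
        if self.row_profile_norm not in ("l1", "l2"):
            raise ValueError("row_profile_norm must be 'l1' or 'l2'")

    @classmethod
    def from_file(cls, path: str | Path) -> "PreprocessConfig":
        kwargs: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if not line or "=" not in line:
                continue
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in cls.__dataclass_fields__:
                raise KeyError(f"unknown preprocess option {key!r}")
            typ = cls.__dataclass_fields__[key].type
            if typ == "int":
                kwargs[key] = int(val)
            elif typ == "float":
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# sklearn-style row/column transformers
# ---------------------------------------------------------------------------

class _StatelessRowTransformer(TransformerMixin, BaseEstimator):
    """Base for per-row transforms: fit only validates, transform does the work.

    Degenerate rows (constant / zero) are reported in ``flagged_rows_`` after
    each ``transform`` call rather than raising, since a handful of dead
    pixels must not abort an image-scale run.
    """

    def fit(self, X, y=None):
        check_array(X)
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def _flag(self, rows: np.ndarray, reason: str) -> None:
        self.flagged_rows_ = np.flatnonzero(rows)
        if self.flagged_rows_.size:
            logger.warning("%s: %d degenerate rows (%s)",
                           type(self).__name__, self.flagged_rows_.size, reason)


class MinMaxRowScaler(_StatelessRowTransformer):
    """Scale each row (spectrum) to [0, 1]; constant rows become all-zero."""

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X, copy=True)
        lo = X.min(axis=1, keepdims=True)
        hi = X.max(axis=1, keepdims=True)
        span = hi - lo
        degenerate = span[:, 0] == 0
        span[degenerate] = 1.0
        out = (X - lo) / span
        out[degenerate] = 0.0
        self._flag(degenerate, "constant row -> zeros")
        return out


class SNVRowScaler(_StatelessRowTransformer):
    """Standard normal variate: centre each row and scale to unit sd (n-1)."""

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X, copy=True)
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=1, keepdims=True)
        degenerate = sd[:, 0] == 0
        sd[degenerate] = 1.0
        out = (X - mu) / sd
        out[degenerate] = 0.0
        self._flag(degenerate, "zero-variance row")
        return out


class SavitzkyGolayDerivative(_StatelessRowTransformer):
    """First derivative by local least-squares polynomial (Savitzky-Golay).

    Parameters
    ----------
    window : odd window length in data points (default 7).
    order : polynomial order (default 3), must be < window.
    delta : sample spacing the derivative is taken with respect to; the
        default 1.0 differentiates per band index.

    Edges are handled by evaluating the polynomial fitted to the first/last
    window (scipy ``mode="interp"``).
    """

    def __init__(self, window: int = 7, order: int = 3, delta: float = 1.0):
        self.window = window
        self.order = order
        self.delta = delta

    def fit(self, X, y=None):
        if self.window % 2 == 0 or self.window <= self.order:
            raise ValueError("window must be odd and > order")
        X = check_array(X)
        if X.shape[1] < self.window:
            raise ValueError(f"rows of length {X.shape[1]} shorter than window {self.window}")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        if X.shape[1] < self.window:
            raise ValueError("row shorter than window")
        return savgol_filter(X, self.window, self.order, deriv=1,
                             delta=self.delta, axis=1, mode="interp")


class RowClosure(_StatelessRowTransformer):
    """Row-profile correction: normalize each row to unit norm.

    The default "l1" closure divides by the sum of absolute values, making the
    output invariant under multiplication of a row by any positive scalar —
    exactly the global (multiplicative) intensity effect it removes.  "l2"
    (unit Euclidean norm) is the conventional alternative.
    """

    def __init__(self, norm: str = "l1"):
        self.norm = norm

    def transform(self, X):
        check_is_fitted(self)
        if self.norm not in ("l1", "l2"):
            raise ValueError("norm must be 'l1' or 'l2'")
        X = check_array(X, copy=True)
        if self.norm == "l1":
            denom = np.abs(X).sum(axis=1, keepdims=True)
        else:
            denom = np.sqrt((X ** 2).sum(axis=1, keepdims=True))
        degenerate = denom[:, 0] == 0
        denom[degenerate] = 1.0
        out = X / denom
        self._flag(degenerate, "all-zero row")
        return out


class BlockAutoscaler(TransformerMixin, BaseEstimator):
    """Per-variable centring and unit-variance scaling (n-1 sd).

    Zero-variance columns are dropped with a warning; the fitted means and
    standard deviations are kept (``means_``, ``stds_``, ``kept_columns_``)
    for inverse transforms and for scaling held-out pixels consistently.
    """

    def fit(self, X, y=None):
        X = check_array(X)
        means = X.mean(axis=0)
        stds = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(X.shape[1])
        keep = stds > 0
        if not keep.all():
            logger.warning("BlockAutoscaler: dropping %d zero-variance columns",
                           int((~keep).sum()))
        self.n_features_in_ = X.shape[1]
        self.means_ = means
        self.stds_ = stds
        self.kept_columns_ = np.flatnonzero(keep)
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        k = self.kept_columns_
        return (X[:, k] - self.means_[k]) / self.stds_[k]

    def inverse_transform(self, X):
        check_is_fitted(self)
        k = self.kept_columns_
        return np.asarray(X) * self.stds_[k] + self.means_[k]


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------

def mask_fluorescence(F: HyperCube, k: int = 2, seed: int = 0) -> np.ndarray:
    """k-means the raw fluorescence spectra; mark the dimmest cluster invalid.

    The cluster with the lowest mean integrated intensity is taken as
    non-fluorescent background.  Deterministic for a given seed (10 restarts).
    """
    if F.modality != "fluorescence":
        raise ValueError("mask_fluorescence expects a fluorescence cube")
    rows, cols, _ = F.shape
    X = F.data.reshape(rows * cols, -1)
    if np.allclose(X, X[0]):
        raise ValueError("no intensity contrast: all spectra identical")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
    integrated = X.sum(axis=1)
    cluster_mean = np.array([integrated[km.labels_ == c].mean() for c in range(k)])
    dark = int(np.argmin(cluster_mean))
    mask = (km.labels_ != dark).reshape(rows, cols)
    logger.info("mask_fluorescence: %d/%d pixels marked non-fluorescent",
                int((~mask).sum()), mask.size)
    return mask


def mask_specular(R: HyperCube, threshold: float = 1.0) -> np.ndarray:
    """Invalidate pixels with any reflectance band strictly above threshold.

    A reflectance factor above 1 means the pixel returned more light than the
    white standard — a specular glint, not diffuse reflectance.
    """
    if R.modality != "reflectance":
        raise ValueError("mask_specular expects a reflectance cube")
    specular = (R.data > threshold).any(axis=2)
    if specular.any():
        logger.info("mask_specular: %d specular pixels (> %g)", int(specular.sum()), threshold)
    return ~specular


def combine_masks(masks: list[np.ndarray]) -> np.ndarray:
    """Logical AND: a pixel is valid only if valid in every modality."""
    if not masks:
        raise ValueError("no masks given")
    shape = masks[0].shape
    out = np.ones(shape, dtype=bool)
    for m in masks:
        if m.shape != shape:
            raise ValueError("mask shape mismatch")
        out &= m.astype(bool)
    return out


# ---------------------------------------------------------------------------
# Spectral corrections
# ---------------------------------------------------------------------------

def km_self_absorption_correct(F: HyperCube, R: HyperCube,
                               floor: float = REFLECTANCE_FLOOR) -> HyperCube:
    """Kubelka-Munk self-absorption correction of measured fluorescence.

    F_true(lambda) = F_measured(lambda) / ((1 + R(lambda)) / 2), with R
    clipped to (floor, 1] before use.  Identity where R = 1; the correction
    increases monotonically as R decreases (stronger re-absorption).
    """
    if F.axis != R.axis:
        raise ValueError("F and R must share the spectral axis")
    if F.data.shape[:2] != R.data.shape[:2]:
        raise ValueError("F and R must share the spatial grid")
    n_clip = int((R.data < floor).sum())
    if n_clip:
        logger.warning("km_self_absorption_correct: clipped %d reflectance values to %g",
                       n_clip, floor)
    Rc = np.clip(R.data, floor, 1.0)
    corrected = F.data / ((1.0 + Rc) / 2.0)
    mask = F.mask & R.mask
    meta = dict(F.meta)
    meta["self_absorption_corrected"] = True
    return HyperCube(corrected, F.axis, "fluorescence", mask, meta)


def to_pseudoabsorbance(R: HyperCube, floor: float = REFLECTANCE_FLOOR) -> HyperCube:
    """Convert reflectance to pseudoabsorbance A = -log10(R), flooring R."""
    n_clip = int((R.data < floor).sum())
    if n_clip:
        clipped = np.argwhere((R.data < floor).any(axis=2))
        logger.warning("to_pseudoabsorbance: %d values clipped to %g at %d pixels "
                       "(first: %s)", n_clip, floor, clipped.shape[0],
                       clipped[0].tolist() if clipped.size else "-")
    A = -np.log10(np.clip(R.data, floor, None))
    meta = dict(R.meta)
    meta["transform"] = "pseudoabsorbance"
    return HyperCube(A, R.axis, "pseudoabsorbance", R.mask.copy(), meta)


# ---------------------------------------------------------------------------
# PixelBlock wrappers over the transformers
# ---------------------------------------------------------------------------

def _apply(block: PixelBlock, tr: _StatelessRowTransformer, reason: str) -> PixelBlock:
    out = tr.fit(block.matrix).transform(block.matrix)
    flags = {int(i): reason for i in getattr(tr, "flagged_rows_", [])}
    return block.with_matrix(out, flags)


def scale01_rows(block: PixelBlock) -> PixelBlock:
    """0-1 intensity scaling per spectrum (row)."""
    return _apply(block, MinMaxRowScaler(), "constant-row")


def snv_rows(block: PixelBlock) -> PixelBlock:
    """Standard normal variate transform per spectrum (row)."""
    return _apply(block, SNVRowScaler(), "zero-variance-row")


def savgol_deriv_rows(block: PixelBlock, order: int = 3, window: int = 7) -> PixelBlock:
    """First Savitzky-Golay derivative per spectrum (row)."""
    tr = SavitzkyGolayDerivative(window=window, order=order)
    return block.with_matrix(tr.fit(block.matrix).transform(block.matrix))


def row_profile_correct(block: PixelBlock, norm: str = "l1") -> PixelBlock:
    """Closure normalization per spectrum (row), removing multiplicative effects."""
    return _apply(block, RowClosure(norm=norm), "all-zero-row")


def autoscale_block(block: PixelBlock) -> tuple[PixelBlock, BlockAutoscaler]:
    """Autoscale columns; returns the scaled block and the fitted scaler."""
    scaler = BlockAutoscaler().fit(block.matrix)
    scaled = scaler.transform(block.matrix)
    labels = [block.variable_labels[i] for i in scaler.kept_columns_]
    return PixelBlock(scaled, block.spatial_index, labels, dict(block.flags)), scaler


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------

@dataclass
class FusedBlock:
    """Low-level fused F&R block: autoscaled F columns then R columns.

    The per-block scalers are retained so the fused variables can be mapped
    back to physical units or applied to held-out pixels.
    """

    block: PixelBlock
    f_scaler: BlockAutoscaler
    r_scaler: BlockAutoscaler
    n_f: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_f = sum(1 for b, _ in self.block.variable_labels if b == "F")
        blocks = [b for b, _ in self.block.variable_labels]
        if blocks != ["F"] * self.n_f + ["R"] * (len(blocks) - self.n_f):
            raise ValueError("fused columns must be F block then R block")

    @property
    def matrix(self) -> np.ndarray:
        return self.block.matrix

    @property
    def variable_labels(self) -> list[tuple[str, float]]:
        return self.block.variable_labels

    @property
    def spatial_index(self) -> np.ndarray:
        return self.block.spatial_index


def fuse_blocks(F: PixelBlock, R: PixelBlock) -> FusedBlock:
    """Autoscale each block separately, then concatenate columns F then R.

    Requires pixel-exact correspondence: identical spatial_index ordering.
    """
    if F.n_pixels != R.n_pixels or not np.array_equal(F.spatial_index, R.spatial_index):
        raise ValueError("fusion requires identical spatial_index in both blocks")
    fs, f_scaler = autoscale_block(F)
    rs, r_scaler = autoscale_block(R)
    matrix = np.hstack([fs.matrix, rs.matrix])
    labels = list(fs.variable_labels) + list(rs.variable_labels)
    flags = {**fs.flags, **rs.flags}
    fused = PixelBlock(matrix, F.spatial_index.copy(), labels, flags)
    return FusedBlock(fused, f_scaler, r_scaler)
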