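"""PCA of the fused F&R block and PC1-histogram segmentation.

The fused block is decomposed by PCA; the first principal component (PC1)
score of each pixel summarizes, across both modalities, how far its spectrum
has moved from the intact-dye signature, so thresholding the PC1 score
distribution splits pixels into three degradation clusters rendered as a
false-color RGB map: blue (low scores, well preserved), green (medium,
intermediate), red (high, highly degraded).

Thresholds come either from the analyst (manual mode) or automatically as
the two deepest interior minima of a Gaussian kernel density estimate
(Silverman bandwidth) of the PC1 scores — the smoothed analogue of reading
local minima off the score histogram.

PC1 sign is arbitrary in PCA; here it is oriented so that *high* scores
mean *degraded*: the loading on the pseudoabsorbance variable nearest the
dye absorption band (630 nm) is forced negative, because fading depletes
that band, putting faded pixels below the mean on that variable.  If no
reflectance variable is available the fallback makes the largest-magnitude
PC1 loading positive.

:class:`PC1Segmenter` packages the whole stage as a scikit-learn estimator
(fit / predict / fit_predict); the module functions expose the individual
steps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_array, check_is_fitted

from fadefit.hsi_core import HyperCube, PixelBlock
from fadefit.preprocess import FusedBlock

logger = logging.getLogger(__name__)

__all__ = [
    "PCAResult",
    "SegmentationResult",
    "PC1Segmenter",
    "fit_pca",
    "orient_pc1",
    "score_histogram",
    "select_thresholds",
    "segment",
    "cluster_mean_spectra",
    "segment_block",
    "CLUSTER_NAMES",
]

CLUSTER_NAMES = {0: "blue", 1: "green", 2: "red", -1: "background"}
DYE_ABSORPTION_BAND_NM = 630.0


@dataclass
class PCAResult:
    """Scores/loadings of mean-centred data with orthonormal loading columns."""

    scores: np.ndarray                 # n_complete_rows x k
    loadings: np.ndarray               # n_variables x k
    explained_variance_ratio: np.ndarray
    mean: np.ndarray                   # per-variable mean used for centring
    row_index: np.ndarray              # block-row indices of complete-case rows

    def reconstruct(self) -> np.ndarray:
        """mean + scores @ loadings.T — exact when k equals the data rank."""
        return self.mean + self.scores @ self.loadings.T


@dataclass
class SegmentationResult:
    score_map: np.ndarray              # 2-D PC1 scores, NaN at masked pixels
    thresholds: tuple[float, float]
    label_map: np.ndarray              # int: 0 blue, 1 green, 2 red, -1 background
    rgb: np.ndarray                    # H x W x 3 float in [0, 1]
    cluster_spectra: dict = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        return {name: int((self.label_map == code).sum())
                for code, name in CLUSTER_NAMES.items()}


def fit_pca(block: FusedBlock | PixelBlock, n_components: int = 2) -> PCAResult:
    """PCA of the fused block on complete-case rows (no imputation).

    Sign convention: each loading column's largest-magnitude element is made
    positive (use :func:`orient_pc1` afterwards to tie PC1 to degradation).
    """
    X = block.matrix
    complete = ~np.isnan(X).any(axis=1)
    n_complete = int(complete.sum())
    if n_complete < n_components:
        raise ValueError(f"only {n_complete} complete rows for {n_components} components")
    Xc = X[complete]
    if Xc.shape[1] < n_components:
        raise ValueError("fewer variables than components")
    pca = PCA(n_components=n_components, svd_solver="full").fit(Xc)
    loadings = pca.components_.T.copy()
    scores = pca.transform(Xc)
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAResult(scores, loadings, pca.explained_variance_ratio_.copy(),
                     pca.mean_.copy(), np.flatnonzero(complete))


def orient_pc1(result: PCAResult, variable_labels: list[tuple[str, float]],
               band_nm: float = DYE_ABSORPTION_BAND_NM) -> PCAResult:
    """Flip PC1 so high scores correspond to degraded (faded) pixels.

    Degradation depletes the dye absorption band, so on the pseudoabsorbance
    variable nearest ``band_nm`` faded pixels sit below the mean; forcing
    that loading negative makes their PC1 scores high.  In place and
    returned for chaining.
    """
    r_cols = [(i, wl) for i, (b, wl) in enumerate(variable_labels) if b == "R"]
    if r_cols:
        anchor = min(r_cols, key=lambda t: abs(t[1] - band_nm))[0]
        flip = result.loadings[anchor, 0] > 0
    else:  # fallback: generic largest-|loading| positive convention
        anchor = int(np.argmax(np.abs(result.loadings[:, 0])))
        flip = result.loadings[anchor, 0] < 0
    if flip:
        result.loadings[:, 0] *= -1
        result.scores[:, 0] *= -1
    return result


def score_histogram(scores: np.ndarray, bins: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of PC1 scores over equal-width bins spanning the range."""
    scores = np.asarray(scores, dtype=float)
    scores = scores[np.isfinite(scores)]
    if np.unique(scores).size < 2:
        raise ValueError("degenerate score range: need >= 2 distinct values")
    return np.histogram(scores, bins=bins)


def select_thresholds(
    scores: np.ndarray,
    mode: str = "auto",
    manual: tuple[float, float] | None = None,
    grid_size: int = 512,
) -> tuple[float, float]:
    """Pick the two cut points that split PC1 scores into three clusters.

    auto: the two deepest interior local minima of the Gaussian-KDE-smoothed
    score density (Silverman bandwidth), in increasing order.  manual:
    passthrough of analyst-chosen values.
    """
    if mode == "manual":
        if manual is None:
            raise ValueError("manual mode requires explicit thresholds")
        t_low, t_high = manual
        if not t_low < t_high:
            raise ValueError("manual thresholds require t_low < t_high")
        return float(t_low), float(t_high)
    if mode != "auto":
        raise ValueError(f"unknown mode {mode!r}")
    scores = np.asarray(scores, dtype=float)
    scores = scores[np.isfinite(scores)]
    if np.unique(scores).size < 2:
        raise ValueError("degenerate score distribution")
    kde = gaussian_kde(scores, bw_method="silverman")
    grid = np.linspace(scores.min(), scores.max(), grid_size)
    dens = kde(grid)
    interior = np.flatnonzero((dens[1:-1] < dens[:-2]) & (dens[1:-1] <= dens[2:])) + 1
    if interior.size < 2:
        raise ValueError(
            "score density has fewer than 2 interior minima (unimodal or bimodal "
            "distribution); use manual thresholds"
        )
    deepest = interior[np.argsort(dens[interior])[:2]]
    t_low, t_high = np.sort(grid[deepest])
    logger.info("select_thresholds: auto minima at %.4f, %.4f", t_low, t_high)
    return float(t_low), float(t_high)


def segment(score_map: np.ndarray, thresholds: tuple[float, float]) -> SegmentationResult:
    """Label pixels blue/green/red by PC1 score; NaN scores become background.

    red: score > t_high; green: t_low <= score <= t_high; blue: score < t_low.
    """
    t_low, t_high = thresholds
    if not t_low < t_high:
        raise ValueError("thresholds require t_low < t_high")
    score_map = np.asarray(score_map, dtype=float)
    label_map = np.full(score_map.shape, -1, dtype=int)
    valid = np.isfinite(score_map)
    label_map[valid & (score_map < t_low)] = 0
    label_map[valid & (score_map >= t_low) & (score_map <= t_high)] = 1
    label_map[valid & (score_map > t_high)] = 2
    rgb = np.zeros(score_map.shape + (3,))
    rgb[label_map == 2, 0] = 1.0
    rgb[label_map == 1, 1] = 1.0
    rgb[label_map == 0, 2] = 1.0
    return SegmentationResult(score_map, (float(t_low), float(t_high)), label_map, rgb)


def cluster_mean_spectra(
    label_map: np.ndarray, F_true: HyperCube, A: HyperCube
) -> dict[str, dict[str, np.ndarray]]:
    """Per-cluster unweighted mean spectra over member unmasked pixels.

    Returns {cluster: {"fluorescence": ..., "pseudoabsorbance": ...,
    "n_pixels": ...}} using the self-absorption-corrected fluorescence and
    the pseudoabsorbance cubes; empty clusters are absent (logged).
    """
    if label_map.shape != F_true.data.shape[:2] or label_map.shape != A.data.shape[:2]:
        raise ValueError("label map must align with cube geometry")
    out: dict[str, dict[str, np.ndarray]] = {}
    for code in (0, 1, 2):
        name = CLUSTER_NAMES[code]
        member = (label_map == code) & F_true.mask & A.mask
        if not member.any():
            logger.warning("cluster_mean_spectra: cluster %s is empty", name)
            continue
        out[name] = {
            "fluorescence": F_true.data[member].mean(axis=0),
            "pseudoabsorbance": A.data[member].mean(axis=0),
            "n_pixels": int(member.sum()),
        }
    return out


class PC1Segmenter(ClusterMixin, BaseEstimator):
    """PCA + PC1-threshold segmentation as a scikit-learn estimator.

    Parameters
    ----------
    n_components : components to keep in the PCA summary (>= 1).
    mode : "auto" (KDE minima) or "manual" threshold selection.
    manual_thresholds : (t_low, t_high), required in manual mode.
    anchor_band_nm : wavelength of the dye absorption band used to orient
        PC1 (needs ``variable_labels`` passed to :meth:`fit`).

    Attributes (after fit)
    ----------------------
    pca_ : :class:`PCAResult` with PC1 oriented to degradation.
    thresholds_ : (t_low, t_high) in score units.
    labels_ : cluster code per fitted row (0 blue, 1 green, 2 red).
    """

    def __init__(self, n_components: int = 2, mode: str = "auto",
                 manual_thresholds: tuple[float, float] | None = None,
                 anchor_band_nm: float = DYE_ABSORPTION_BAND_NM):
        self.n_components = n_components
        self.mode = mode
        self.manual_thresholds = manual_thresholds
        self.anchor_band_nm = anchor_band_nm

    def fit(self, X, y=None, variable_labels: list[tuple[str, float]] | None = None):
        if isinstance(X, FusedBlock):
            variable_labels = X.variable_labels
            X = X.matrix
        X = check_array(X, ensure_all_finite="allow-nan")
        result = fit_pca(_as_block(X), self.n_components)
        result = orient_pc1(result, variable_labels or [], self.anchor_band_nm)
        pc1 = result.scores[:, 0]
        self.pca_ = result
        self.thresholds_ = select_thresholds(pc1, self.mode, self.manual_thresholds)
        self.labels_ = self._classify(pc1)
        self.n_features_in_ = X.shape[1]
        return self

    def _classify(self, scores: np.ndarray) -> np.ndarray:
        t_low, t_high = self.thresholds_
        labels = np.where(scores > t_high, 2, np.where(scores < t_low, 0, 1))
        return labels.astype(int)

    def transform(self, X) -> np.ndarray:
        """Project rows onto the fitted components (PC1 in column 0)."""
        check_is_fitted(self)
        if isinstance(X, FusedBlock):
            X = X.matrix
        X = check_array(X)
        return (X - self.pca_.mean) @ self.pca_.loadings

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self)
        return self._classify(self.transform(X)[:, 0])


class _as_block:
    """Duck-typed matrix holder so fit_pca accepts bare arrays."""

    def __init__(self, matrix: np.ndarray):
        self.matrix = matrix


def segment_block(fused: FusedBlock, canvas_shape: tuple[int, int],
                  segmenter: PC1Segmenter) -> SegmentationResult:
    """Fit the segmenter on a fused block and render maps in cube geometry."""
    segmenter.fit(fused)
    pc1 = segmenter.pca_.scores[:, 0]
    rows = fused.spatial_index[segmenter.pca_.row_index]
    score_map = np.full(canvas_shape, np.nan)
    score_map[rows[:, 1], rows[:, 2]] = pc1
    return segment(score_map, segmenter.thresholds_)
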