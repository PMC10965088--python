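"""Hybrid 90-feature descriptor assembly and PCA reduction.

The default configuration concatenates twelve extractor families into a
fixed-order 90-dimensional vector per image:

====================  ==  =============================================
GLCM                  20  5 statistics x 4 offsets
LBP                   10  uniform rotation-invariant histogram, P=8
RLBP                  10  radial-mean LBP histogram
LTP                   10  upper/lower ternary histograms, 5 bins each
SGM                   16  statistical-geometrical region metrics
BIBS                   8  centroid-to-boundary ray signature
Gabor                  8  mean magnitude, 2 frequencies x 4 orientations
Log-Energy             4  wavelet/Fourier log-energy differences
PCA-filter             1  mean |first-PC score| of image tiles
ICA-filter             1  mean |ICA activation| of image tiles
Fractal                1  box-counting dimension
Shape-signature        1  boundary bounding-box aspect ratio
====================  ==  =============================================

Feature names are stable across platforms; matrices round-trip through
CSV with a header of registry names plus a ``label`` column.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA

from . import shape, texture
from .io import LabeledDataset, validate_gray_image

log = logging.getLogger(__name__)


@dataclass
class ExtractorConfig:
    """Which extractor families are enabled and their parameters."""

    glcm: texture.GLCMSpec | None = field(default_factory=texture.GLCMSpec)
    lbp: texture.LBPSpec | None = field(default_factory=texture.LBPSpec)
    rlbp: texture.LBPSpec | None = field(default_factory=texture.LBPSpec)
    rlbp_n_radii: int = 3
    ltp: texture.LBPSpec | None = field(default_factory=texture.LBPSpec)
    ltp_t: float = 0.1
    sgm: bool = True
    bibs_rays: int | None = 8
    gabor: texture.GaborBankSpec | None = field(default_factory=texture.GaborBankSpec)
    log_energy: texture.LogEnergySpec | None = field(default_factory=texture.LogEnergySpec)
    pca_filter_patch: int | None = 8
    ica_filter_patch: int | None = 8
    fractal: bool = True
    shape_signature: bool = True
    seed: int = 0


def feature_names(config: ExtractorConfig | None = None) -> list:
    """Registry of feature names in extraction order."""
    c = config or ExtractorConfig()
    names = []
    if c.glcm is not None:
        stats = ("contrast", "correlation", "energy", "homogeneity", "entropy")
        for k, off in enumerate(c.glcm.offsets):
            names += [f"glcm_o{k}_{s}" for s in stats]
    if c.lbp is not None:
        names += [f"lbp_bin{i}" for i in range(c.lbp.n_bins)]
    if c.rlbp is not None:
        names += [f"rlbp_bin{i}" for i in range(c.rlbp.n_bins)]
    if c.ltp is not None:
        half = c.ltp.n_bins // 2
        names += [f"ltp_upper{i}" for i in range(half)]
        names += [f"ltp_lower{i}" for i in range(half)]
    if c.sgm:
        names += [f"sgm_{n}" for n in shape.REGION_METRIC_NAMES]
    if c.bibs_rays:
        names += [f"bibs_ray{i}" for i in range(c.bibs_rays)]
    if c.gabor is not None:
        for f in c.gabor.frequencies:
            for t in c.gabor.orientations:
                names.append(f"gabor_f{f:g}_t{t:.3f}")
    if c.log_energy is not None:
        names += ["logenergy_ra", "logenergy_rh", "logenergy_rv", "logenergy_rd"]
    if c.pca_filter_patch:
        names.append("pca_filter")
    if c.ica_filter_patch:
        names.append("ica_filter")
    if c.fractal:
        names.append("fractal_dimension")
    if c.shape_signature:
        names.append("shape_aspect")
    return names


def _shape_block(img, fn, length):
    """Run a shape extractor; degenerate segmentations (no object) yield
    zeros under the finite-substitution rule instead of aborting a batch."""
    try:
        mask = shape.binarize_object(img)
        return np.atleast_1d(fn(mask)).astype(float)
    except ValueError as e:
        log.warning("shape extractor substituted zeros: %s", e)
        return np.zeros(length)


def extract_feature_vector(img: np.ndarray, config: ExtractorConfig | None = None) -> np.ndarray:
    """Compute the hybrid feature vector of one image (default length 90).

    Non-finite values are replaced by 0 (and logged) so degenerate images
    never poison a feature matrix.
    """
    c = config or ExtractorConfig()
    img = validate_gray_image(img)
    parts = []
    if c.glcm is not None:
        parts.append(texture.glcm_features(img, c.glcm))
    if c.lbp is not None:
        parts.append(texture.lbp_histogram(img, c.lbp))
    if c.rlbp is not None:
        parts.append(texture.rlbp_histogram(img, c.rlbp, c.rlbp_n_radii))
    if c.ltp is not None:
        parts.append(texture.ltp_features(img, c.ltp, c.ltp_t))
    if c.sgm:
        parts.append(_shape_block(img, shape.region_metrics, len(shape.REGION_METRIC_NAMES)))
    if c.bibs_rays:
        parts.append(_shape_block(img, lambda m: shape.bibs_signature(m, c.bibs_rays), c.bibs_rays))
    if c.gabor is not None:
        parts.append(texture.gabor_features(img, c.gabor))
    if c.log_energy is not None:
        parts.append(texture.log_energy(img, c.log_energy))
    if c.pca_filter_patch:
        parts.append([texture.pca_filter_feature(img, c.pca_filter_patch, c.seed)])
    if c.ica_filter_patch:
        parts.append([texture.ica_filter_feature(img, c.ica_filter_patch, c.seed)])
    if c.fractal:
        parts.append(_shape_block(img, shape.fractal_dimension, 1))
    if c.shape_signature:
        parts.append(_shape_block(img, shape.shape_signature_aspect, 1))
    vec = np.concatenate([np.asarray(p, dtype=float).ravel() for p in parts])
    bad = ~np.isfinite(vec)
    if bad.any():
        log.warning("replaced %d non-finite feature values with 0", int(bad.sum()))
        vec[bad] = 0.0
    return vec


def extract_feature_matrix(ds: LabeledDataset, config: ExtractorConfig | None = None):
    """Feature matrix (n x d) and labels for a dataset, row order preserved."""
    if len(ds) == 0:
        raise ValueError("dataset is empty")
    rows = []
    for i, img in enumerate(ds.images):
        try:
            rows.append(extract_feature_vector(img, config))
        except ValueError as e:
            raise ValueError(f"feature extraction failed on image {i}: {e}") from e
        if (i + 1) % 100 == 0:
            log.info("extracted features for %d/%d images", i + 1, len(ds))
    X = np.vstack(rows)
    zero_var = np.flatnonzero(X.std(axis=0) == 0)
    if zero_var.size:
        log.info("zero-variance feature columns: %s", zero_var.tolist())
    return X, ds.labels.copy()


class HybridFeatureExtractor(BaseEstimator, TransformerMixin):
    """Transformer mapping a list of grayscale images to the feature matrix.

    Stateless apart from its configuration; `fit` only records the
    registry so the extractor composes with sklearn pipelines.
    """

    def __init__(self, config: ExtractorConfig | None = None):
        self.config = config

    def fit(self, X, y=None):
        self.feature_names_ = feature_names(self.config)
        self.n_features_out_ = len(self.feature_names_)
        return self

    def transform(self, X):
        if not hasattr(self, "feature_names_"):
            self.fit(X)
        return np.vstack([extract_feature_vector(img, self.config) for img in X])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(feature_names(self.config), dtype=object)


# ---------------------------------------------------------------------------
# PCA reduction
# ---------------------------------------------------------------------------

class PCAReducer(BaseEstimator, TransformerMixin):
    """Standardize (z-score) then project onto principal axes.

    Fitted attributes
    -----------------
    means_, scales_ : per-feature standardization (zero-variance columns
        get scale 1)
    eigenvalues_ : covariance eigenvalues, nonincreasing, clamped at 0
    loadings_ : (d, d) orthonormal loading matrix, columns sorted by
        eigenvalue; each column's largest-magnitude entry is positive
    ncse_ : normalized cumulative sum of eigenvalues (final value 1)

    Parameters
    ----------
    n_components : fixed component count, or None to choose the smallest
        k whose NCSE reaches ``threshold``.
    threshold : cumulative-variance target used when n_components is None.
    """

    def __init__(self, n_components: int | None = None, threshold: float = 0.999):
        self.n_components = n_components
        self.threshold = threshold

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("PCA requires a 2-D matrix with at least 2 rows")
        self.means_ = X.mean(axis=0)
        std = X.std(axis=0, ddof=1)
        self.scales_ = np.where(std > 0, std, 1.0)
        Z = (X - self.means_) / self.scales_
        pca = PCA(n_components=min(X.shape), svd_solver="full")
        pca.fit(Z)
        lam = np.clip(pca.explained_variance_, 0.0, None)
        V = pca.components_.T  # columns are principal axes
        # complete to a full orthonormal basis when n < d (trailing axes
        # have zero variance and exist only so k=d round-trips exactly)
        d = X.shape[1]
        if V.shape[1] < d:
            q, _ = np.linalg.qr(np.eye(d) - V @ V.T)
            extra = q[:, :d - V.shape[1]]
            V = np.hstack([V, extra])
            lam = np.concatenate([lam, np.zeros(d - lam.size)])
        # deterministic sign: largest-|.| entry of each column positive
        idx = np.argmax(np.abs(V), axis=0)
        signs = np.sign(V[idx, np.arange(V.shape[1])])
        signs[signs == 0] = 1.0
        self.loadings_ = V * signs
        self.eigenvalues_ = lam
        total = lam.sum()
        self.ncse_ = np.cumsum(lam) / total if total > 0 else np.ones_like(lam)
        self.ncse_[-1] = 1.0
        self.n_components_ = (self.n_components if self.n_components is not None
                              else self.select_k(self.threshold))
        return self

    def select_k(self, threshold: float) -> int:
        """Smallest k with NCSE[k] >= threshold."""
        if not (0 < threshold <= 1):
            raise ValueError("threshold must be in (0, 1]")
        return int(np.searchsorted(self.ncse_, threshold - 1e-12) + 1)

    def transform(self, X, k: int | None = None):
        k = self.n_components_ if k is None else int(k)
        if not (1 <= k <= self.loadings_.shape[1]):
            raise ValueError(f"k={k} out of range 1..{self.loadings_.shape[1]}")
        Z = (np.asarray(X, dtype=float) - self.means_) / self.scales_
        return Z @ self.loadings_[:, :k]

    def inverse_transform(self, Zk):
        k = np.asarray(Zk).shape[1]
        Z = np.asarray(Zk) @ self.loadings_[:, :k].T
        return Z * self.scales_ + self.means_

    def to_json(self) -> str:
        return json.dumps({
            "means": self.means_.tolist(), "scales": self.scales_.tolist(),
            "eigenvalues": self.eigenvalues_.tolist(),
            "loadings": self.loadings_.tolist(), "ncse": self.ncse_.tolist(),
            "n_components": int(self.n_components_),
        })

    @classmethod
    def from_json(cls, text: str) -> "PCAReducer":
        d = json.loads(text)
        model = cls(n_components=d["n_components"])
        model.means_ = np.array(d["means"])
        model.scales_ = np.array(d["scales"])
        model.eigenvalues_ = np.array(d["eigenvalues"])
        model.loadings_ = np.array(d["loadings"])
        model.ncse_ = np.array(d["ncse"])
        model.n_components_ = d["n_components"]
        return model


def pca_fit(X: np.ndarray) -> PCAReducer:
    """Fit the standardize-plus-PCA model on a feature matrix."""
    return PCAReducer().fit(X)


def pca_transform(model: PCAReducer, X: np.ndarray, k: int) -> np.ndarray:
    return model.transform(X, k=k)


def select_k(model: PCAReducer, threshold: float) -> int:
    return model.select_k(threshold)


def save_feature_csv(path, X, y, config: ExtractorConfig | None = None) -> None:
    df = pd.DataFrame(X, columns=feature_names(config))
    df["label"] = np.asarray(y, dtype=int)
    df.to_csv(path, index=False)


def load_feature_csv(path):
    df = pd.read_csv(path)
    y = df.pop("label").to_numpy(dtype=int)
    return df.to_numpy(dtype=float), y, list(df.columns)
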