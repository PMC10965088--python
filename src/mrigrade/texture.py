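"""Intensity-texture feature extractors.

Implements the texture half of the hybrid descriptor: gray-level
co-occurrence matrices (GLCM) with Haralick-style statistics, local
binary/ternary patterns and their radial-mean variant (LBP/LTP/RLBP),
a bank of discrete 2-D Gabor filters, a wavelet log-energy feature,
and single-scalar PCA/ICA patch-filter features.

Conventions shared by the local-pattern operators
-------------------------------------------------
* neighbours are sampled at P angles counter-clockwise from angle 0
  (east), at off-grid positions by bilinear interpolation;
* thresholding uses >= (a neighbour equal to the centre sets the bit);
* only interior pixels (full neighbourhood inside the image) are coded;
* histograms are normalized to sum to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy.ndimage import convolve
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .io import validate_gray_image


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class GLCMSpec:
    """Quantization and displacement parameters for co-occurrence matrices.

    Defaults give the standard 4-direction, distance-1, 8-level symmetric
    normalized GLCM (offsets 0, 45, 90, 135 degrees).
    """

    levels: int = 8
    offsets: tuple = ((0, 1), (-1, 1), (-1, 0), (-1, -1))
    symmetric: bool = True
    normalized: bool = True

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if not self.offsets:
            raise ValueError("at least one offset required")
        if any(dr == 0 and dc == 0 for dr, dc in self.offsets):
            raise ValueError("offsets must be nonzero")


@dataclass
class LBPSpec:
    """Circular-neighbourhood parameters for LBP-family operators."""

    radius: int = 1
    points: int = 8
    mapping: str = "uniform-rotation-invariant"  # or "raw"

    def __post_init__(self):
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.points not in (8, 16):
            raise ValueError("points must be 8 or 16")
        if self.mapping not in ("raw", "uniform-rotation-invariant"):
            raise ValueError(f"unknown mapping {self.mapping!r}")

    @property
    def n_bins(self) -> int:
        return self.points + 2 if self.mapping == "uniform-rotation-invariant" else 2 ** self.points


@dataclass
class GaborBankSpec:
    """Frequencies (cycles/pixel), orientations (radians) and envelope of
    the Gabor bank.  Kernels are normalized to unit L2 norm, which fixes
    the free amplitude factors of the even and odd kernels."""

    frequencies: tuple = (0.1, 0.25)
    orientations: tuple = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
    sigma: float = 2.0
    kernel_halfwidth: int = 7

    def __post_init__(self):
        if any(f <= 0 for f in self.frequencies) or self.sigma <= 0:
            raise ValueError("frequencies and sigma must be positive")
        if self.kernel_halfwidth < 1:
            raise ValueError("kernel_halfwidth must be >= 1")


@dataclass
class LogEnergySpec:
    """Wavelet log-energy parameters.  epsilon stabilises log(|spectrum|):
    detail subbands of flat regions are exactly zero under Haar."""

    level: int = 2
    wavelet: str = "haar"
    epsilon: float = 1e-12

    def __post_init__(self):
        if self.level < 1:
            raise ValueError("level must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def quantize(img: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width binning of [0,1] into integer levels 0..levels-1.

    Bins are half-open; the value 1.0 falls in the top bin.
    """
    q = np.floor(np.asarray(img, dtype=float) * levels).astype(int)
    return np.clip(q, 0, levels - 1)


def compute_glcm(img: np.ndarray, spec: GLCMSpec = GLCMSpec()) -> np.ndarray:
    """Co-occurrence matrices, one ``levels x levels`` grid per offset.

    Entry (i, j) of offset (dr, dc) counts pixel pairs with quantized
    value i at (r, c) and j at (r + dr, c + dc).  Symmetric adds the
    transpose; normalized divides each matrix by its total.
    """
    img = validate_gray_image(img, min_size=2)
    q = quantize(img, spec.levels)
    h, w = q.shape
    out = np.zeros((len(spec.offsets), spec.levels, spec.levels), dtype=float)
    for k, (dr, dc) in enumerate(spec.offsets):
        if abs(dr) >= h or abs(dc) >= w:
            raise ValueError(f"offset {(dr, dc)} exceeds image size {q.shape}")
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        a = q[r0:r1, c0:c1].ravel()
        b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
        m = np.bincount(a * spec.levels + b, minlength=spec.levels ** 2)
        m = m.reshape(spec.levels, spec.levels).astype(float)
        if spec.symmetric:
            m = m + m.T
        if spec.normalized:
            m /= m.sum()
        out[k] = m
    return out


def glcm_stats(glcm: np.ndarray) -> np.ndarray:
    """Contrast, correlation, energy, homogeneity and entropy of one
    normalized co-occurrence matrix.

    entropy is in bits with 0*log(0) := 0; correlation is defined as 0
    when either marginal standard deviation vanishes.
    """
    p = np.asarray(glcm, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("glcm must be a square matrix")
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("glcm must be nonnegative and normalized to sum 1")
    n = p.shape[0]
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    contrast = float(np.sum((i - j) ** 2 * p))
    energy = float(np.sum(p ** 2))
    homogeneity = float(np.sum(p / (1.0 + np.abs(i - j))))
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    sd_i = np.sqrt(np.sum((i - mu_i) ** 2 * p))
    sd_j = np.sqrt(np.sum((j - mu_j) ** 2 * p))
    if sd_i > 0 and sd_j > 0:
        correlation = float(np.sum((i - mu_i) * (j - mu_j) * p) / (sd_i * sd_j))
    else:
        correlation = 0.0
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    return np.array([contrast, correlation, energy, homogeneity, entropy])


def glcm_features(img: np.ndarray, spec: GLCMSpec = GLCMSpec()) -> np.ndarray:
    """5 statistics per offset, concatenated in offset order (default 20)."""
    mats = compute_glcm(img, spec)
    return np.concatenate([glcm_stats(m) for m in mats])


# ---------------------------------------------------------------------------
# LBP family
# ---------------------------------------------------------------------------

def _bilinear_sample(img: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Bilinear interpolation at (possibly fractional) coordinates."""
    r0 = np.floor(rows).astype(int)
    c0 = np.floor(cols).astype(int)
    fr, fc = rows - r0, cols - c0
    r1 = np.minimum(r0 + 1, img.shape[0] - 1)
    c1 = np.minimum(c0 + 1, img.shape[1] - 1)
    return ((1 - fr) * (1 - fc) * img[r0, c0] + (1 - fr) * fc * img[r0, c1]
            + fr * (1 - fc) * img[r1, c0] + fr * fc * img[r1, c1])


def _neighbor_grid(img: np.ndarray, radius: float, points: int):
    """Sampled neighbour stack (P, H', W') and matching centre grid for all
    interior pixels (those whose full circle lies inside the image)."""
    h, w = img.shape
    m = int(np.ceil(radius))
    if h <= 2 * m or w <= 2 * m:
        raise ValueError(f"image {img.shape} too small for radius {radius}")
    rr, cc = np.meshgrid(np.arange(m, h - m), np.arange(m, w - m), indexing="ij")
    angles = 2 * np.pi * np.arange(points) / points
    samples = np.empty((points, *rr.shape))
    for p, a in enumerate(angles):
        # counter-clockwise from east in image coordinates: row decreases upward
        dr, dc = -radius * np.sin(a), radius * np.cos(a)
        samples[p] = _bilinear_sample(img, rr + dr, cc + dc)
    return samples, img[rr, cc]


_URI_CACHE: dict = {}


def _uniform_ri_table(points: int) -> np.ndarray:
    """Map raw P-bit codes to rotation-invariant uniform bins.

    Codes with at most two 0/1 circular transitions map to their bit count
    (0..P); all other codes share the miscellaneous bin P+1.
    """
    if points in _URI_CACHE:
        return _URI_CACHE[points]
    codes = np.arange(2 ** points)
    bits = (codes[:, None] >> np.arange(points)) & 1
    transitions = np.sum(bits != np.roll(bits, -1, axis=1), axis=1)
    table = np.where(transitions <= 2, bits.sum(axis=1), points + 1)
    _URI_CACHE[points] = table
    return table


def _codes_to_histogram(codes: np.ndarray, spec: LBPSpec) -> np.ndarray:
    if spec.mapping == "uniform-rotation-invariant":
        codes = _uniform_ri_table(spec.points)[codes]
    hist = np.bincount(codes.ravel(), minlength=spec.n_bins).astype(float)
    return hist / hist.sum()


# comparison slack absorbing bilinear round-off, so flat regions
# deterministically code as "neighbour >= centre"
_EQ_TOL = 1e-12


def lbp_codes(img: np.ndarray, spec: LBPSpec = LBPSpec()) -> np.ndarray:
    """Raw LBP code per interior pixel (bit p set iff neighbour >= centre)."""
    img = validate_gray_image(img, min_size=2)
    samples, center = _neighbor_grid(img, spec.radius, spec.points)
    bits = samples >= center - _EQ_TOL
    weights = (1 << np.arange(spec.points)).reshape(-1, 1, 1)
    return np.sum(bits * weights, axis=0).astype(int)


def lbp_histogram(img: np.ndarray, spec: LBPSpec = LBPSpec()) -> np.ndarray:
    """Normalized histogram of LBP codes under the spec's mapping."""
    return _codes_to_histogram(lbp_codes(img, spec), spec)


def rlbp_codes(img: np.ndarray, spec: LBPSpec = LBPSpec(), n_radii: int = 3) -> np.ndarray:
    """Radial LBP: each angular sample is the mean of interpolated values
    at radii 1..n_radii along that angle, then thresholded as in LBP."""
    img = validate_gray_image(img, min_size=2)
    if n_radii < 1:
        raise ValueError("n_radii must be >= 1")
    stacks = []
    for r in range(1, n_radii + 1):
        samples, center = _neighbor_grid(img, float(r), spec.points)
        stacks.append(samples)
    # interior shrinks with radius; crop all stacks to the smallest grid
    hmin = min(s.shape[1] for s in stacks)
    wmin = min(s.shape[2] for s in stacks)

    def crop(a, h, w):
        dh, dw = (a.shape[-2] - h) // 2, (a.shape[-1] - w) // 2
        return a[..., dh:dh + h, dw:dw + w]

    mean_samples = np.mean([crop(s, hmin, wmin) for s in stacks], axis=0)
    m = int(np.ceil(n_radii))
    center = img[m:img.shape[0] - m, m:img.shape[1] - m]
    bits = mean_samples >= center - _EQ_TOL
    weights = (1 << np.arange(spec.points)).reshape(-1, 1, 1)
    return np.sum(bits * weights, axis=0).astype(int)


def rlbp_histogram(img: np.ndarray, spec: LBPSpec = LBPSpec(), n_radii: int = 3) -> np.ndarray:
    return _codes_to_histogram(rlbp_codes(img, spec, n_radii), spec)


def ltp_codes(img: np.ndarray, spec: LBPSpec = LBPSpec(), t: float = 0.1):
    """Upper and lower LTP binary code maps.

    Neighbours are coded +1 if >= centre + t, -1 if <= centre - t, else 0;
    the upper map binarizes (+1), the lower map binarizes (-1).
    """
    img = validate_gray_image(img, min_size=2)
    if not (0 < t < 1):
        raise ValueError("t must be in (0, 1)")
    samples, center = _neighbor_grid(img, spec.radius, spec.points)
    upper_bits = samples >= center + t
    lower_bits = samples <= center - t
    weights = (1 << np.arange(spec.points)).reshape(-1, 1, 1)
    upper = np.sum(upper_bits * weights, axis=0).astype(int)
    lower = np.sum(lower_bits * weights, axis=0).astype(int)
    return upper, lower


def ltp_histograms(img: np.ndarray, spec: LBPSpec = LBPSpec(), t: float = 0.1):
    """(upper, lower) normalized histograms of the two LTP binary maps."""
    upper, lower = ltp_codes(img, spec, t)
    return _codes_to_histogram(upper, spec), _codes_to_histogram(lower, spec)


def ltp_features(img: np.ndarray, spec: LBPSpec = LBPSpec(), t: float = 0.1) -> np.ndarray:
    """Compact 10-value LTP descriptor: each 10-bin uniform-RI histogram is
    compressed to 5 bins by merging adjacent bins pairwise."""
    hu, hl = ltp_histograms(img, spec, t)
    return np.concatenate([hu.reshape(-1, 2).sum(axis=1), hl.reshape(-1, 2).sum(axis=1)])


# ---------------------------------------------------------------------------
# Gabor bank
# ---------------------------------------------------------------------------

def gabor_kernel(spec: GaborBankSpec, f: float, theta: float):
    """Even (cosine) and odd (sine) discrete Gabor kernels.

    Gc(i,j) = B exp(-(i^2+j^2)/(2 sigma)) cos(2 pi f (i cos theta + j sin theta)),
    Gs analogously with sin; B and C are fixed by unit L2 norm.  Note the
    envelope divides by 2*sigma (sigma in squared-pixel units).
    """
    h = spec.kernel_halfwidth
    i, j = np.meshgrid(np.arange(-h, h + 1), np.arange(-h, h + 1), indexing="ij")
    envelope = np.exp(-(i ** 2 + j ** 2) / (2.0 * spec.sigma))
    phase = 2 * np.pi * f * (i * np.cos(theta) + j * np.sin(theta))
    gc = envelope * np.cos(phase)
    gs = envelope * np.sin(phase)
    gc /= np.linalg.norm(gc)
    ns = np.linalg.norm(gs)
    if ns > 0:
        gs /= ns
    return gc, gs


def gabor_features(img: np.ndarray, spec: GaborBankSpec = GaborBankSpec()) -> np.ndarray:
    """Mean magnitude response per (frequency, orientation) pair.

    Each image is convolved ('same' size, reflect padding) with the even
    and odd kernels; the feature is the mean of sqrt(rc^2 + rs^2).
    """
    img = validate_gray_image(img, min_size=2)
    k = 2 * spec.kernel_halfwidth + 1
    if img.shape[0] < k or img.shape[1] < k:
        raise ValueError(f"image {img.shape} smaller than kernel {k}x{k}")
    feats = []
    for f in spec.frequencies:
        for theta in spec.orientations:
            gc, gs = gabor_kernel(spec, f, theta)
            rc = convolve(img, gc, mode="reflect")
            rs = convolve(img, gs, mode="reflect")
            feats.append(float(np.mean(np.hypot(rc, rs))))
    return np.array(feats)


# ---------------------------------------------------------------------------
# Wavelet log-energy
# ---------------------------------------------------------------------------

def log_energy(img: np.ndarray, spec: LogEnergySpec = LogEnergySpec()) -> np.ndarray:
    """Four log-energy scalars [RA, RH, RV, RD].

    At each decomposition level the approximation subband is split into
    (approx, horizontal, vertical, diagonal); each subband is summarised by
    the mean natural log magnitude of its centred 2-D Fourier spectrum
    (plus epsilon).  R* sums the successive differences of each summary
    across levels, so level=1 yields all zeros.
    """
    img = validate_gray_image(img, min_size=2)
    if min(img.shape) < 2 ** spec.level:
        raise ValueError(f"level {spec.level} too deep for image {img.shape}")
    A, H, V, D = [], [], [], []
    approx = np.asarray(img, dtype=float)
    for _ in range(spec.level):
        approx, (horiz, vert, diag) = pywt.dwt2(approx, spec.wavelet)
        for acc, band in zip((A, H, V, D), (approx, horiz, vert, diag)):
            spectrum = np.fft.fftshift(np.fft.fft2(band))
            acc.append(float(np.mean(np.log(np.abs(spectrum) + spec.epsilon))))
    return np.array([np.sum(np.diff(x)) for x in (A, H, V, D)])


# ---------------------------------------------------------------------------
# PCA / ICA patch filters
# ---------------------------------------------------------------------------

def _tiles(img: np.ndarray, patch: int) -> np.ndarray:
    """Non-overlapping patch x patch tiles as row vectors (cropped to fit)."""
    img = validate_gray_image(img, min_size=2)
    h = (img.shape[0] // patch) * patch
    w = (img.shape[1] // patch) * patch
    if h == 0 or w == 0 or (h // patch) * (w // patch) < 2:
        raise ValueError(f"image {img.shape} yields fewer than 2 {patch}x{patch} tiles")
    a = img[:h, :w].reshape(h // patch, patch, w // patch, patch)
    return a.transpose(0, 2, 1, 3).reshape(-1, patch * patch)


def pca_filter_feature(img: np.ndarray, patch: int = 8, seed: int = 0) -> float:
    """Mean absolute score of the tiles on their first principal axis."""
    X = _tiles(img, patch)
    if X.max() == X.min():
        return 0.0
    Xc = X - X.mean(axis=0)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    return float(np.mean(np.abs(Xc @ vt[0])))


def ica_filter_feature(img: np.ndarray, patch: int = 8, seed: int = 0) -> float:
    """Mean absolute activation of one FastICA component over the tiles.

    Fixed-point estimation (deflation, logcosh/tanh nonlinearity, max 200
    iterations, tolerance 1e-4, seeded); falls back to the PCA-filter value
    if the iteration does not converge.
    """
    X = _tiles(img, patch)
    if X.max() == X.min():
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            ica = FastICA(n_components=1, algorithm="deflation", fun="logcosh",
                          max_iter=200, tol=1e-4, whiten="unit-variance",
                          random_state=seed)
            s = ica.fit_transform(X)
        except (ConvergenceWarning, ValueError):
            return pca_filter_feature(img, patch, seed)
    return float(np.mean(np.abs(s[:, 0])))
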