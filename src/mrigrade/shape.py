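"""Binary-object shape features.

A grayscale image is segmented to a single binary object (Otsu threshold,
largest 8-connected component), from which four families of descriptors
are computed: statistical-geometrical region metrics, a centroid-to-
boundary ray signature (BIBS), a box-counting fractal dimension, and a
conventional bounding-box shape signature.
"""

from __future__ import annotations

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from scipy.ndimage import binary_fill_holes

from .io import validate_gray_image


def binarize_object(img: np.ndarray) -> np.ndarray:
    """Segment the dominant bright object.

    Otsu threshold on a 256-bin histogram, keeping the largest
    8-connected component of the above-threshold pixels.  Raises if no
    object pixel survives (e.g. a constant image).
    """
    img = validate_gray_image(img)
    if img.max() == img.min():
        raise ValueError("constant image has no object")
    thresh = threshold_otsu(img, nbins=256)
    mask = img > thresh
    if not mask.any():
        raise ValueError("thresholding produced an empty object mask")
    lab = label(mask, connectivity=2)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == int(np.argmax(sizes))


def _require_nonempty(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2 or not mask.any():
        raise ValueError("mask must be a nonempty 2-D binary grid")
    return mask


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Object pixels with at least one background 4-neighbour (the image
    border counts as background)."""
    mask = _require_nonempty(mask)
    padded = np.pad(mask, 1, constant_values=False)
    interior = (padded[:-2, 1:-1] & padded[2:, 1:-1]
                & padded[1:-1, :-2] & padded[1:-1, 2:])
    return mask & ~interior


#: Fixed output order of :func:`region_metrics`.
REGION_METRIC_NAMES = (
    "area", "centroid_row", "centroid_col", "convex_area",
    "equivalent_diameter", "euler_number", "extent",
    "major_axis_length", "minor_axis_length", "orientation",
    "eccentricity", "perimeter", "filled_area", "solidity",
    "bbox_height", "bbox_width",
)


def region_metrics(mask: np.ndarray) -> np.ndarray:
    """16 statistical-geometrical metrics of the object, in the fixed
    order of :data:`REGION_METRIC_NAMES`.

    The object is taken 8-connected with 4-connected background (the
    standard Euler-number pairing); the moment-equivalent ellipse gives
    the axis lengths, orientation and eccentricity; the perimeter is the
    count of 8-connected contour pixels (object pixels with a background
    4-neighbour).
    """
    mask = _require_nonempty(mask)
    lab = mask.astype(int)
    props = regionprops(lab)[0]
    filled = binary_fill_holes(mask)
    bbox = props.bbox  # (min_row, min_col, max_row, max_col)
    return np.array([
        float(props.area),
        float(props.centroid[0]),
        float(props.centroid[1]),
        float(props.area_convex),
        float(np.sqrt(4.0 * props.area / np.pi)),
        float(props.euler_number),
        float(props.extent),
        float(props.axis_major_length),
        float(props.axis_minor_length),
        float(props.orientation),
        float(props.eccentricity),
        float(boundary_pixels(mask).sum()),
        float(filled.sum()),
        float(props.solidity),
        float(bbox[2] - bbox[0]),
        float(bbox[3] - bbox[1]),
    ])


def bibs_signature(mask: np.ndarray, n_rays: int = 8) -> np.ndarray:
    """Boundary intersection-based signature.

    Rays are cast from the centroid at angles 2*pi*m/n_rays (counter-
    clockwise from east); each entry is the distance from the centroid to
    the farthest object pixel along the ray (the outermost intersection,
    which is what registers concavities).  The signature is divided by
    its maximum; a degenerate mask with no reachable boundary yields all
    zeros.
    """
    mask = _require_nonempty(mask)
    if n_rays < 4:
        raise ValueError("n_rays must be >= 4")
    h, w = mask.shape
    rows, cols = np.nonzero(mask)
    cr, cc = rows.mean(), cols.mean()
    max_dist = float(np.hypot(h, w))
    steps = np.arange(0, max_dist, 0.5)
    sig = np.zeros(n_rays)
    for m in range(n_rays):
        a = 2 * np.pi * m / n_rays
        rr = cr - steps * np.sin(a)
        cc_ = cc + steps * np.cos(a)
        ri_all = np.round(rr).astype(int)
        ci_all = np.round(cc_).astype(int)
        inside = (ri_all >= 0) & (ri_all < h) & (ci_all >= 0) & (ci_all < w)
        ri, ci = ri_all[inside], ci_all[inside]
        hits = np.flatnonzero(mask[ri, ci])
        if hits.size:
            sig[m] = steps[inside][hits[-1]]
    if sig.max() > 0:
        sig = sig / sig.max()
    return sig


def fractal_dimension(mask: np.ndarray) -> float:
    """Box-counting (Hausdorff-style) fractal dimension.

    The mask is zero-padded to the next power-of-two square; N(eps)
    counts occupied eps x eps grid boxes for eps = 2, 4, ..., side/2, and
    D is the least-squares slope of log N versus log(1/eps), clipped to
    [0, 2].
    """
    mask = _require_nonempty(mask)
    side = int(2 ** np.ceil(np.log2(max(mask.shape + (4,)))))
    padded = np.zeros((side, side), dtype=bool)
    padded[:mask.shape[0], :mask.shape[1]] = mask
    eps = 2 ** np.arange(1, int(np.log2(side)))
    counts = []
    for e in eps:
        blocks = padded.reshape(side // e, e, side // e, e)
        counts.append(int(blocks.any(axis=(1, 3)).sum()))
    if len(eps) < 2:
        return 0.0
    slope = np.polyfit(np.log(1.0 / eps), np.log(counts), 1)[0]
    return float(np.clip(slope, 0.0, 2.0))


def shape_signature_aspect(mask: np.ndarray) -> float:
    """Width/height aspect ratio of the object's boundary bounding box."""
    border = boundary_pixels(_require_nonempty(mask))
    rows, cols = np.nonzero(border)
    height = rows.max() - rows.min() + 1
    width = cols.max() - cols.min() + 1
    return float(width) / float(height)
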