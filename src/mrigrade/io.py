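"""Image reading, normalization, and class-labelled dataset handling.

Images are handled throughout the package as 2-D float arrays in [0, 1]
(row-major, origin top-left).  Datasets are directories with one
subdirectory per severity class; labels are the integers 1..4 in the
fixed clinical order Non-Demented, Very-Mild, Mild, Moderate.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from skimage.transform import resize

#: Fixed severity-class order; label = 1-based index into this list.
CLASS_NAMES = ("NonDemented", "VeryMild", "Mild", "Moderate")

# ITU-R BT.601 luminance weights for RGB -> gray collapse
# (full precision, summing exactly to 1; rounds to 0.2989/0.5870/0.1140).
_LUMA = np.array([0.298936021293775, 0.587043074451121, 0.114020904255104])


def validate_gray_image(img: np.ndarray, min_size: int = 8) -> np.ndarray:
    """Check an array satisfies the grayscale-image contract and return it.

    Values must be finite, within [0, 1], and both dimensions at least
    ``min_size`` (feature extractors assume 8).
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got ndim={img.ndim}")
    if img.shape[0] < min_size or img.shape[1] < min_size:
        raise ValueError(f"image {img.shape} smaller than minimum {min_size}x{min_size}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if img.min() < 0 or img.max() > 1:
        raise ValueError("image values must lie in [0, 1]")
    return img


@dataclass
class LabeledDataset:
    """Images with 1-based severity labels.

    Attributes
    ----------
    images : list of 2-D float arrays in [0, 1]
    labels : int array, values in 1..4
    class_names : ordered class names; ``class_names[label - 1]`` names a label
    """

    images: list
    labels: np.ndarray
    class_names: tuple = CLASS_NAMES

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels length mismatch")
        if len(self.labels) and not np.all((self.labels >= 1) & (self.labels <= len(self.class_names))):
            raise ValueError("labels must be in 1..%d" % len(self.class_names))

    def __len__(self):
        return len(self.images)

    def class_counts(self) -> dict:
        return {c: int(np.sum(self.labels == c)) for c in range(1, len(self.class_names) + 1)}


def read_image(path) -> np.ndarray:
    """Read a raster image as a grayscale float array in [0, 1].

    RGB inputs are collapsed with BT.601 luminance weights; integer pixel
    values are scaled by the bit-depth maximum (255 for 8-bit).
    """
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    scale = float(np.iinfo(arr.dtype).max) if np.issubdtype(arr.dtype, np.integer) else 1.0
    arr = arr.astype(float)
    if arr.ndim == 3:  # RGB(A) -> luminance before scaling
        arr = arr[..., :3] @ _LUMA
    img = np.clip(arr / scale, 0.0, 1.0)
    return validate_gray_image(img, min_size=1)


def write_image(img: np.ndarray, path) -> None:
    """Write a [0,1] grayscale image as an 8-bit PNG."""
    arr = np.clip(np.asarray(img, dtype=float), 0, 1)
    Image.fromarray(np.round(arr * 255).astype(np.uint8)).save(path)


def rescale(img: np.ndarray, size) -> np.ndarray:
    """Bilinear resize to ``size = (height, width)``, clipped to [0, 1]."""
    h, w = int(size[0]), int(size[1])
    if h < 8 or w < 8:
        raise ValueError("target dimensions must be at least 8 pixels")
    img = np.asarray(img, dtype=float)
    if img.shape == (h, w):
        return img.copy()
    out = resize(img, (h, w), order=1, mode="reflect", anti_aliasing=False)
    return np.clip(out, 0.0, 1.0)


def load_labeled_dataset(root) -> LabeledDataset:
    """Load ``root/<ClassName>/*.png`` into a :class:`LabeledDataset`.

    Requires exactly the four class directories; files are loaded in
    lexicographic order for cross-platform reproducibility.
    """
    root = os.fspath(root)
    missing = [c for c in CLASS_NAMES if not os.path.isdir(os.path.join(root, c))]
    if missing:
        raise ValueError(f"missing class directories under {root}: {missing}")
    images, labels = [], []
    for label, cname in enumerate(CLASS_NAMES, start=1):
        cdir = os.path.join(root, cname)
        files = sorted(f for f in os.listdir(cdir) if not f.startswith("."))
        loaded = 0
        for f in files:
            path = os.path.join(cdir, f)
            if not os.path.isfile(path):
                continue
            try:
                img = read_image(path)
            except (OSError, ValueError):
                continue  # non-raster files in the directory are skipped
            images.append(img)
            labels.append(label)
            loaded += 1
        if loaded == 0:
            raise ValueError(f"class directory {cdir} contains no decodable images")
    return LabeledDataset(images, np.array(labels))


def stratified_split(ds: LabeledDataset, train_fraction: float, seed: int):
    """Split per class into train/test with round-half-up train sizes.

    Returns ``(train, test)`` with disjoint union equal to the input,
    reproducible for a given seed.
    """
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for c in range(1, len(ds.class_names) + 1):
        idx = np.flatnonzero(ds.labels == c)
        if len(idx) < 2:
            raise ValueError(f"class {c} has fewer than 2 images")
        n_train = int(np.floor(train_fraction * len(idx) + 0.5))  # round half up
        n_train = min(max(n_train, 1), len(idx) - 1)
        perm = rng.permutation(len(idx))
        train_idx.extend(idx[perm[:n_train]])
        test_idx.extend(idx[perm[n_train:]])
    train_idx = sorted(train_idx)
    test_idx = sorted(test_idx)

    def subset(indices):
        return LabeledDataset([ds.images[i] for i in indices], ds.labels[indices], ds.class_names)

    return subset(train_idx), subset(np.array(test_idx, dtype=int))
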