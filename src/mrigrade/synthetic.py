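"""Seeded four-class brain-phantom generator.

Real dementia-severity MRI datasets are not redistributable, so the
package benchmarks its pipeline on structural phantoms that emulate the
two morphological markers of progressing atrophy: enlargement of the
ventricles and thinning (shrinkage) of the cortex.  Each phantom is a
bright elliptical "brain" with a mid-gray cortical band on a dark
background and a dark central "ventricle" ellipse; severity class 1..4
monotonically scales the ventricle up and the cortex down.  Additive
Gaussian noise and per-image position/rotation/scale jitter make the
classes learnable but not trivially separable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .io import CLASS_NAMES, LabeledDataset, write_image

#: Ventricle semi-axis scale (fraction of brain semi-axis), per class 1..4.
VENTRICLE_SCALE = (0.10, 0.18, 0.28, 0.42)
#: Cortical band thickness as a fraction of the brain semi-minor axis.
CORTEX_THICKNESS = (0.30, 0.24, 0.18, 0.12)


@dataclass
class PhantomSpec:
    size: int = 64
    severity: int = 1
    ventricle_scale: tuple = VENTRICLE_SCALE
    cortex_thickness: tuple = CORTEX_THICKNESS
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.size < 32:
            raise ValueError("size must be >= 32")
        if not 1 <= self.severity <= 4:
            raise ValueError("severity must be in 1..4")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not all(a < b for a, b in zip(self.ventricle_scale, self.ventricle_scale[1:])):
            raise ValueError("ventricle_scale must be strictly increasing")
        if not all(a > b for a, b in zip(self.cortex_thickness, self.cortex_thickness[1:])):
            raise ValueError("cortex_thickness must be strictly decreasing")


def _ellipse_mask(size, cr, cc, a, b, angle):
    """Boolean mask of a rotated ellipse with semi-axes (a, b)."""
    rr, cc_ = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    dr, dc = rr - cr, cc_ - cc
    u = dr * np.cos(angle) + dc * np.sin(angle)
    v = -dr * np.sin(angle) + dc * np.cos(angle)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec, jitter: bool = False,
                     rng: np.random.Generator | None = None) -> np.ndarray:
    """One phantom image in [0, 1], reproducible given the seed.

    With ``jitter`` the centre shifts by up to 5% of the image, the
    orientation by up to 10 degrees, and the brain size by +-10%,
    emulating acquisition variability.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    s = spec.size
    cr = cc = (s - 1) / 2.0
    a, b = 0.42 * s, 0.34 * s  # brain semi-axes (rows taller than wide)
    angle = 0.0
    if jitter:
        cr += rng.uniform(-0.05, 0.05) * s
        cc += rng.uniform(-0.05, 0.05) * s
        angle = np.deg2rad(rng.uniform(-10, 10))
        scale = 1.0 + rng.uniform(-0.1, 0.1)
        a, b = a * scale, b * scale
    k = spec.severity - 1
    img = np.full((s, s), 0.05)
    brain = _ellipse_mask(s, cr, cc, a, b, angle)
    img[brain] = 0.85  # bright parenchyma
    thick = spec.cortex_thickness[k] * b
    inner = _ellipse_mask(s, cr, cc, a - thick, b - thick, angle)
    img[brain & ~inner] = 0.55  # mid-gray cortical band
    vs = spec.ventricle_scale[k]
    ventricle = _ellipse_mask(s, cr, cc, vs * a, vs * b, angle)
    img[ventricle] = 0.15  # dark CSF-filled ventricle
    if spec.noise_sd > 0:
        img = img + rng.normal(0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_dataset(n_per_class: int, size: int = 64, noise_sd: float = 0.05,
                     seed: int = 0) -> LabeledDataset:
    """Balanced 4-class phantom dataset with per-image jitter."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for severity in range(1, 5):
        spec = PhantomSpec(size=size, severity=severity, noise_sd=noise_sd, seed=seed)
        for _ in range(n_per_class):
            images.append(generate_phantom(spec, jitter=True, rng=rng))
            labels.append(severity)
    return LabeledDataset(images, np.array(labels))


def write_dataset(ds: LabeledDataset, root, manifest: bool = True) -> list:
    """Write a dataset in the ``root/<ClassName>/*.png`` layout; returns
    (path, label) manifest rows."""
    rows = []
    counters = {c: 0 for c in range(1, 5)}
    for img, label in zip(ds.images, ds.labels):
        cdir = os.path.join(os.fspath(root), CLASS_NAMES[label - 1])
        os.makedirs(cdir, exist_ok=True)
        path = os.path.join(cdir, f"img_{counters[label]:05d}.png")
        counters[label] += 1
        write_image(img, path)
        rows.append((path, int(label)))
    return rows
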