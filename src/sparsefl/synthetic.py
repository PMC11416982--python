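"""Synthetic desk-scale datasets with the structure of smoothed brain maps.

``make_volumes`` emulates the inputs the method targets: smooth nonnegative 3-D
intensity volumes (think Gaussian-smoothed gray-matter density maps) carrying a
class-dependent spatial signal, an optional per-site intensity shift, and white
acquisition noise.  Each volume is

    base + effect_size * pattern(class) + shift(site) + noise,  clipped at 0,

where ``base`` is a smoothed Gaussian random field (unit variance), the class
pattern is a fixed set of Gaussian blobs whose locations depend only on
``(seed, class)`` — so the signal is learnable across samples — the site shift
is a scalar offset drawn once per site, and the noise has unit standard
deviation (``effect_size`` is therefore the signal-to-noise amplitude ratio).
A positive baseline keeps the clip from truncating the distribution.

Default grid is 16x16x16: the method is architecture-agnostic and desk-scale
grids keep every downstream test fast; full-size volumes are available through
the same spec.  What this generator does NOT emulate: anatomical structure,
registration/segmentation artefacts, or realistic covariance between sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["VolumeDatasetSpec", "make_volumes", "make_tabular", "save_volumes_nifti"]

_BASELINE = 3.0  # keeps voxel intensities essentially nonnegative before the clip


@dataclass
class VolumeDatasetSpec:
    """Parameters of the synthetic volumetric classification task."""

    n: int = 400
    shape: tuple[int, int, int] = (16, 16, 16)
    n_classes: int = 2
    effect_size: float = 5.0
    n_signal_blobs: int = 3
    smoothing_sigma: float = 1.5
    site_shift_sd: float = 0.0
    n_sites: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) != 3 or any(s < 4 for s in self.shape):
            raise ValueError("shape must be 3-D with every dimension >= 4")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n < self.n_classes:
            raise ValueError("need at least one sample per class")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")


def _class_pattern(spec: VolumeDatasetSpec, cls: int) -> np.ndarray:
    """Fixed blob pattern for one class; depends only on (seed, class)."""
    rng = np.random.default_rng([spec.seed, 101, cls])
    grid = np.indices(spec.shape).astype(np.float64)
    pattern = np.zeros(spec.shape)
    sigma_blob = max(min(spec.shape) / 8.0, 1.0)
    for _ in range(spec.n_signal_blobs):
        center = np.array([rng.uniform(2, s - 2) for s in spec.shape])
        d2 = sum((grid[a] - center[a]) ** 2 for a in range(3))
        pattern += np.exp(-d2 / (2 * sigma_blob**2))
    peak = pattern.max()
    return pattern / peak if peak > 0 else pattern


def make_volumes(
    spec: VolumeDatasetSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate ``(volumes, labels, sites)``; deterministic given ``spec.seed``.

    Labels are exactly balanced (up to remainder) and shuffled; sites are
    assigned uniformly at random.  All voxel values are >= 0.
    """
    rng = np.random.default_rng([spec.seed, 7])
    n, C = spec.n, spec.n_classes
    labels = np.tile(np.arange(C), n // C + 1)[:n]
    labels = labels[rng.permutation(n)]
    sites = rng.integers(0, spec.n_sites, size=n)
    site_shift = np.random.default_rng([spec.seed, 202]).normal(
        0.0, spec.site_shift_sd, size=spec.n_sites
    )
    patterns = np.stack([_class_pattern(spec, c) for c in range(C)])
    vols = np.empty((n,) + spec.shape)
    for i in range(n):
        base = rng.standard_normal(spec.shape)
        base = gaussian_filter(base, spec.smoothing_sigma)
        sd = base.std()
        if sd > 0:
            base /= sd
        noise = rng.standard_normal(spec.shape)
        vols[i] = (
            _BASELINE
            + base
            + spec.effect_size * patterns[labels[i]]
            + site_shift[sites[i]]
            + noise
        )
    np.clip(vols, 0.0, None, out=vols)
    return vols, labels, sites


def make_tabular(
    n: int, d: int, n_classes: int = 2, separation: float = 2.0, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian class-mean mixture: fast fixture for unit tests.

    Class c's mean is ``separation`` along coordinate ``c % d``; features have
    unit noise, so ``separation`` directly controls Bayes accuracy.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    rng = np.random.default_rng(seed)
    labels = np.tile(np.arange(n_classes), n // n_classes + 1)[:n]
    labels = labels[rng.permutation(n)]
    means = np.zeros((n_classes, d))
    for c in range(n_classes):
        means[c, c % d] = separation
    X = means[labels] + rng.standard_normal((n, d))
    return X, labels


def save_volumes_nifti(volumes: np.ndarray, directory, prefix: str = "vol") -> list:
    """Write one NIfTI file per volume; returns the written paths."""
    import os

    import nibabel as nib

    paths = []
    for i, v in enumerate(volumes):
        img = nib.Nifti1Image(np.asarray(v, dtype=np.float32), affine=np.eye(4))
        path = os.path.join(str(directory), f"{prefix}_{i:04d}.nii")
        nib.save(img, path)
        paths.append(path)
    return paths
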