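"""Seeded generators of labeled spectra and leaf cubes for testing the method.

The generator reproduces the *statistical* structure the self-training
method relies on, not leaf biophysics:

* five status classes with a configurable (typically strongly imbalanced)
  count vector;
* smooth 224-band reflectance curves built from a shared archetype, with
  class-conditional bumps planted inside known informative wavelength
  windows so that wavelength-importance analysis has a recoverable target;
* per-sample multiplicative scatter and additive white noise, plus a
  single-band high-variance artifact near 1,380 nm that smoothing should
  suppress;
* leaf cubes whose vein pixels closely resemble the whole-leaf mean
  spectrum while lamina pixels scatter more strongly and asymmetrically,
  so similarity screening prefers the vein region.

Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import uniform_filter

from nirleaf.spectra_io import (
    ClassScheme, HSICube, LabeledSet, N_SCHEME, SpectrumMatrix,
    default_wavelength_grid,
)

__all__ = ["GeneratorSpec", "simulate_labeled_set", "simulate_leaf_cube",
           "make_split", "N_WINDOWS_NM", "K_WINDOWS_NM",
           "REFERENCE_SPLIT_COUNTS"]

#: Wavelength windows (nm) carrying most of the class signal for each element.
N_WINDOWS_NM = ((945.0, 980.0), (1548.0, 1592.0), (1651.0, 1680.0))
K_WINDOWS_NM = ((964.0, 1044.0), (1283.0, 1400.0), (1665.0, 1676.0))

#: Reference study design: per-class counts (VL, Low, Proper, High, VH) of
#: the train/validation/test splits for each element.
REFERENCE_SPLIT_COUNTS = {
    "N": {"train": (45, 93, 225, 104, 268),
          "val": (19, 43, 83, 49, 121),
          "test": (13, 45, 93, 47, 152)},
    "K": {"train": (29, 131, 185, 289, 116),
          "val": (17, 69, 88, 126, 49),
          "test": (16, 75, 87, 128, 44)},
}

# control points of the shared reflectance archetype: a broad NIR plateau
# with absorption dips near 1,200 and 1,450 nm
_ARCHETYPE_NM = (900.0, 1000.0, 1100.0, 1200.0, 1300.0, 1400.0, 1500.0, 1600.0, 1700.0)
_ARCHETYPE_R = (0.55, 0.58, 0.55, 0.48, 0.52, 0.40, 0.33, 0.38, 0.36)


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic spectrum/cube generator.

    ``effect_size`` scales the separation of adjacent class means inside
    the informative windows, in units of ``noise_sd``; 0 removes all class
    signal.  ``scatter_sd`` is the scale of per-sample multiplicative
    scatter (1 + eps).  ``artifact_nm`` locates the single-band noise
    spike.
    """

    scheme: ClassScheme = N_SCHEME
    class_counts: tuple[int, ...] = REFERENCE_SPLIT_COUNTS["N"]["train"]
    informative_windows: tuple[tuple[float, float], ...] = N_WINDOWS_NM
    effect_size: float = 2.0
    noise_sd: float = 0.01
    scatter_sd: float = 0.03
    artifact_nm: float = 1380.0
    artifact_scale: float = 10.0
    seed: int = 0
    wavelengths: np.ndarray = field(default_factory=default_wavelength_grid)

    def __post_init__(self) -> None:
        self.class_counts = tuple(int(c) for c in self.class_counts)
        if len(self.class_counts) != 5 or min(self.class_counts) < 0:
            raise ValueError("class_counts must be 5 non-negative integers")
        if max(self.class_counts) == 0:
            raise ValueError("at least one class_count must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)


def _archetype(wavelengths: np.ndarray) -> np.ndarray:
    return CubicSpline(_ARCHETYPE_NM, _ARCHETYPE_R)(wavelengths)


def _window_profile(wavelengths: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Raised-cosine bump supported on [lo, hi], peak 1 at the centre."""
    centre, half = (lo + hi) / 2.0, (hi - lo) / 2.0
    x = (wavelengths - centre) / max(half, 1e-9)
    prof = np.where(np.abs(x) <= 1.0, 0.5 * (1.0 + np.cos(np.pi * x)), 0.0)
    return prof


def class_mean_spectra(spec: GeneratorSpec) -> np.ndarray:
    """Noise-free per-class mean curves, shape (5, n_bands).

    Class c shifts the archetype inside each informative window by
    ``effect_size * noise_sd * (c - 2) / 2`` at the window centre, so
    adjacent classes are separated by half an effect size per window.
    """
    base = _archetype(spec.wavelengths)
    bump = np.zeros_like(base)
    for lo, hi in spec.informative_windows:
        bump += _window_profile(spec.wavelengths, lo, hi)
    step = spec.effect_size * spec.noise_sd / 2.0
    return np.stack([base + (c - 2) * step * bump for c in range(5)])


def _concentration_bounds(scheme: ClassScheme) -> list[tuple[float, float]]:
    """Closed sampling intervals per class; open-ended classes get a bounded
    extension of width equal to the neighbouring interval."""
    t = scheme.thresholds
    w_low, w_high = t[1] - t[0], t[3] - t[2]
    return [(t[0] - w_low, t[0]), (t[0], t[1]), (t[1], t[2]),
            (t[2], t[3]), (t[3], t[3] + w_high)]


def simulate_labeled_set(spec: GeneratorSpec,
                         rng: np.random.Generator | None = None) -> LabeledSet:
    """Draw a labeled mean-spectrum set under ``spec``.

    Each sample is ``(1 + eps) * mean_c + noise`` with an extra Normal
    spike of ``artifact_scale * noise_sd`` in the band nearest
    ``artifact_nm``; concentrations are uniform within the class's
    diagnostic interval.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    means = class_mean_spectra(spec)
    n_bands = spec.wavelengths.size
    labels = np.repeat(np.arange(5), spec.class_counts)
    n = labels.size

    eps = rng.normal(0.0, spec.scatter_sd, size=n)
    noise = rng.normal(0.0, spec.noise_sd, size=(n, n_bands))
    values = (1.0 + eps)[:, None] * means[labels] + noise
    spike_band = int(np.argmin(np.abs(spec.wavelengths - spec.artifact_nm)))
    values[:, spike_band] += rng.normal(
        0.0, spec.artifact_scale * spec.noise_sd, size=n)

    bounds = _concentration_bounds(spec.scheme)
    conc = np.empty(n)
    for c in range(5):
        m = labels == c
        lo, hi = bounds[c]
        conc[m] = rng.uniform(lo, hi, size=int(m.sum()))
    return LabeledSet(SpectrumMatrix(values, spec.wavelengths), labels,
                      conc, spec.scheme)


# ---------------------------------------------------------------------------
# leaf cubes


def _leaf_masks(height: int, width: int,
                vein_fraction: float) -> tuple[np.ndarray, np.ndarray]:
    """Elliptic leaf mask with a midrib plus diagonal branch veins.

    Vein thickness is widened until the vein share of leaf pixels reaches
    approximately ``vein_fraction``.
    """
    yy, xx = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0
    leaf = ((yy - cy) / (0.48 * height)) ** 2 + ((xx - cx) / (0.48 * width)) ** 2 <= 1.0
    if not leaf.any():
        raise ValueError("degenerate leaf mask: no pixels inside the ellipse")

    # distance to midrib (horizontal centre line) and to diagonal branches
    d_mid = np.abs(yy - cy)
    branches = [np.abs((yy - cy) - s * (xx - bx)) / np.sqrt(1 + s * s)
                for bx in np.linspace(0.2 * width, 0.8 * width, 4)
                for s in (+0.8, -0.8)]
    d_vein = np.minimum(d_mid, np.minimum.reduce(branches))

    target = max(1, int(round(vein_fraction * leaf.sum())))
    # take the `target` leaf pixels closest to the vein skeleton
    flat = np.where(leaf.ravel())[0]
    order = np.argsort(d_vein.ravel()[flat], kind="stable")[:target]
    vein = np.zeros(height * width, dtype=bool)
    vein[flat[order]] = True
    return leaf, vein.reshape(height, width)


def simulate_leaf_cube(spec: GeneratorSpec, height: int, width: int,
                       class_label: int, vein_fraction: float = 0.3) -> HSICube:
    """Simulate one leaf cube of a given status class.

    Vein pixels deviate only slightly from the leaf-mean curve; lamina
    pixels carry (a) a right-skewed multiplicative scatter (centred
    exponential, mean 0) so their typical projection onto the mean
    spectrum falls below the vein's, (b) a spatially correlated
    multiplicative field (separable moving-average of white noise), and
    (c) the same additive noise and 1,380 nm artifact as the labeled
    spectra.  The leaf-mean spectrum of the cube is unbiased for the
    class mean.
    """
    if not 0.0 < vein_fraction < 1.0:
        raise ValueError("vein_fraction must lie in (0, 1)")
    if not 0 <= class_label <= 4:
        raise ValueError("class_label must lie in 0..4")
    rng = np.random.default_rng(spec.seed)
    mean = class_mean_spectra(spec)[class_label]
    n_bands = spec.wavelengths.size
    leaf, vein = _leaf_masks(height, width, vein_fraction)
    lamina = leaf & ~vein

    factor = np.ones((height, width))
    # vein: tight symmetric scatter
    factor[vein] = 1.0 + rng.normal(0.0, spec.scatter_sd / 5.0, size=int(vein.sum()))
    # lamina: right-skewed, zero-mean scatter (occasional bright pixels,
    # most slightly dim) so median similarity drops below the vein's
    factor[lamina] = 1.0 + 2.0 * spec.scatter_sd * (
        rng.exponential(1.0, size=int(lamina.sum())) - 1.0)

    # spatially correlated multiplicative field on the lamina
    field_ = uniform_filter(rng.normal(0.0, 1.0, size=(height, width)), size=7)
    field_ -= field_[leaf].mean()
    sd = field_[leaf].std()
    if sd > 0:
        field_ *= 0.5 * spec.scatter_sd / sd
    mult = factor + np.where(lamina, field_, 0.0)

    data = mult[:, :, None] * mean[None, None, :]
    data += rng.normal(0.0, spec.noise_sd, size=(height, width, n_bands))
    spike_band = int(np.argmin(np.abs(spec.wavelengths - spec.artifact_nm)))
    data[:, :, spike_band] += rng.normal(
        0.0, spec.artifact_scale * spec.noise_sd, size=(height, width))
    return HSICube(data, spec.wavelengths, leaf, vein)


def make_split(labeled: LabeledSet,
               ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
               seed: int = 0) -> tuple[LabeledSet, LabeledSet, LabeledSet]:
    """Random (non-stratified) train/validation/test split by ``ratios``."""
    if len(labeled) == 0:
        raise ValueError("cannot split an empty labeled set")
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size != 3 or not np.isclose(ratios.sum(), 1.0):
        raise ValueError("ratios must be 3 floats summing to 1")
    n = len(labeled)
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(round(ratios[0] * n))
    n_val = int(round(ratios[1] * n))
    n_val = min(n_val, n - n_train)
    return (labeled.subset(perm[:n_train]),
            labeled.subset(perm[n_train:n_train + n_val]),
            labeled.subset(perm[n_train + n_val:]))
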