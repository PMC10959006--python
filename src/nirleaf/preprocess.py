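"""Spectral preprocessing and similarity screening of unlabeled pixels.

Unlabeled hyperspectral pixels are only useful to self-training if they
live near the labeled data in feature space.  Vein-region pixels closely
track the whole-leaf mean spectrum (which is what carries the wet-chemistry
label), so pixels are scored by their similarity to the leaf-mean spectrum
and only the top-scoring ones are kept as the unlabeled pool.

The similarity score for pixel spectrum k_i against mean spectrum q is

    score_i = (q . k_i) / d,        d = number of bands (224),

min-max normalised to [0, 1] across the pixels of a leaf.  The score is a
scaled projection onto the mean spectrum; despite the field's habit of
calling it "cosine similarity" it carries no vector-norm denominator, and
a true cosine variant is available via ``metric="cosine"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from nirleaf.spectra_io import HSICube, SpectrumMatrix

__all__ = ["SimilarityResult", "sg_smooth", "mean_spectrum", "minmax_norm",
           "pixel_similarity", "screen_pixels"]

#: Savitzky-Golay defaults for the ~3.3 nm band spacing.
SG_WINDOW = 11
SG_POLYORDER = 2


@dataclass
class SimilarityResult:
    """Per-pixel similarity scores in [0, 1] and the derived keep mask."""

    scores: np.ndarray
    keep_mask: np.ndarray


def sg_smooth(spectra: SpectrumMatrix, window: int = SG_WINDOW,
              polyorder: int = SG_POLYORDER) -> SpectrumMatrix:
    """Savitzky-Golay smoothing along the band axis of each spectrum.

    Fits a local least-squares polynomial in a sliding window; reproduces
    any polynomial of degree <= ``polyorder`` exactly and strongly damps
    single-band artifacts such as the 1,380 nm noise spike.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    smoothed = savgol_filter(spectra.values, window_length=window,
                             polyorder=polyorder, axis=1)
    return SpectrumMatrix(smoothed, spectra.wavelengths)


def mean_spectrum(cube: HSICube, region: str = "leaf") -> np.ndarray:
    """Per-band arithmetic mean over the pixels of ``region`` (leaf/vein/lamina)."""
    from nirleaf.spectra_io import _region_mask
    mask = _region_mask(cube, region)
    if not mask.any():
        raise ValueError(f"region {region!r} mask is empty")
    return cube.data[mask].mean(axis=0)


def minmax_norm(x: np.ndarray) -> np.ndarray:
    """Affine map of ``x`` onto [0, 1]: min -> 0, max -> 1, order preserved.

    A constant vector has no span; it maps to all zeros with a warning.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn("minmax_norm: constant input, returning all zeros")
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def pixel_similarity(q: np.ndarray, pixels: SpectrumMatrix,
                     metric: str = "projection") -> np.ndarray:
    """Similarity of each pixel spectrum to the mean spectrum ``q``.

    ``metric="projection"`` (default) is the dot product divided by the
    band count, then min-max normalised across pixels.  ``metric="cosine"``
    uses the conventional cosine similarity instead (also normalised).
    """
    q = np.asarray(q, dtype=float)
    if q.size != pixels.n_bands:
        raise ValueError(
            f"band mismatch: q has {q.size}, pixels have {pixels.n_bands}")
    if metric == "projection":
        raw = pixels.values @ q / q.size
    elif metric == "cosine":
        norms = np.linalg.norm(pixels.values, axis=1) * np.linalg.norm(q)
        raw = (pixels.values @ q) / np.where(norms == 0, 1.0, norms)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return minmax_norm(raw)


def screen_pixels(cube: HSICube, q: np.ndarray | None = None, *,
                  top_fraction: float | None = None,
                  threshold: float | None = None,
                  sg_window: int = SG_WINDOW, sg_polyorder: int = SG_POLYORDER,
                  metric: str = "projection") -> tuple[SpectrumMatrix, SimilarityResult]:
    """Select leaf pixels similar to the mean spectrum as the unlabeled pool.

    ``q`` defaults to the cube's leaf-mean spectrum.  Both ``q`` and the
    pixels are Savitzky-Golay smoothed before scoring; the kept pixels are
    returned smoothed.  Exactly one keep rule applies:

    - ``top_fraction=f``: keep the ceil(f * n) highest-scoring pixels
      (ties broken by pixel raster order);
    - ``threshold=t``: keep pixels with score >= t.

    The default rule is ``top_fraction=0.3`` — the vein region is a
    minority of the leaf.
    """
    if top_fraction is not None and threshold is not None:
        raise ValueError("give either top_fraction or threshold, not both")
    if top_fraction is None and threshold is None:
        top_fraction = 0.3
    if top_fraction is not None and not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must lie in (0, 1]")
    if threshold is not None and not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")

    pixels = sg_smooth(cube.pixels("leaf"), sg_window, sg_polyorder)
    if q is None:
        q = mean_spectrum(cube, "leaf")
    q = sg_smooth(SpectrumMatrix(np.asarray(q, dtype=float)[None, :],
                                 cube.wavelengths),
                  sg_window, sg_polyorder).values[0]
    scores = pixel_similarity(q, pixels, metric=metric)

    n = scores.size
    if top_fraction is not None:
        k = max(1, int(np.ceil(top_fraction * n)))
        # stable sort on (-score, raster index): ties keep raster order
        order = np.argsort(-scores, kind="stable")[:k]
        keep = np.zeros(n, dtype=bool)
        keep[order] = True
    else:
        keep = scores >= threshold
    if not keep.any():
        raise ValueError("keep rule selected zero pixels")
    kept = SpectrumMatrix(pixels.values[keep], pixels.wavelengths)
    return kept, SimilarityResult(scores=scores, keep_mask=keep)
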