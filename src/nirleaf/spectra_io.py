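"""Spectra tables and hyperspectral cubes: containers, grids, and I/O.

Conventions
-----------
* Reflectance is unitless, roughly in [0, 1.2].
* The spectrometer records 256 bands over 866-1,701 nm; the first 32 bands
  have very low signal-to-noise and are dropped, leaving the 224-band
  working grid from 942 to 1,680 nm.  All downstream code assumes the
  trimmed 224-band grid.
* Cubes are always held band-last (H, W, B) in memory regardless of the
  on-disk interleave.
* Wavelength metadata travels with the values; band indexing is 0-based.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpectrumMatrix", "HSICube", "ClassScheme", "LabeledSet",
    "CLASS_NAMES", "N_SCHEME", "K_SCHEME",
    "N_BANDS_RAW", "N_BANDS", "N_DROPPED_BANDS",
    "default_wavelength_grid", "raw_wavelength_grid", "trim_bands",
    "read_labeled_table", "write_labeled_table",
    "read_cube", "write_cube",
    "FormatError",
]

#: Number of bands the spectrometer records.
N_BANDS_RAW = 256
#: Low-SNR leading bands removed before any analysis.
N_DROPPED_BANDS = 32
#: Bands on the working grid.
N_BANDS = N_BANDS_RAW - N_DROPPED_BANDS

#: The five foliar nutrient status classes, index 0..4.
CLASS_NAMES = ("VL", "Low", "Proper", "High", "VH")


class FormatError(ValueError):
    """Raised when an on-disk file violates the expected layout."""


def default_wavelength_grid() -> np.ndarray:
    """The 224-band working grid: evenly spaced 942-1,680 nm inclusive."""
    return np.linspace(942.0, 1680.0, N_BANDS)


def raw_wavelength_grid() -> np.ndarray:
    """The 256-band instrument grid: evenly spaced 866-1,701 nm inclusive.

    The mean adjacent spacing of both grids is ~3.3 nm.  Note the two grids
    are published as independent facts and are not exactly consistent with
    each other under 32-band trimming; the trimmed 942-1,680 nm grid is
    authoritative for all analysis.
    """
    return np.linspace(866.0, 1701.0, N_BANDS_RAW)


@dataclass
class SpectrumMatrix:
    """Reflectance spectra, one row per sample, with the band grid attached.

    Parameters
    ----------
    values : ndarray, shape (n_samples, n_bands)
        Reflectance, unitless.
    wavelengths : ndarray, shape (n_bands,)
        Band centres in nm, strictly increasing.
    """

    values: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (n_samples, n_bands)")
        if self.wavelengths.ndim != 1 or self.wavelengths.size != self.values.shape[1]:
            raise ValueError("wavelengths length must equal the band count")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectra contain NaN/Inf")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    def __len__(self) -> int:
        return self.n_samples


@dataclass
class HSICube:
    """A hyperspectral leaf image: (H, W, B) reflectance plus pixel masks.

    ``leaf_mask`` marks pixels on the leaf; ``vein_mask`` is the subset of
    leaf pixels on the vein structure (midrib and branches), whose spectra
    closely resemble the whole-leaf mean spectrum.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    leaf_mask: np.ndarray
    vein_mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.leaf_mask = np.asarray(self.leaf_mask, dtype=bool)
        self.vein_mask = np.asarray(self.vein_mask, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("cube data must be 3-D (H, W, B)")
        if self.wavelengths.size != self.data.shape[2]:
            raise ValueError("wavelengths length must equal the band count")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.leaf_mask.shape != self.data.shape[:2]:
            raise ValueError("leaf_mask shape must match (H, W)")
        if self.vein_mask.shape != self.data.shape[:2]:
            raise ValueError("vein_mask shape must match (H, W)")
        if np.any(self.vein_mask & ~self.leaf_mask):
            raise ValueError("vein_mask must be a subset of leaf_mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def pixels(self, region: str = "leaf") -> SpectrumMatrix:
        """Masked pixels as a SpectrumMatrix, in raster (row-major) order."""
        mask = _region_mask(self, region)
        return SpectrumMatrix(self.data[mask], self.wavelengths)


def _region_mask(cube: HSICube, region: str) -> np.ndarray:
    if region == "leaf":
        return cube.leaf_mask
    if region == "vein":
        return cube.vein_mask
    if region == "lamina":
        return cube.leaf_mask & ~cube.vein_mask
    raise ValueError(f"unknown region {region!r}")


@dataclass(frozen=True)
class ClassScheme:
    """A five-level diagnostic scheme for one element.

    ``thresholds`` are the four concentration breakpoints (% dry mass)
    separating VL | Low | Proper | High | VH.
    """

    element: str
    thresholds: tuple[float, float, float, float]
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        if self.element not in ("N", "K"):
            raise ValueError("element must be 'N' or 'K'")
        if len(self.thresholds) != 4 or np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be 4 strictly increasing values")
        if len(self.class_names) != 5:
            raise ValueError("exactly 5 classes required")

    def classify_concentration(self, conc) -> np.ndarray:
        """Map concentrations (% dry mass) to class indices 0..4.

        Breakpoints belong to the lower class of each pair, i.e. class i is
        (t_{i-1}, t_i]; values above the last breakpoint are class 4.
        """
        conc = np.atleast_1d(np.asarray(conc, dtype=float))
        return np.searchsorted(np.asarray(self.thresholds), conc, side="left").astype(int)


#: Foliar diagnostic breakpoints for rubber leaves, % dry mass.
N_SCHEME = ClassScheme("N", (2.90, 3.20, 3.40, 3.80))
K_SCHEME = ClassScheme("K", (0.70, 0.90, 1.10, 1.50))


@dataclass
class LabeledSet:
    """Spectra with 5-level status labels and optional concentrations."""

    spectra: SpectrumMatrix
    labels: np.ndarray
    concentrations: np.ndarray | None = None
    scheme: ClassScheme | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (self.spectra.n_samples,):
            raise ValueError("labels length must equal the sample count")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() > 4):
            raise ValueError("labels must lie in 0..4")
        if self.concentrations is not None:
            self.concentrations = np.asarray(self.concentrations, dtype=float)
            if self.concentrations.shape != self.labels.shape:
                raise ValueError("concentrations length must equal the sample count")

    @property
    def class_counts(self) -> np.ndarray:
        """Per-class sample counts C_i, i = 0..4."""
        return np.bincount(self.labels, minlength=5)

    def __len__(self) -> int:
        return self.spectra.n_samples

    def subset(self, idx) -> "LabeledSet":
        idx = np.asarray(idx)
        return LabeledSet(
            SpectrumMatrix(self.spectra.values[idx], self.spectra.wavelengths),
            self.labels[idx],
            None if self.concentrations is None else self.concentrations[idx],
            self.scheme,
        )


# ---------------------------------------------------------------------------
# band trimming

def trim_bands(x, n_drop: int = N_DROPPED_BANDS):
    """Drop the first ``n_drop`` low-SNR bands of a matrix or cube.

    The wavelength vector is trimmed in lockstep.  With the defaults this
    takes the 256 instrument bands to the 224-band working grid.
    """
    if isinstance(x, SpectrumMatrix):
        if n_drop >= x.n_bands:
            raise ValueError(f"n_drop={n_drop} >= band count {x.n_bands}")
        if n_drop == 0:
            return x
        return SpectrumMatrix(x.values[:, n_drop:], x.wavelengths[n_drop:])
    if isinstance(x, HSICube):
        if n_drop >= x.n_bands:
            raise ValueError(f"n_drop={n_drop} >= band count {x.n_bands}")
        if n_drop == 0:
            return x
        return HSICube(x.data[:, :, n_drop:], x.wavelengths[n_drop:],
                       x.leaf_mask, x.vein_mask)
    raise TypeError("expected a SpectrumMatrix or HSICube")


# ---------------------------------------------------------------------------
# labeled tables (CSV)

_BAND_COL_RE = re.compile(r"^band_([0-9.]+)$")


def _band_columns(wavelengths: np.ndarray) -> list[str]:
    return [f"band_{w:06.1f}" for w in wavelengths]


def write_labeled_table(path, labeled: LabeledSet) -> None:
    """Write a LabeledSet as CSV: band columns, `label`, optional `concentration_pct`."""
    df = pd.DataFrame(labeled.spectra.values,
                      columns=_band_columns(labeled.spectra.wavelengths))
    df["label"] = labeled.labels
    if labeled.concentrations is not None:
        df["concentration_pct"] = labeled.concentrations
    df.to_csv(path, index=False)


def read_labeled_table(path, scheme: ClassScheme | None = None,
                       n_bands: int = N_BANDS) -> LabeledSet:
    """Read a labeled mean-spectrum table (CSV).

    The table must carry ``n_bands`` band columns named ``band_<nm>``, and a
    ``label`` column (integer 0-4 or class name) and/or a
    ``concentration_pct`` column.  When only concentrations are present,
    labels are derived from ``scheme``.
    """
    df = pd.read_csv(path)
    band_cols = [c for c in df.columns if _BAND_COL_RE.match(c)]
    if len(band_cols) != n_bands:
        raise FormatError(
            f"expected {n_bands} band columns, found {len(band_cols)} in {path}")
    wavelengths = np.array([float(_BAND_COL_RE.match(c).group(1)) for c in band_cols])
    order = np.argsort(wavelengths)
    wavelengths = wavelengths[order]
    band_cols = [band_cols[i] for i in order]
    spectra = SpectrumMatrix(df[band_cols].to_numpy(dtype=float), wavelengths)

    conc = None
    if "concentration_pct" in df.columns:
        conc = df["concentration_pct"].to_numpy(dtype=float)

    if "label" in df.columns:
        labels = _parse_labels(df["label"])
    elif conc is not None:
        if scheme is None:
            raise FormatError("table has only concentrations; a ClassScheme is required")
        labels = scheme.classify_concentration(conc)
    else:
        raise FormatError("table has neither a 'label' nor a 'concentration_pct' column")
    return LabeledSet(spectra, labels, conc, scheme)


def _parse_labels(col: pd.Series) -> np.ndarray:
    name_to_idx = {n.lower(): i for i, n in enumerate(CLASS_NAMES)}
    name_to_idx.update({"very low": 0, "very high": 4})
    out = np.empty(len(col), dtype=int)
    for i, tok in enumerate(col):
        if isinstance(tok, str) and not tok.strip().lstrip("-").isdigit():
            key = tok.strip().lower()
            if key not in name_to_idx:
                raise FormatError(f"unknown label token {tok!r}")
            out[i] = name_to_idx[key]
        else:
            v = int(tok)
            if not 0 <= v <= 4:
                raise FormatError(f"label {v} outside 0..4")
            out[i] = v
    return out


# ---------------------------------------------------------------------------
# hyperspectral cubes (NPZ canonical; ENVI .hdr + raw)

def write_cube(path, cube: HSICube, dialect: str = "NPZ",
               interleave: str = "bil") -> None:
    """Write a cube as NPZ (canonical) or ENVI header + raw.

    ENVI data are stored float32 little-endian in the requested interleave;
    NPZ keeps full float64 precision.
    """
    path = Path(path)
    if dialect.upper() == "NPZ":
        np.savez(path, data=cube.data, wavelengths=cube.wavelengths,
                 leaf_mask=cube.leaf_mask, vein_mask=cube.vein_mask)
        return
    if dialect.upper() != "ENVI":
        raise ValueError(f"unknown dialect {dialect!r}")
    interleave = interleave.lower()
    if interleave not in ("bil", "bip", "bsq"):
        raise ValueError(f"unknown interleave {interleave!r}")
    h, w, b = cube.shape
    arr = cube.data.astype("<f4")
    if interleave == "bip":        # (lines, samples, bands)
        raw = arr
    elif interleave == "bil":      # (lines, bands, samples)
        raw = arr.transpose(0, 2, 1)
    else:                          # bsq: (bands, lines, samples)
        raw = arr.transpose(2, 0, 1)
    raw_path = path.with_suffix(".raw")
    raw.tofile(raw_path)
    wl = ", ".join(f"{x:.4f}" for x in cube.wavelengths)
    hdr = (
        "ENVI\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength = {{ {wl} }}\n"
    )
    path.with_suffix(".hdr").write_text(hdr)
    # masks ride alongside as a small NPZ (ENVI has no mask convention)
    np.savez(path.with_suffix(".masks.npz"),
             leaf_mask=cube.leaf_mask, vein_mask=cube.vein_mask)


def read_cube(path, dialect: str | None = None) -> HSICube:
    """Read a cube written by :func:`write_cube`; returns band-last layout.

    ``dialect`` is inferred from the file name when omitted (``.npz`` vs
    ``.hdr``/``.raw``).
    """
    path = Path(path)
    if dialect is None:
        dialect = "NPZ" if path.suffix == ".npz" else "ENVI"
    if dialect.upper() == "NPZ":
        with np.load(path) as z:
            for key in ("data", "wavelengths", "leaf_mask", "vein_mask"):
                if key not in z:
                    raise FormatError(f"NPZ cube missing key {key!r}")
            return HSICube(z["data"], z["wavelengths"], z["leaf_mask"], z["vein_mask"])
    if dialect.upper() != "ENVI":
        raise ValueError(f"unknown dialect {dialect!r}")

    hdr = _parse_envi_header(path.with_suffix(".hdr").read_text())
    h, w, b = hdr["lines"], hdr["samples"], hdr["bands"]
    if "wavelength" not in hdr:
        raise FormatError("ENVI header lacks wavelength metadata")
    wavelengths = np.asarray(hdr["wavelength"], dtype=float)
    if wavelengths.size != b:
        raise FormatError("ENVI wavelength list length differs from band count")
    if hdr.get("data type", 4) != 4:
        raise FormatError("only data type 4 (float32) is supported")
    raw = np.fromfile(path.with_suffix(".raw"), dtype="<f4")
    if raw.size != h * w * b:
        raise FormatError(
            f"raw size {raw.size} does not match header {h}x{w}x{b}")
    interleave = hdr.get("interleave", "bil")
    if interleave == "bip":
        data = raw.reshape(h, w, b)
    elif interleave == "bil":
        data = raw.reshape(h, b, w).transpose(0, 2, 1)
    elif interleave == "bsq":
        data = raw.reshape(b, h, w).transpose(1, 2, 0)
    else:
        raise FormatError(f"unknown interleave {interleave!r}")
    masks_path = path.with_suffix(".masks.npz")
    if masks_path.exists():
        with np.load(masks_path) as z:
            leaf, vein = z["leaf_mask"], z["vein_mask"]
    else:
        warnings.warn("no mask sidecar found; assuming all pixels are leaf")
        leaf = np.ones((h, w), dtype=bool)
        vein = np.zeros((h, w), dtype=bool)
    return HSICube(np.ascontiguousarray(data, dtype=float), wavelengths, leaf, vein)


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().startswith("ENVI"):
        raise FormatError("not an ENVI header")
    # join { ... } blocks that may span lines
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    out: dict = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, val = (s.strip() for s in line.split("=", 1))
        key = key.lower()
        if val.startswith("{"):
            items = [s for s in val.strip("{} ").split(",") if s.strip()]
            out[key] = [float(s) for s in items]
        else:
            try:
                out[key] = int(val)
            except ValueError:
                out[key] = val.lower()
    return out
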