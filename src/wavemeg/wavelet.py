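"""Multilevel 2D Haar wavelet decomposition of stimulus images.

One decomposition level splits an image into four half-resolution
sub-bands by separable low-pass (``h_phi``) / high-pass (``h_psi``)
filtering followed by dyadic downsampling:

* **A** (approximation): low-pass on both axes — a smoothed half-size copy;
* **H** (horizontal detail): the band that responds maximally to
  horizontal stripes (high-pass across rows, low-pass along them);
* **V** (vertical detail): symmetric, maximal for vertical stripes;
* **D** (diagonal detail): high-pass on both axes.

Levels recurse on A. With 5 levels a 175 x 175 image yields per-level side
lengths 88 / 44 / 22 / 11 / 6. Per stimulus and level the flattened A, H,
V, D vectors plus their concatenation "ALL" = [H | V | D] give 5
descriptors, hence 25 descriptors (W1...W25) for a 5-level decomposition.

The filters are the orthonormal Haar pair (coefficients ``1/sqrt(2)``),
so a single level conserves energy and is exactly invertible on
even-sided inputs. Odd side lengths use half-sample symmetric padding
(the last row/column is mirrored once), which produces output side
length ``floor((n + 1) / 2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import h5py
import numpy as np
import pywt
from PIL import Image

__all__ = [
    "BT601_WEIGHTS",
    "FilterPair",
    "HAAR",
    "QuadBands",
    "WaveletDescriptor",
    "to_grayscale",
    "load_image",
    "dwt2_level",
    "idwt2_level",
    "multilevel_decompose",
    "build_descriptors",
    "descriptor_index",
    "save_descriptors",
]

#: ITU-R BT.601 luminance weights for RGB -> grayscale conversion.
BT601_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Bands in storage order; "ALL" denotes the concatenated details [H|V|D].
BANDS = ("A", "H", "V", "D", "ALL")

MIN_SIDE = 2  # a single Haar filter tap pair needs at least 2 samples


@dataclass(frozen=True)
class FilterPair:
    """An orthonormal low-pass / high-pass FIR analysis pair."""

    lowpass: tuple[float, ...]
    highpass: tuple[float, ...]
    name: str = "haar"

    def __post_init__(self) -> None:
        lo, hi = np.asarray(self.lowpass), np.asarray(self.highpass)
        if not (np.isfinite(lo).all() and np.isfinite(hi).all()):
            raise ValueError("filter coefficients must be finite")
        if abs(lo @ lo - 1.0) > 1e-12 or abs(lo @ hi) > 1e-12:
            raise ValueError("filters must be orthonormal (unit energy, orthogonal)")


_S = 1.0 / math.sqrt(2.0)
#: The orthonormal Haar analysis pair.
HAAR = FilterPair(lowpass=(_S, _S), highpass=(-_S, _S))


@dataclass
class QuadBands:
    """The four sub-band grids of one decomposition level."""

    level: int
    A: np.ndarray
    H: np.ndarray
    V: np.ndarray
    D: np.ndarray

    def __post_init__(self) -> None:
        shapes = {b.shape for b in (self.A, self.H, self.V, self.D)}
        if len(shapes) != 1:
            raise ValueError(f"sub-bands must share one shape; got {shapes}")
        if self.level < 1:
            raise ValueError("level must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.A.shape

    def band(self, name: str) -> np.ndarray:
        return {"A": self.A, "H": self.H, "V": self.V, "D": self.D}[name]


@dataclass
class WaveletDescriptor:
    """One flattened sub-band coefficient vector of one stimulus."""

    id: str  # W1..W25 in (level-major, band A,H,V,D,ALL) order
    level: int
    band: str
    vector: np.ndarray = field(repr=False)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert a raster image to a single-channel grid in [0, 1].

    RGB inputs are combined with BT.601 luminance weights
    (0.299 R + 0.587 G + 0.114 B); grayscale inputs pass through. 8-bit
    integer inputs are scaled by 1/255.
    """
    arr = np.asarray(image)
    if not np.isfinite(np.asarray(arr, dtype=float)).all():
        raise ValueError("image contains non-finite values")
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / 255.0
    else:
        arr = arr.astype(float)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] == 1:
        return arr[:, :, 0]
    if arr.ndim == 3 and arr.shape[2] == 3:
        return arr @ BT601_WEIGHTS
    nch = arr.shape[2] if arr.ndim == 3 else arr.ndim
    raise ValueError(f"unsupported channel count: {nch} (expected 1 or 3)")


def load_image(path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG raster and return a grayscale grid in [0, 1]."""
    with Image.open(path) as im:
        if im.mode not in ("L", "RGB"):
            im = im.convert("RGB")
        return to_grayscale(np.asarray(im))


def dwt2_level(x: np.ndarray, filters: FilterPair = HAAR, *, level: int = 1) -> QuadBands:
    """One level of separable 2D wavelet analysis with dyadic downsampling.

    Output grids have side length ``floor((n + 1) / 2)`` per axis
    (half-sample symmetric padding on odd sides).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("input must be a 2D grid")
    if min(x.shape) < MIN_SIDE:
        raise ValueError(f"input must be at least {MIN_SIDE}x{MIN_SIDE}; got {x.shape}")
    if not np.isfinite(x).all():
        raise ValueError("input contains non-finite values")
    wav = pywt.Wavelet(filters.name, filter_bank=(
        list(filters.lowpass), list(filters.highpass),
        list(filters.lowpass[::-1]), list(filters.highpass[::-1]),
    ))
    cA, (cH, cV, cD) = pywt.dwt2(x, wav, mode="symmetric")
    return QuadBands(level=level, A=cA, H=cH, V=cV, D=cD)


def idwt2_level(bands: QuadBands, filters: FilterPair = HAAR) -> np.ndarray:
    """Invert one analysis level (exact for even-sided original inputs)."""
    wav = pywt.Wavelet(filters.name, filter_bank=(
        list(filters.lowpass), list(filters.highpass),
        list(filters.lowpass[::-1]), list(filters.highpass[::-1]),
    ))
    return pywt.idwt2((bands.A, (bands.H, bands.V, bands.D)), wav, mode="symmetric")


def multilevel_decompose(
    image: np.ndarray, levels: int = 5, filters: FilterPair = HAAR
) -> list[QuadBands]:
    """Recursive decomposition: each level re-analyses the previous A band.

    Raises if some level's input would drop below 2x2, naming the first
    failing level.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    x = np.asarray(image, dtype=float)
    out: list[QuadBands] = []
    for j in range(1, levels + 1):
        if min(x.shape) < MIN_SIDE:
            raise ValueError(
                f"image too small for {levels} levels: level {j} input would be {x.shape}"
            )
        qb = dwt2_level(x, filters, level=j)
        out.append(qb)
        x = qb.A
    return out


def _descriptor_vectors(bands: list[QuadBands]) -> list[tuple[int, str, np.ndarray]]:
    vecs = []
    for qb in bands:
        flat = {b: qb.band(b).ravel(order="C") for b in ("A", "H", "V", "D")}
        flat["ALL"] = np.concatenate([flat["H"], flat["V"], flat["D"]])
        for b in BANDS:
            vecs.append((qb.level, b, flat[b]))
    return vecs


def build_descriptors(
    images: list[np.ndarray],
    levels: int = 5,
    filters: FilterPair = HAAR,
    *,
    band_convention: str = "stripe",
) -> list[list[WaveletDescriptor]]:
    """Per-stimulus descriptor vectors W1..W(5*levels).

    For each level the flattened A, H, V, D grids and the concatenation
    ALL = [H | V | D] are emitted, ids assigned level-major in band order
    A, H, V, D, ALL — 25 descriptors per stimulus at 5 levels.

    ``band_convention`` selects what "horizontal detail" means:
    ``"stripe"`` (default) labels H as the band maximal for horizontal
    stripes; ``"gradient"`` swaps the H and V labels (horizontal = band of
    horizontal intensity gradients, i.e. vertical edges).
    """
    if band_convention not in ("stripe", "gradient"):
        raise ValueError(f"unknown band convention: {band_convention!r}")
    shapes = {np.asarray(im).shape for im in images}
    if len(shapes) > 1:
        raise ValueError(f"all images must share one shape; got {sorted(shapes)}")
    out: list[list[WaveletDescriptor]] = []
    for im in images:
        bands = multilevel_decompose(np.asarray(im, dtype=float), levels, filters)
        if band_convention == "gradient":
            bands = [QuadBands(level=q.level, A=q.A, H=q.V, V=q.H, D=q.D) for q in bands]
        descs = [
            WaveletDescriptor(id=f"W{k + 1}", level=lvl, band=b, vector=v)
            for k, (lvl, b, v) in enumerate(_descriptor_vectors(bands))
        ]
        out.append(descs)
    return out


def descriptor_index(levels: int = 5) -> list[tuple[str, int, str]]:
    """(id, level, band) triples in emission order (W1..W25 at 5 levels)."""
    out = []
    k = 0
    for lvl in range(1, levels + 1):
        for b in BANDS:
            k += 1
            out.append((f"W{k}", lvl, b))
    return out


def save_descriptors(descriptors: list[list[WaveletDescriptor]], h5_path, manifest_path=None) -> None:
    """Write descriptors to HDF5 (`/W{k}/stimulus_{i}`) plus a CSV manifest."""
    with h5py.File(h5_path, "w") as f:
        for i, descs in enumerate(descriptors):
            for d in descs:
                f.create_dataset(f"/{d.id}/stimulus_{i}", data=d.vector)
    if manifest_path is not None:
        import csv

        with open(manifest_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "level", "band", "length"])
            for d in descriptors[0]:
                w.writerow([d.id, d.level, d.band, len(d.vector)])
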