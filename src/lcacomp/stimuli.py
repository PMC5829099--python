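"""Synthetic stimuli, raster I/O, and display-RGB <-> cone-LMS conversion.

The model operates on three aligned planes of linear cone excitations
(L, M, S).  Ordinary RGB rasters are mapped to cone planes with a fixed
invertible 3x3 matrix: linear sRGB -> CIE XYZ (D65) -> Hunt-Pointer-Estevez
cone fundamentals, row-normalized so that an equal-RGB (achromatic) pixel
yields L = M = S ("achromatic closure").  Any fixed invertible transform with
that closure property is adequate for the model; the matrix is exposed as
:data:`RGB_TO_LMS` so the convention is fully documented.

Two synthetic fixtures are provided: an achromatic grid of equal-energy
squares (for chromatic-fringe measurements) and a concentric ring pattern
in the style of the Shevell-Monnier S-cone stimulus, built in two variants
that differ only in which inducer chromaticity flanks the physically
identical test ring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "RGBImage",
    "ConeImage",
    "StimulusSpec",
    "RGB_TO_LMS",
    "LMS_TO_RGB",
    "srgb_encode",
    "srgb_decode",
    "rgb_to_cones",
    "cones_to_rgb",
    "make_grid",
    "make_ring_pattern",
    "make_uniform",
    "ring_index_map",
    "ring_mask",
    "read_image",
    "write_image",
]

# linear sRGB -> XYZ (D65), IEC 61966-2-1
_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)

# XYZ -> Hunt-Pointer-Estevez cone space (equal-energy normalized)
_XYZ_TO_HPE = np.array(
    [
        [0.38971, 0.68898, -0.07868],
        [-0.22981, 1.18340, 0.04641],
        [0.0, 0.0, 1.0],
    ]
)

_RAW = _XYZ_TO_HPE @ _SRGB_TO_XYZ
# Row-normalize so that RGB (1,1,1) maps to LMS (1,1,1): guarantees that any
# equal-RGB input produces identical L, M and S planes.
RGB_TO_LMS = _RAW / _RAW.sum(axis=1, keepdims=True)
LMS_TO_RGB = np.linalg.inv(RGB_TO_LMS)


@dataclass
class RGBImage:
    """An RGB raster with (H, W, 3) float planes in linear or encoded light."""

    data: np.ndarray
    linear: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise ValueError("RGBImage.data must have shape (H, W, 3)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("RGBImage contains non-finite values")

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    def plane(self, i: int) -> np.ndarray:
        return self.data[:, :, i]


@dataclass
class ConeImage:
    """Aligned L, M, S cone-excitation planes (linear units, non-negative)."""

    L: np.ndarray
    M: np.ndarray
    S: np.ndarray

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if not (self.L.shape == self.M.shape == self.S.shape):
            raise ValueError("cone planes must share one shape")

    @property
    def shape(self) -> tuple:
        return self.L.shape

    def planes(self) -> tuple:
        return self.L, self.M, self.S

    def stack(self) -> np.ndarray:
        return np.stack([self.L, self.M, self.S], axis=-1)


# default ring chromaticities: documented approximations of the published
# S-cone pattern (see docs/methods.md).  Linear-light RGB; the test ring sits
# near mid S/(L+M) while the inducers swing between high-S purple and low-S
# lime at roughly comparable L+M.
TEST_RGB = (0.8, 0.5, 0.6)
PURPLE_RGB = (0.5, 0.3, 0.8)
LIME_RGB = (0.6, 0.8, 0.3)


@dataclass
class StimulusSpec:
    """Parameters of a synthetic stimulus (grid, rings or uniform field)."""

    kind: str = "grid"
    size: int = 256
    square_size: int = 64
    levels: tuple = (0.9, 0.1)
    ring_width: int = 8
    n_rings: int = 13
    test_rgb: tuple = TEST_RGB
    inducer_a_rgb: tuple = PURPLE_RGB
    inducer_b_rgb: tuple = LIME_RGB
    background_rgb: tuple = (0.5, 0.5, 0.5)

    def __post_init__(self) -> None:
        if self.kind not in ("grid", "rings", "uniform"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.size <= 0 or self.square_size <= 0 or self.ring_width <= 0:
            raise ValueError("geometry must be positive")
        if self.n_rings < 1 or self.n_rings % 2 == 0:
            raise ValueError("n_rings must be a positive odd count")


def _as_rgb(level) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(level, dtype=float))
    if arr.size == 1:
        arr = np.repeat(arr, 3)
    if arr.size != 3:
        raise ValueError("chromaticity must be scalar gray or RGB triplet")
    return arr


def make_grid(spec: StimulusSpec) -> RGBImage:
    """Checkerboard grid of alternating squares of two gray levels."""
    if spec.kind != "grid":
        raise ValueError("spec.kind must be 'grid'")
    bright = _as_rgb(spec.levels[0])
    dark = _as_rgb(spec.levels[1])
    for lv in (bright, dark):
        if not (lv[0] == lv[1] == lv[2]):
            warnings.warn("non-achromatic grid level; the default fringe "
                          "fixture expects equal-energy squares")
    idx = np.arange(spec.size) // spec.square_size
    parity = (idx[:, None] + idx[None, :]) % 2
    data = np.where(parity[:, :, None] == 0, bright, dark)
    return RGBImage(data, linear=True)


def ring_index_map(spec: StimulusSpec) -> np.ndarray:
    """Ring index per pixel (0 = central disk); -1 outside the pattern."""
    if spec.n_rings * spec.ring_width > spec.size / 2:
        raise ValueError("ring widths exceed the image radius")
    c = (spec.size - 1) / 2.0
    yy, xx = np.mgrid[0:spec.size, 0:spec.size]
    r = np.hypot(yy - c, xx - c)
    idx = np.floor(r / spec.ring_width).astype(int)
    idx[idx >= spec.n_rings] = -1
    return idx


def ring_mask(spec: StimulusSpec, index: int) -> np.ndarray:
    """Boolean mask of one ring; the test ring is index ``n_rings // 2``."""
    return ring_index_map(spec) == index


def make_ring_pattern(spec: StimulusSpec, variant: str = "a") -> RGBImage:
    """Concentric square-wave ring pattern with a fixed central test ring.

    Rings alternate between the two inducer chromaticities; the two variants
    ("a" and "b") swap the inducers, so the rings immediately flanking the
    test ring carry inducer A in variant "a" and inducer B in variant "b".
    The test ring itself is pixel-identical across variants.
    """
    if spec.kind != "rings":
        raise ValueError("spec.kind must be 'rings'")
    if variant not in ("a", "b"):
        raise ValueError("variant must be 'a' or 'b'")
    primary = _as_rgb(spec.inducer_a_rgb if variant == "a" else spec.inducer_b_rgb)
    secondary = _as_rgb(spec.inducer_b_rgb if variant == "a" else spec.inducer_a_rgb)
    test = _as_rgb(spec.test_rgb)
    background = _as_rgb(spec.background_rgb)

    idx = ring_index_map(spec)
    test_idx = spec.n_rings // 2
    data = np.empty((spec.size, spec.size, 3), dtype=float)
    data[:] = background
    inside = idx >= 0
    offset = idx - test_idx
    data[inside & (offset % 2 == 1)] = primary
    data[inside & (offset % 2 == 0) & (offset != 0)] = secondary
    data[idx == test_idx] = test
    return RGBImage(data, linear=True)


def make_uniform(spec: StimulusSpec) -> RGBImage:
    data = np.empty((spec.size, spec.size, 3), dtype=float)
    data[:] = _as_rgb(spec.background_rgb)
    return RGBImage(data, linear=True)


def srgb_encode(linear: np.ndarray) -> np.ndarray:
    """Linear light -> sRGB-encoded values (IEC 61966-2-1 OETF)."""
    linear = np.clip(linear, 0.0, 1.0)
    return np.where(
        linear <= 0.0031308,
        12.92 * linear,
        1.055 * np.power(linear, 1 / 2.4) - 0.055,
    )


def srgb_decode(encoded: np.ndarray) -> np.ndarray:
    """sRGB-encoded values -> linear light (EOTF)."""
    encoded = np.asarray(encoded, dtype=float)
    return np.where(
        encoded <= 0.04045,
        encoded / 12.92,
        np.power((encoded + 0.055) / 1.055, 2.4),
    )


def rgb_to_cones(img: RGBImage) -> ConeImage:
    """Map a linear-light RGB image to L, M, S cone planes.

    The transform is the fixed matrix :data:`RGB_TO_LMS`; equal-RGB pixels
    produce identical cone planes.  Encoded (gamma) input is rejected.
    """
    if not img.linear:
        raise ValueError("rgb_to_cones requires linear-light input; "
                         "decode with srgb_decode first")
    lms = img.data @ RGB_TO_LMS.T
    lms = np.clip(lms, 0.0, None)  # matrix is non-negative-dominant; guard fp dust
    return ConeImage(lms[:, :, 0], lms[:, :, 1], lms[:, :, 2])


def cones_to_rgb(cones: ConeImage, clip: bool = True) -> RGBImage:
    """Inverse of :func:`rgb_to_cones`; out-of-gamut values are clipped."""
    rgb = cones.stack() @ LMS_TO_RGB.T
    if clip:
        rgb = np.clip(rgb, 0.0, 1.0)
    return RGBImage(rgb, linear=True)


def write_image(img: RGBImage, path, bit_depth: int | None = None,
                encode: bool = True) -> None:
    """Write an image as 8- or 16-bit PNG/TIFF.

    Linear data is sRGB-encoded by default before quantization; pass
    ``encode=False`` to store linear values directly.  ``bit_depth``
    defaults to 16 for TIFF and 8 for PNG (Pillow cannot encode 16-bit
    color PNG, so 16-bit storage goes through TIFF).
    """
    path = Path(path)
    is_png = path.suffix.lower() == ".png"
    if bit_depth is None:
        bit_depth = 8 if is_png else 16
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    if bit_depth == 16 and is_png:
        raise ValueError("16-bit color PNG is not supported; use TIFF")
    data = np.clip(img.data, 0.0, 1.0)
    if encode and img.linear:
        data = srgb_encode(data)
    maxval = 2 ** bit_depth - 1
    quant = np.round(data * maxval)
    arr = quant.astype(np.uint8 if bit_depth == 8 else np.uint16)
    iio.imwrite(path, arr)


def read_image(path, assume_encoded: bool = True) -> RGBImage:
    """Read a PNG/TIFF raster into a linear-light :class:`RGBImage`."""
    raw = iio.imread(Path(path))
    if raw.ndim == 2:
        raw = np.repeat(raw[:, :, None], 3, axis=2)
    if raw.shape[2] == 4:
        raw = raw[:, :, :3]
    if np.issubdtype(raw.dtype, np.integer):
        scale = float(np.iinfo(raw.dtype).max)
        data = raw.astype(float) / scale
    else:
        data = raw.astype(float)
    if assume_encoded:
        data = srgb_decode(data)
    return RGBImage(data, linear=True)
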