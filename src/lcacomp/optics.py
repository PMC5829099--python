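"""Simplified simulation of the retinal image under longitudinal chromatic
aberration (LCA).

The ocular refractive power varies by about two diopters across the visible
spectrum, so when the eye accommodates on mid/long wavelengths the S-cone
image is strongly defocused while the L- and M-cone images remain nearly
sharp.  Here each cone plane is blurred with a Gaussian point-spread function
whose width is proportional to that channel's defocus:

    sigma_px = k * defocus(D) * pupil_diameter(mm) * pixels_per_degree / 60

with ``k`` a single calibration constant (default 1.0).  This replaces a full
wavefront-optics simulation: the downstream model only requires a realistic,
controllable blue-channel blur, not optical fidelity.  Boundaries are handled
with reflective padding to avoid spurious border fringes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._conv import conv2_reflect
from .stimuli import ConeImage

__all__ = ["LCAParams", "PSFBank", "build_psfs", "simulate_retina"]


@dataclass
class LCAParams:
    """Defocus model of chromatic aberration.

    defocus_span
        Diopters of longitudinal chromatic aberration across the visible
        spectrum (default 2.0 D).
    s_defocus_scale
        Fraction of the span attributed to the S channel when the eye is
        focused for mid wavelengths (default 0.75, i.e. 1.5 D).
    defocus_per_channel
        Explicit (L, M, S) defocus in diopters; overrides the span/scale
        defaults when given.
    pupil_diameter_mm
        Pupil diameter in millimetres; blur radius scales linearly with it.
    pixels_per_degree
        Sampling density of the image on the retina.
    blur_calibration
        The constant ``k`` converting diopters x millimetres to a Gaussian
        sigma in pixels.
    """

    defocus_span: float = 2.0
    s_defocus_scale: float = 0.75
    defocus_per_channel: tuple | None = None
    pupil_diameter_mm: float = 3.0
    pixels_per_degree: float = 64.0
    blur_calibration: float = 1.0
    psf_model: str = "gaussian"

    def __post_init__(self) -> None:
        if self.psf_model != "gaussian":
            raise ValueError("only the gaussian PSF model is implemented")
        if self.pixels_per_degree <= 0:
            raise ValueError("pixels_per_degree must be positive")
        dL, dM, dS = self.resolved_defocus()
        if min(dL, dM, dS) < 0:
            raise ValueError("defocus must be non-negative")
        if dS < max(dL, dM):
            raise ValueError("S-channel defocus must be >= L and M defocus")

    def resolved_defocus(self) -> tuple:
        if self.defocus_per_channel is not None:
            return tuple(float(d) for d in self.defocus_per_channel)
        return (0.0, 0.0, self.defocus_span * self.s_defocus_scale)

    def sigma_pixels(self) -> tuple:
        """Gaussian blur sigma, in pixels, per cone channel."""
        k = self.blur_calibration
        return tuple(
            k * d * self.pupil_diameter_mm * self.pixels_per_degree / 60.0
            for d in self.resolved_defocus()
        )


@dataclass
class PSFBank:
    """One normalized 2-D blur kernel per cone channel (L, M, S)."""

    L: np.ndarray
    M: np.ndarray
    S: np.ndarray

    def kernels(self) -> tuple:
        return self.L, self.M, self.S


def _gaussian_psf(sigma: float) -> np.ndarray:
    if sigma <= 0:
        return np.ones((1, 1))
    radius = max(1, int(math.ceil(3.0 * sigma)))
    ax = np.arange(-radius, radius + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    kern = np.exp(-(xx ** 2 + yy ** 2) / (2.0 * sigma ** 2))
    kern[np.hypot(xx, yy) > 3.0 * sigma] = 0.0
    return kern / kern.sum()


def build_psfs(params: LCAParams) -> PSFBank:
    """Build the per-channel PSFs; zero defocus yields a unit impulse."""
    sL, sM, sS = params.sigma_pixels()
    return PSFBank(_gaussian_psf(sL), _gaussian_psf(sM), _gaussian_psf(sS))


def simulate_retina(cones: ConeImage, bank: PSFBank) -> ConeImage:
    """Blur each cone plane with its channel PSF (reflective boundaries).

    Normalized kernels plus reflective padding preserve each channel's mean,
    so overall flux is conserved.
    """
    h, w = cones.shape
    out = []
    for plane, kern in zip(cones.planes(), bank.kernels()):
        if kern.shape[0] > h or kern.shape[1] > w:
            raise ValueError("PSF support exceeds the image size")
        out.append(np.clip(conv2_reflect(plane, kern), 0.0, None))
    return ConeImage(*out)
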