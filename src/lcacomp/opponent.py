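"""Opponent receptive-field responses of retinal color-coding ganglion cells.

Two cell classes are modeled on the adapted cone planes:

* **Type I** (midget-like, spatially antagonistic): difference-of-Gaussians
  responses L+M- = L_cen - M_sur and M+L- = M_cen - L_sur, where the center
  kernel f_c has decay constant rho_cen (1 px) and the surround kernel f_s is
  three times larger (rho_sur = 3 px).  These cells respond to both
  luminance and red-green chromatic structure.

* **Type II** (small bistratified cell, coextensive): the blue-yellow signal
  S+(L+M)- integrates the per-pixel chromatic difference
  S - (L + M)/2 under a single-signed Gaussian of decay rho_s_rf (3 px).
  Because the opposing inputs share one spatial region, this channel is a
  spatial low-pass of chromatic contrast and gives a null response to any
  achromatic pattern - the property that discards the blurred-S distortion
  from form processing.

Discrete kernels use exp(-r^2 / rho^2) weights truncated at 3*rho and
renormalized to unit total weight, so uniform fields pass through convolution
unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._conv import conv2_reflect
from .adaptation import AdaptedCones

__all__ = [
    "RFGeometry",
    "CenterSurroundMaps",
    "OpponentMaps",
    "gaussian_kernel",
    "center_surround",
    "type1_responses",
    "type2_response",
    "opponent_responses",
]


@dataclass
class RFGeometry:
    """Receptive-field kernel geometry (decay constants in pixels)."""

    rho_cen: float = 1.0
    rho_sur: float = 3.0
    rho_s_rf: float = 3.0
    truncation: float = 3.0

    def __post_init__(self) -> None:
        if min(self.rho_cen, self.rho_sur, self.rho_s_rf) <= 0:
            raise ValueError("decay constants must be positive")
        if self.truncation <= 0:
            raise ValueError("truncation must be positive")

    def center_kernel(self) -> np.ndarray:
        return gaussian_kernel(self.rho_cen, self.truncation)

    def surround_kernel(self) -> np.ndarray:
        return gaussian_kernel(self.rho_sur, self.truncation)

    def s_kernel(self) -> np.ndarray:
        return gaussian_kernel(self.rho_s_rf, self.truncation)


@dataclass
class CenterSurroundMaps:
    """Center and surround integrals of the adapted L and M planes."""

    L_cen: np.ndarray
    M_cen: np.ndarray
    L_sur: np.ndarray
    M_sur: np.ndarray


@dataclass
class OpponentMaps:
    """Per-pixel responses of the three opponent cell types."""

    LplusM: np.ndarray
    MplusL: np.ndarray
    SplusLM: np.ndarray

    @property
    def shape(self) -> tuple:
        return self.LplusM.shape


def gaussian_kernel(rho: float, truncation: float = 3.0) -> np.ndarray:
    """Radially symmetric kernel exp(-r^2/rho^2), truncated and unit-sum.

    The support is the disk r <= truncation * rho (at least one pixel), and
    the discrete weights are renormalized so they sum to exactly 1.
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    radius = int(math.ceil(truncation * rho))
    ax = np.arange(-radius, radius + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    r2 = xx ** 2 + yy ** 2
    kern = np.exp(-r2 / rho ** 2)
    kern[np.sqrt(r2) > truncation * rho + 1e-12] = 0.0
    return kern / kern.sum()


def center_surround(adapted: AdaptedCones, geom: RFGeometry) -> CenterSurroundMaps:
    """Convolve the adapted L and M planes with f_c and f_s.

    Surrounds are computed from the same-named plane; the chromatic pairing
    (L-center against M-surround) is applied in :func:`type1_responses`.
    """
    fc = geom.center_kernel()
    fs = geom.surround_kernel()
    return CenterSurroundMaps(
        L_cen=conv2_reflect(adapted.L, fc),
        M_cen=conv2_reflect(adapted.M, fc),
        L_sur=conv2_reflect(adapted.L, fs),
        M_sur=conv2_reflect(adapted.M, fs),
    )


def type1_responses(maps: CenterSurroundMaps) -> tuple:
    """Difference-of-Gaussians opponent responses (L+M-, M+L-)."""
    return maps.L_cen - maps.M_sur, maps.M_cen - maps.L_sur


def type2_response(adapted: AdaptedCones, geom: RFGeometry) -> np.ndarray:
    """Coextensive S+(L+M)- response of the small bistratified cell."""
    diff = adapted.S - 0.5 * (adapted.L + adapted.M)
    return conv2_reflect(diff, geom.s_kernel())


def opponent_responses(adapted: AdaptedCones, geom: RFGeometry) -> OpponentMaps:
    """All three opponent maps from one adapted cone image."""
    lpm, mpl = type1_responses(center_surround(adapted, geom))
    return OpponentMaps(LplusM=lpm, MplusL=mpl,
                        SplusLM=type2_response(adapted, geom))
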