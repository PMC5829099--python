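"""First-order cone-signal adaptation with local and remote gain control.

Each cone plane is passed through a Naka-Rushton-style compressive
nonlinearity whose semisaturation is set jointly by the local signal and a
"remote" signal pooled over an annulus surrounding the entire receptive
field:

    sigma    = a * photo + b + c * remote
    adapted  = photo / (photo + sigma) * (photo + remote)

with a = c = 1 (equal local and remote strength) and adaptation-strength
constant b = 3 by default.  The remote signal is a weighted average of the
plane over an annulus of 35 px diameter, with exponentially decaying weights
renormalized to unit sum so that a uniform field is a fixed point
(remote == photo).  The multiplication by (photo + remote) is the
"curve-shifting" form of the underlying adaptation model; a pure
Naka-Rushton variant (``form="naka_rushton"``) is available for comparison.

All three cone channels use the identical operator, so achromatic inputs
stay achromatic after adaptation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._conv import conv2_reflect
from .stimuli import ConeImage

__all__ = [
    "AdaptationParams",
    "AdaptedCones",
    "remote_kernel",
    "compute_remote",
    "adapt_channel",
    "adapt_image",
]


@dataclass
class AdaptationParams:
    """Constants of the first-order adaptation stage.

    a, c : local and remote gain weights (1 each: equal strength).
    b : adaptation-strength constant (3).
    remote_diameter : outer diameter of the remote annulus in pixels (35).
    rho_remote : decay constant of the annulus weights; defaults to
        ``remote_diameter / 4``.
    inner_radius : inner edge of the annulus, just outside the classical
        receptive field (default 9 px = 3 * rho_sur).
    form : "curve_shift" (default) or "naka_rushton" (drops the
        (photo + remote) factor).
    """

    a: float = 1.0
    b: float = 3.0
    c: float = 1.0
    remote_diameter: int = 35
    rho_remote: float | None = None
    inner_radius: float | None = None
    form: str = "curve_shift"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("a, b, c must be non-negative")
        if self.remote_diameter < 3 or self.remote_diameter % 2 == 0:
            raise ValueError("remote_diameter must be odd and >= 3")
        if self.form not in ("curve_shift", "naka_rushton"):
            raise ValueError(f"unknown adaptation form {self.form!r}")

    @property
    def resolved_rho_remote(self) -> float:
        return self.rho_remote if self.rho_remote is not None else self.remote_diameter / 4.0

    @property
    def resolved_inner_radius(self) -> float:
        return self.inner_radius if self.inner_radius is not None else 9.0


@dataclass
class AdaptedCones:
    """Adapted L, M, S planes (outputs of :func:`adapt_image`)."""

    L: np.ndarray
    M: np.ndarray
    S: np.ndarray

    @property
    def shape(self) -> tuple:
        return self.L.shape

    def planes(self) -> tuple:
        return self.L, self.M, self.S


def remote_kernel(params: AdaptationParams) -> np.ndarray:
    """Annulus weighting kernel of the remote area, renormalized to sum 1.

    Weights follow exp(-r^2 / rho_remote^2) on the annulus
    inner_radius < r <= remote_diameter / 2 and are zero elsewhere, so the
    remote signal is a weighted mean that excludes the central RF region.
    """
    radius = params.remote_diameter // 2
    ax = np.arange(-radius, radius + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    r = np.hypot(xx, yy)
    rho = params.resolved_rho_remote
    mask = (r > params.resolved_inner_radius) & (r <= params.remote_diameter / 2.0)
    if not mask.any():
        raise ValueError("remote annulus is empty; check inner_radius/diameter")
    kern = np.where(mask, np.exp(-(r ** 2) / rho ** 2), 0.0)
    return kern / kern.sum()


def compute_remote(plane: np.ndarray, params: AdaptationParams) -> np.ndarray:
    """Weighted average of ``plane`` over the surrounding remote annulus."""
    plane = np.asarray(plane, dtype=float)
    if params.remote_diameter > min(plane.shape):
        raise ValueError("remote annulus larger than the image")
    return conv2_reflect(plane, remote_kernel(params))


def adapt_channel(photo: np.ndarray, remote: np.ndarray,
                  params: AdaptationParams) -> np.ndarray:
    """Apply the adaptation nonlinearity to one cone plane."""
    photo = np.asarray(photo, dtype=float)
    remote = np.asarray(remote, dtype=float)
    if photo.shape != remote.shape:
        raise ValueError("photo and remote must share one shape")
    if (photo < 0).any() or (remote < 0).any():
        raise ValueError("cone signals must be non-negative")
    sigma = params.a * photo + params.b + params.c * remote
    denom = photo + sigma
    gain = np.divide(photo, denom, out=np.zeros_like(photo), where=denom > 0)
    if params.form == "curve_shift":
        return gain * (photo + remote)
    return gain


def adapt_image(cones: ConeImage, params: AdaptationParams) -> AdaptedCones:
    """Channel-wise remote pooling followed by the adaptation nonlinearity."""
    out = []
    for plane in cones.planes():
        remote = compute_remote(plane, params)
        out.append(adapt_channel(plane, remote, params))
    return AdaptedCones(*out)
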