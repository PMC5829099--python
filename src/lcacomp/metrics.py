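"""Quantification of chromatic fringes and chromatic induction.

Blue-yellow deviation from neutral is measured as the per-pixel ratio of
the blue channel to the yellow channel, Y = (R+G)/2, on linear-light RGB
renderings: an achromatic pixel has contrast B/Y = 1, larger values are
bluish, smaller values yellowish.  Fringe magnitude is the maximum
|B/Y - 1| within a window around known edge positions.

Chromatic induction on the ring stimulus is reported as the difference in
mean S/(L+M) chromatic contrast of the physically identical test ring
between the two inducer variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .inverse import PerceivedImage
from .stimuli import RGBImage

__all__ = [
    "ContrastProfile",
    "InductionReport",
    "by_contrast_profile",
    "fringe_magnitude",
    "s_contrast_shift",
    "profile_to_csv",
]

_DENOM_EPS = 1e-6


@dataclass
class ContrastProfile:
    """1-D cross-section of blue-yellow chromatic contrast.

    ``values`` holds B/((R+G)/2) per position (NaN where flagged); ``valid``
    marks pixels whose denominator exceeded the guard threshold.  The
    achromatic reference level is 1.
    """

    positions: np.ndarray
    values: np.ndarray
    valid: np.ndarray
    reference: float = 1.0


@dataclass
class InductionReport:
    """Mean S/(L+M) of the test ring per variant and their absolute shift."""

    variant_a_contrast: float
    variant_b_contrast: float

    @property
    def shift(self) -> float:
        return abs(self.variant_a_contrast - self.variant_b_contrast)


def by_contrast_profile(img: RGBImage, row: int) -> ContrastProfile:
    """Per-pixel blue/yellow ratio B / ((R+G)/2) along one image row.

    Computed on linear-light values; an achromatic pixel gives exactly 1.
    Pixels with R+G below the guard threshold are flagged rather than
    silently dropped.
    """
    if not img.linear:
        raise ValueError("contrast profiles require linear-light images")
    if not 0 <= row < img.height:
        raise IndexError("row outside the image")
    r = img.data[row, :, 0]
    g = img.data[row, :, 1]
    b = img.data[row, :, 2]
    denom = 0.5 * (r + g)
    valid = denom > _DENOM_EPS
    values = np.full(img.width, np.nan)
    values[valid] = b[valid] / denom[valid]
    return ContrastProfile(positions=np.arange(img.width), values=values,
                           valid=valid)


def fringe_magnitude(profile: ContrastProfile, edge_positions,
                     window: int = 9) -> float:
    """Max |blue/yellow - 1| within +/- ``window`` pixels of the given edges."""
    dev = np.abs(profile.values - profile.reference)
    best = 0.0
    for edge in np.atleast_1d(edge_positions):
        near = np.abs(profile.positions - edge) <= window
        sel = near & profile.valid
        if sel.any():
            best = max(best, float(np.nanmax(dev[sel])))
    return best


def s_contrast_shift(perceived_a: PerceivedImage, perceived_b: PerceivedImage,
                     mask: np.ndarray,
                     denominator: str = "sum") -> InductionReport:
    """Mean S/(L+M) chromatic contrast of a masked region, per variant.

    ``denominator`` selects the convention for the yellow term: "sum"
    (L_per + M_per, default) or "mean" ((L_per + M_per)/2).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if denominator not in ("sum", "mean"):
        raise ValueError("denominator must be 'sum' or 'mean'")

    def region_contrast(p: PerceivedImage) -> float:
        if p.S_per is None:
            raise ValueError("perceived image lacks an S_per plane")
        lm = p.L_per[mask] + p.M_per[mask]
        if denominator == "mean":
            lm = lm / 2.0
        return float(np.mean(p.S_per[mask] / lm))

    return InductionReport(variant_a_contrast=region_contrast(perceived_a),
                           variant_b_contrast=region_contrast(perceived_b))


def profile_to_csv(profile: ContrastProfile, path) -> None:
    """Write a contrast profile as CSV with columns position, value, flag."""
    frame = pd.DataFrame({
        "position": profile.positions,
        "value": profile.values,
        "flag": (~profile.valid).astype(int),
    })
    frame.to_csv(Path(path), index=False)
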