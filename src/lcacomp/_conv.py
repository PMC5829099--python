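"""Shared 2-D convolution with reflective (half-sample symmetric) boundaries.

Every spatial integral in the model (receptive-field center/surround, remote
annulus, optics PSF, perceived-domain surround) goes through
:func:`conv2_reflect` so that boundary handling is identical everywhere.
All kernels in this package are radially symmetric, so convolution and
correlation coincide.
"""

from __future__ import annotations

import numpy as np
from scipy import signal


def reflect_index(i, n: int):
    """Map an out-of-range index onto [0, n) by half-sample symmetric reflection.

    Matches ``np.pad(mode="symmetric")``: ...d c b a | a b c d | d c b a...
    Works for any integer offset (multiple reflections).
    """
    j = np.asarray(i) % (2 * n)
    return np.where(j < n, j, 2 * n - 1 - j)


def conv2_reflect(plane: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Convolve ``plane`` with ``kernel`` under reflective padding.

    ``kernel`` must have odd dimensions; the output has the shape of ``plane``.
    """
    plane = np.asarray(plane, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim != 2 or kernel.shape[0] % 2 == 0 or kernel.shape[1] % 2 == 0:
        raise ValueError("kernel must be 2-D with odd dimensions")
    rh, rw = kernel.shape[0] // 2, kernel.shape[1] // 2
    if rh == 0 and rw == 0:
        return plane * kernel[0, 0]
    h, w = plane.shape
    padded = np.pad(plane, ((rh, rh), (rw, rw)), mode="symmetric")
    full = signal.convolve(padded, kernel, mode="same")
    return full[rh:rh + h, rw:rw + w]
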