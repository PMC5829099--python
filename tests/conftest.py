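"""Shared fixtures and an independent nested-loop convolution oracle."""

import numpy as np
import pytest

from lcacomp import AdaptationParams, RFGeometry, SolverSettings


def reflect(i: int, n: int) -> int:
    """Half-sample symmetric reflection of a scalar index (oracle version)."""
    j = i % (2 * n)
    return j if j < n else 2 * n - 1 - j


def conv_reflect_loop(plane: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """O(N*K) nested-loop reference for reflective-boundary convolution."""
    h, w = plane.shape
    kh, kw = kernel.shape
    rh, rw = kh // 2, kw // 2
    out = np.zeros_like(plane, dtype=float)
    for i in range(h):
        for j in range(w):
            acc = 0.0
            for a in range(kh):
                for b in range(kw):
                    si = reflect(i + a - rh, h)
                    sj = reflect(j + b - rw, w)
                    acc += kernel[a, b] * plane[si, sj]
            out[i, j] = acc
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def geom():
    return RFGeometry()


@pytest.fixture
def adapt_params():
    return AdaptationParams()


@pytest.fixture
def tight_settings():
    return SolverSettings(tol=1e-10, max_iter=20000)
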