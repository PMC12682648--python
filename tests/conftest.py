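"""Shared oracles and fixtures.

The dense-matrix oracle below builds the periodic-convolution matrix by
explicit index arithmetic (no FFTs), independently of the operator module it
is used to check.
"""

from __future__ import annotations

import numpy as np
import pytest

from mpsgp import BlurOperator, PSF, Problem, gaussian_psf


def dense_bccb(kernel: np.ndarray, n: int) -> np.ndarray:
    """Dense N x N matrix of periodic 2-D convolution with ``kernel``.

    Coefficient of x[r, s] in output pixel (p, q) is the kernel entry at
    offset (p - r, q - s) modulo n, accumulated over aliases when the
    support wraps.
    """
    w = kernel.shape[0]
    c = w // 2
    N = n * n
    mat = np.zeros((N, N))
    for p in range(n):
        for q in range(n):
            row = p * n + q
            for a in range(w):
                for b in range(w):
                    r = (p - (a - c)) % n
                    s = (q - (b - c)) % n
                    mat[row, r * n + s] += kernel[a, b]
    return mat


def random_psf(rng: np.random.Generator, max_support: int = 5) -> PSF:
    """Random normalized non-negative PSF with odd support."""
    support = int(rng.choice(np.arange(1, max_support + 1, 2)))
    kernel = rng.uniform(0.05, 1.0, size=(support, support))
    kernel /= kernel.sum()
    return PSF(kernel=kernel)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


@pytest.fixture
def small_problem(rng) -> tuple[Problem, np.ndarray]:
    """8x8 Gaussian-blur problem with a known clean image."""
    clean = rng.uniform(0.0, 255.0, size=(8, 8))
    psf = gaussian_psf(3, 1.5)
    op = BlurOperator(psf, clean.shape)
    observed = op.forward(clean)
    return Problem(op=op, observation=observed, reg_weight=0.1), clean
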