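"""Degradation model for spatially invariant blur under periodic boundary conditions.

An observed image ``y`` is modelled as ``y = A x + b + noise`` where ``A`` is
circular (block circulant with circulant blocks, BCCB) convolution with a
point-spread function (PSF) and ``b`` is an optional constant background.
Because BCCB matrices are diagonalized by the 2-D DFT, ``A`` and its adjoint
are applied in O(N log N) via the FFT instead of ever forming the N x N
matrix.

The composite deconvolution objective solved by the package is

    F(x) = 1/2 ||A x + b - y||^2 + lam * ||x||_1,   subject to x >= 0,

whose smooth part has gradient ``A^T (A x + b - y)`` and Lipschitz constant
``||A^T A||_2`` (the largest squared transfer-function magnitude).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PSF",
    "BlurOperator",
    "Problem",
    "gaussian_psf",
    "default_support",
    "apply_forward",
    "apply_adjoint",
    "grad_f",
    "objective",
    "lipschitz_constant",
]


@dataclass(frozen=True)
class PSF:
    """A normalized, non-negative blur kernel on an odd square support.

    Parameters
    ----------
    kernel:
        2-D non-negative array with odd side length; entries must sum to 1
        within 1e-12 (the operator then preserves constant images).
    variance:
        Optional Gaussian variance (pixels^2) the kernel was built from;
        purely informational for non-Gaussian kernels.
    """

    kernel: np.ndarray
    variance: float | None = None

    def __post_init__(self) -> None:
        k = np.asarray(self.kernel, dtype=float)
        if k.ndim != 2 or k.shape[0] != k.shape[1]:
            raise ValueError("PSF kernel must be a square 2-D array")
        if k.shape[0] % 2 != 1:
            raise ValueError("PSF support must be odd")
        if np.any(k < 0):
            raise ValueError("PSF entries must be non-negative")
        if abs(k.sum() - 1.0) > 1e-12:
            raise ValueError("PSF entries must sum to 1 within 1e-12")
        object.__setattr__(self, "kernel", k)

    @property
    def support(self) -> int:
        return self.kernel.shape[0]

    @property
    def is_centrosymmetric(self) -> bool:
        """True when the kernel equals its 180-degree rotation (self-adjoint A)."""
        return bool(np.allclose(self.kernel, self.kernel[::-1, ::-1], atol=1e-14))


def default_support(variance: float) -> int:
    """Odd kernel width covering +/- 3 sigma of a Gaussian of given variance."""
    if variance <= 0:
        raise ValueError("variance must be positive")
    return 2 * math.ceil(3.0 * math.sqrt(variance)) + 1


def gaussian_psf(support: int, variance: float) -> PSF:
    """Sampled, renormalized isotropic Gaussian kernel.

    ``kernel[i, j] ~ exp(-(i^2 + j^2) / (2 variance))`` on the centered integer
    grid of the given odd ``support``, normalized to unit sum.  ``support=1``
    degenerates to the identity (delta) kernel.
    """
    if support < 1 or support % 2 != 1:
        raise ValueError("support must be a positive odd integer")
    if variance <= 0:
        raise ValueError("variance must be positive")
    half = support // 2
    coords = np.arange(-half, half + 1, dtype=float)
    r2 = coords[:, None] ** 2 + coords[None, :] ** 2
    kernel = np.exp(-r2 / (2.0 * variance))
    kernel /= kernel.sum()
    return PSF(kernel=kernel, variance=float(variance))


class BlurOperator:
    """Circular 2-D convolution ``A`` held as a precomputed transfer function.

    The kernel is embedded at the grid origin with periodic wrap-around so the
    operator matches multiplication by the BCCB matrix whose first column is
    the wrapped kernel.  Forward and adjoint applications each cost two FFTs.

    ``psf`` may be a :class:`PSF` (validated, normalized) or a raw 2-D kernel
    array (odd square support, arbitrary sign) for general linear-operator
    use; the unit-sum invariants apply only to the :class:`PSF` case.
    """

    def __init__(self, psf: PSF | np.ndarray, shape: tuple[int, int]):
        if isinstance(psf, PSF):
            kernel = psf.kernel
            self.psf: PSF | None = psf
        else:
            kernel = np.asarray(psf, dtype=float)
            if kernel.ndim != 2 or kernel.shape[0] != kernel.shape[1] or kernel.shape[0] % 2 != 1:
                raise ValueError("kernel must be a square 2-D array with odd support")
            self.psf = None
        if len(shape) != 2:
            raise ValueError("shape must be (rows, cols)")
        n0, n1 = int(shape[0]), int(shape[1])
        w = kernel.shape[0]
        if w > n0 or w > n1:
            raise ValueError(f"kernel support {w} exceeds image shape {shape}")
        self.shape = (n0, n1)
        self.kernel = kernel
        embedded = np.zeros(self.shape)
        embedded[:w, :w] = kernel
        half = w // 2
        # center the kernel at index (0, 0) with periodic wrap
        embedded = np.roll(embedded, (-half, -half), axis=(0, 1))
        self.transfer = np.fft.fft2(embedded)

    @property
    def n_pixels(self) -> int:
        return self.shape[0] * self.shape[1]

    def _as_image(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 1 and x.size == self.n_pixels:
            return x.reshape(self.shape)
        if x.shape != self.shape:
            raise ValueError(f"expected image of shape {self.shape}, got {x.shape}")
        return x

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Apply ``A`` (periodic convolution with the PSF)."""
        img = self._as_image(x)
        out = np.fft.ifft2(np.fft.fft2(img) * self.transfer).real
        return out

    def adjoint(self, r: np.ndarray) -> np.ndarray:
        """Apply ``A^T`` (periodic correlation; conjugate transfer function)."""
        img = self._as_image(r)
        out = np.fft.ifft2(np.fft.fft2(img) * np.conj(self.transfer)).real
        return out

    def spectral_norm_sq(self) -> float:
        """``||A^T A||_2``: the largest squared transfer magnitude."""
        return float(np.max(np.abs(self.transfer) ** 2))


@dataclass
class Problem:
    """Bundle of operator, observation, background and regularization weight.

    Defines the composite objective ``F(x) = f(x) + lam ||x||_1`` with smooth
    part ``f(x) = 1/2 ||A x + b - y||^2`` over the non-negative orthant.
    """

    op: BlurOperator
    observation: np.ndarray
    background: float | np.ndarray = 0.0
    reg_weight: float = 0.0

    def __post_init__(self) -> None:
        y = self.op._as_image(self.observation)
        if not np.all(np.isfinite(y)):
            raise ValueError("observation must be finite")
        if self.reg_weight < 0:
            raise ValueError("reg_weight must be non-negative")
        self.observation = y
        if np.ndim(self.background) > 0:
            self.background = self.op._as_image(self.background)

    @property
    def shape(self) -> tuple[int, int]:
        return self.op.shape

    def residual(self, x: np.ndarray) -> np.ndarray:
        return self.op.forward(x) + self.background - self.observation

    def f(self, x: np.ndarray) -> float:
        """Smooth data-fidelity term ``1/2 ||A x + b - y||^2``."""
        r = self.residual(x)
        return 0.5 * float(np.vdot(r, r).real)

    def grad_f(self, x: np.ndarray) -> np.ndarray:
        """Gradient of the smooth part: ``A^T (A x + b - y)``."""
        return self.op.adjoint(self.residual(x))

    def l1(self, x: np.ndarray) -> float:
        return float(np.abs(x).sum())

    def objective(self, x: np.ndarray) -> float:
        """Composite objective ``F(x) = f(x) + lam ||x||_1``."""
        return self.f(x) + self.reg_weight * self.l1(x)

    def lipschitz_constant(self) -> float:
        return self.op.spectral_norm_sq()


# ---------------------------------------------------------------------------
# thin functional wrappers matching the operation-level API


def apply_forward(op: BlurOperator, x: np.ndarray) -> np.ndarray:
    return op.forward(x)


def apply_adjoint(op: BlurOperator, r: np.ndarray) -> np.ndarray:
    return op.adjoint(r)


def grad_f(problem: Problem, x: np.ndarray) -> np.ndarray:
    return problem.grad_f(x)


def objective(problem: Problem, x: np.ndarray) -> float:
    return problem.objective(x)


def lipschitz_constant(op: BlurOperator) -> float:
    return op.spectral_norm_sq()
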