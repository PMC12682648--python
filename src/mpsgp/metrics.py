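"""Reconstruction quality measures: RRE, PSNR and global-statistics SSIM.

PSNR uses the 8-bit peak 255 by default, so images are expected on their
native 0-255 intensity scale.  SSIM here is the *global* formula evaluated
from whole-image means, variances and covariance -- deliberately not the
sliding-window variant found in most imaging libraries, so values are not
interchangeable with windowed implementations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["MetricsReport", "rre", "psnr", "ssim", "evaluate"]

#: conventional SSIM stability constants for an 8-bit dynamic range
DEFAULT_C1 = (0.01 * 255.0) ** 2
DEFAULT_C2 = (0.03 * 255.0) ** 2


@dataclass
class MetricsReport:
    rre: float
    psnr: float
    ssim: float
    internals: dict = field(default_factory=dict)


def _pair(truth, estimate) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(truth, dtype=float)
    e = np.asarray(estimate, dtype=float)
    if t.shape != e.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {e.shape}")
    return t, e


def rre(truth, estimate) -> float:
    """Relative reconstruction error ``||estimate - truth|| / ||truth||``."""
    t, e = _pair(truth, estimate)
    denom = float(np.linalg.norm(t))
    if denom == 0:
        raise ValueError("truth image has zero norm")
    return float(np.linalg.norm(e - t)) / denom


def psnr(truth, estimate, peak: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` for identical images."""
    t, e = _pair(truth, estimate)
    mse = float(np.mean((t - e) ** 2))
    if mse == 0:
        return math.inf
    return 10.0 * math.log10(peak * peak / mse)


def ssim(truth, estimate, c1: float = DEFAULT_C1, c2: float = DEFAULT_C2) -> float:
    """Structural similarity from global image statistics (no sliding window).

    Uses population (divide-by-N) variances and covariance; the stability
    constants default to the usual ``(0.01*255)^2`` and ``(0.03*255)^2``.
    """
    return evaluate(truth, estimate, c1=c1, c2=c2).ssim


def evaluate(
    truth, estimate, c1: float = DEFAULT_C1, c2: float = DEFAULT_C2
) -> MetricsReport:
    """All three measures plus the SSIM internals in one report."""
    t, e = _pair(truth, estimate)
    mu_t = float(t.mean())
    mu_e = float(e.mean())
    var_t = float(t.var())  # population convention
    var_e = float(e.var())
    cov = float(np.mean((t - mu_t) * (e - mu_e)))
    ssim_val = ((2 * mu_t * mu_e + c1) * (2 * cov + c2)) / (
        (mu_t**2 + mu_e**2 + c1) * (var_t + var_e + c2)
    )
    return MetricsReport(
        rre=rre(t, e),
        psnr=psnr(t, e),
        ssim=float(ssim_val),
        internals={
            "mu_truth": mu_t,
            "mu_estimate": mu_e,
            "var_truth": var_t,
            "var_estimate": var_e,
            "covariance": cov,
            "c1": c1,
            "c2": c2,
        },
    )
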