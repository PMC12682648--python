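"""Synthetic ground-truth phantoms and the blur/noise degradation protocol.

Phantoms come in three flavours on the 8-bit 0-255 intensity scale:

``stars``
    isolated bright pixels on a dark background (sparse, astronomy-like);
``shapes``
    piecewise-constant rectangles and disks (natural-image-like edges);
``cells``
    soft-edged disks of varying radius and brightness (bioimage-like).

Degradation convolves the phantom with a sampled Gaussian kernel (variance
``sigma^2`` in pixels^2, the standard blur levels being 5 and 10) under
periodic boundary conditions and adds i.i.d. Gaussian noise of variance 0.01
in native intensity units.  Everything is driven by numpy's PCG64 generator,
so fixtures are bit-reproducible per seed across platforms.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .imaging_model import PSF, BlurOperator, default_support, gaussian_psf

__all__ = [
    "PhantomSpec",
    "DegradationSpec",
    "make_phantom",
    "degrade",
    "make_fixture_suite",
    "PHANTOM_KINDS",
]

PHANTOM_KINDS = ("stars", "shapes", "cells")

#: canonical blur variances (pixels^2) of the degradation protocol
STANDARD_BLUR_VARIANCES = (5.0, 10.0)
#: canonical additive-noise variance in native intensity units
STANDARD_NOISE_VARIANCE = 0.01


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a reproducible ground-truth phantom."""

    kind: str
    n: int
    seed: int = 0
    count: int | None = None
    density: float | None = None
    intensity: tuple[float, float] = (60.0, 255.0)

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; choose from {PHANTOM_KINDS}")
        if self.n < 8:
            raise ValueError("phantom side length must be at least 8")
        lo, hi = self.intensity
        if not (0 <= lo <= hi <= 255):
            raise ValueError("intensity range must satisfy 0 <= lo <= hi <= 255")

    def resolved_count(self) -> int:
        if self.count is not None:
            return int(self.count)
        if self.density is not None:
            return int(round(self.density * self.n * self.n))
        defaults = {"stars": max(5, self.n * self.n // 300), "shapes": 6, "cells": 8}
        return defaults[self.kind]


@dataclass(frozen=True)
class DegradationSpec:
    """Blur + noise protocol applied to a clean phantom.

    ``support=None`` chooses the +/- 3 sigma Gaussian support automatically;
    ``support=1`` degenerates to the identity (delta) kernel, useful as a
    blur-free control.
    """

    blur_variance: float
    noise_variance: float = STANDARD_NOISE_VARIANCE
    seed: int = 0
    support: int | None = None

    def __post_init__(self) -> None:
        if self.blur_variance <= 0:
            raise ValueError("blur_variance must be positive")
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be non-negative")


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Deterministically generate the phantom described by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    count = spec.resolved_count()
    lo, hi = spec.intensity
    img = np.zeros((n, n))
    if count == 0:
        return img

    if spec.kind == "stars":
        flat = rng.choice(n * n, size=min(count, n * n), replace=False)
        img.ravel()[flat] = rng.uniform(lo, hi, size=flat.size)
        return img

    if spec.kind == "shapes":
        yy, xx = np.mgrid[0:n, 0:n]
        for _ in range(count):
            value = rng.uniform(lo, hi)
            if rng.integers(2) == 0:  # axis-aligned rectangle
                h = int(rng.integers(n // 8, max(n // 3, n // 8 + 1)))
                w = int(rng.integers(n // 8, max(n // 3, n // 8 + 1)))
                r0 = int(rng.integers(0, n - h))
                c0 = int(rng.integers(0, n - w))
                img[r0 : r0 + h, c0 : c0 + w] = value
            else:  # disk
                r = rng.uniform(n / 12, n / 5)
                cy, cx = rng.uniform(r, n - r, size=2)
                mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
                img[mask] = value
        return np.clip(img, 0.0, hi)

    # cells: additive soft-edged disks
    yy, xx = np.mgrid[0:n, 0:n]
    for _ in range(count):
        amp = rng.uniform(lo, hi)
        r = rng.uniform(max(2.0, n / 16), n / 8)
        cy, cx = rng.uniform(0, n, size=2)
        dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        img += amp / (1.0 + np.exp((dist - r) / (0.15 * r)))
    return np.clip(img, 0.0, hi)


def degrade(clean: np.ndarray, spec: DegradationSpec) -> tuple[np.ndarray, PSF]:
    """Blur a clean image and add white Gaussian noise.

    Returns the observation together with the PSF actually used, since the
    deconvolution setting is non-blind.  Noise may push observed values
    slightly below zero; the solver's projection handles feasibility.
    """
    clean = np.asarray(clean, dtype=float)
    if np.any(clean < 0):
        raise ValueError("clean image must be non-negative")
    support = spec.support if spec.support is not None else default_support(spec.blur_variance)
    psf = gaussian_psf(support, spec.blur_variance)
    op = BlurOperator(psf, clean.shape)
    observed = op.forward(clean)
    if spec.noise_variance > 0:
        rng = np.random.default_rng(spec.seed)
        observed = observed + rng.normal(
            0.0, np.sqrt(spec.noise_variance), size=clean.shape
        )
    return observed, psf


def make_fixture_suite(
    out_dir: str | Path,
    seed: int = 42,
    n: int = 64,
    reg_weight: float = 0.05,
) -> dict:
    """Write the standard degraded/clean fixture set plus a JSON manifest.

    Three phantom kinds x two blur variances (5 and 10 pixels^2) at noise
    variance 0.01, plus one delta-kernel (blur-free, noise-free) control per
    kind.  Per-case seeds are derived deterministically from ``seed``.
    """
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, kind in enumerate(PHANTOM_KINDS):
        pspec = PhantomSpec(kind=kind, n=n, seed=seed + 10 * i)
        clean = make_phantom(pspec)
        clean_name = f"clean_{kind}.tif"
        tifffile.imwrite(out / clean_name, clean.astype(np.float32))
        for j, blur_var in enumerate(STANDARD_BLUR_VARIANCES):
            dspec = DegradationSpec(
                blur_variance=blur_var,
                noise_variance=STANDARD_NOISE_VARIANCE,
                seed=seed + 10 * i + j + 1,
            )
            observed, psf = degrade(clean, dspec)
            obs_name = f"blurred_{kind}_s{int(blur_var)}.tif"
            psf_name = f"psf_s{int(blur_var)}.tif"
            tifffile.imwrite(out / obs_name, observed.astype(np.float32))
            tifffile.imwrite(out / psf_name, psf.kernel.astype(np.float32))
            entries.append(
                {
                    "kind": kind,
                    "clean": clean_name,
                    "observed": obs_name,
                    "psf": psf_name,
                    "phantom_spec": asdict(pspec),
                    "degradation_spec": asdict(dspec),
                    "psf_support": psf.support,
                    "reg_weight": reg_weight,
                }
            )
        # delta-kernel control: observed == clean exactly
        control = DegradationSpec(
            blur_variance=STANDARD_BLUR_VARIANCES[0],
            noise_variance=0.0,
            seed=seed + 10 * i,
            support=1,
        )
        obs_c, psf_c = degrade(clean, control)
        ctrl_name = f"control_{kind}.tif"
        tifffile.imwrite(out / ctrl_name, obs_c.astype(np.float32))
        entries.append(
            {
                "kind": kind,
                "clean": clean_name,
                "observed": ctrl_name,
                "psf": None,
                "phantom_spec": asdict(pspec),
                "degradation_spec": asdict(control),
                "psf_support": psf_c.support,
                "reg_weight": 0.0,
            }
        )
    manifest = {
        "prng": "numpy PCG64 (default_rng)",
        "seed": seed,
        "n": n,
        "blur_variances": list(STANDARD_BLUR_VARIANCES),
        "noise_variance": STANDARD_NOISE_VARIANCE,
        "intensity_scale": "native 0-255",
        "entries": entries,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
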