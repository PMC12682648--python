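# mpsgp — momentum proximal scaled gradient projection deconvolution

`mpsgp` restores blurred, noisy grayscale images — microscopy frames,
astronomical exposures, CT slices — by solving the non-negative
ℓ1-regularized deconvolution problem

```
min_x  F(x) = 1/2 ‖A x − y‖² + λ‖x‖₁    subject to  x ≥ 0,
```

where `y` is the observed image, `A` is convolution with a known
point-spread function (PSF) under periodic boundary conditions (a BCCB
matrix, applied in O(N log N) by FFT), and λ trades data fidelity against
sparsity. It is aimed at imaging scientists who know their PSF (non-blind
deconvolution) and want a fast first-order solver with reproducible
synthetic benchmarks.

## The algorithm

The core solver is **M-PSGP**, a momentum-accelerated proximal *scaled*
gradient projection method. Each iteration:

1. **Scaled prox-projection.** With diagonal scaling
   `D_k = diag(min(L, max(1/L, x_k)))`, take
   `y_kᵖ = Π≥0[ prox_{αλ‖·‖₁}^{D⁻¹}(x_k − α_k D_k ∇f(x_k)) ]` —
   componentwise soft-thresholding followed by clamping to the orthant.
2. **Adaptive step size.** `α_k` comes from partitioned Barzilai–Borwein
   rules: indices that are zero with `−∇f` inside the subdifferential band
   `[−λ, λ]` (the set `J_k`, optimally zero) are excluded from the curvature
   estimate. The **BB2\*** rule drops the `z_J` term from the scaled BB2
   denominator (a provably larger step), and the **SS\*** rule switches to
   BB1 whenever `BB1/BB2* < τ` (τ = 0.15).
3. **Momentum.** A unified momentum framework with parameters `(η, s)`
   covering heavy-ball (`s = 0`), Nesterov (`s = 1`) and an accelerated
   gradient form (`s = 1/(1−η)`): the extrapolated point
   `m_k = x_k − s α_k D_k ∇f(x_k)` yields the momentum carrier
   `v_k = Π≥0(m_k − m_{k−1})` and the candidate `y_k = y_kᵖ + η v_k`.
4. **Nonmonotone Armijo line search.** Along `d_k = y_k − x_k`, accept the
   first `β^w` (β = 0.95, θ = 1e−4) with
   `F(x_k + β^w d_k) ≤ F_max + θ β^w Δ_k`, where `F_max` is the maximum of
   the last `M = 10` composite values and
   `Δ_k = ∇f(x_k)ᵀd_k + λ(‖x_k + d_k‖₁ − ‖x_k‖₁) < 0` is the composite
   slope guaranteed negative by prox optimality.

Momentum-free runs (`η = 0`) give the SGP\* baseline; classical rule tokens
(`bb1`, `bb2`, `ss-approx`) give plain SGP; a constant-step FISTA baseline
is included for comparison. Quality is scored by RRE, PSNR (255 peak) and a
global-statistics SSIM, and a synthetic-data module generates seeded
phantoms (sparse stars, piecewise-constant shapes, soft-edged cells)
degraded by Gaussian blur (σ² ∈ {5, 10} pixels²) plus white Gaussian noise
(variance 0.01 in native 8-bit intensity units).

## Worked example

```python
import numpy as np
from mpsgp import (BlurOperator, DegradationSpec, PhantomSpec, Problem,
                   SolverConfig, degrade, evaluate, make_phantom,
                   mpsgp_solve, psnr)

clean = make_phantom(PhantomSpec(kind="cells", n=64, seed=42))
observed, psf = degrade(clean, DegradationSpec(blur_variance=5.0,
                                               noise_variance=0.01, seed=43))
problem = Problem(op=BlurOperator(psf, observed.shape),
                  observation=observed, reg_weight=0.05)
result = mpsgp_solve(problem, SolverConfig(lam=0.05), truth=clean)

print(f"iterations: {result.niter} (stop: {result.stop_reason})")
print(f"objective F: {result.trace[0].F:.1f} -> {result.trace[-1].F:.1f}")
rep = evaluate(clean, result.x)
print(f"blurred input PSNR: {psnr(clean, observed):.2f} dB")
print(f"restored PSNR: {rep.psnr:.2f} dB, SSIM: {rep.ssim:.4f}, RRE: {rep.rre:.4f}")
```

prints

```
iterations: 200 (stop: max_iter)
objective F: 5037208.2 -> 6281.5
blurred input PSNR: 23.98 dB
restored PSNR: 32.27 dB, SSIM: 0.9947, RRE: 0.0920
```

The restoration gains about 8 dB over the blurred input: the objective
drops three orders of magnitude while the iterate stays non-negative, and
the final image recovers the cell bodies that blur plus noise had merged.
`result.trace_frame()` returns the per-iteration diagnostics (objective,
step size, rule fired, backtracks, stationarity residual, RRE) as a
DataFrame.

The same pipeline is available from the shell:

```bash
deblur simulate --kind cells --n 64 --blur-sigma2 5 --noise-var 0.01 \
    --seed 42 --out-dir fixtures/
deblur run --input fixtures/blurred.tif --psf-file fixtures/psf.tif \
    --lam 0.05 --out restored.tif --trace trace.csv --truth fixtures/clean.tif
deblur metrics --truth fixtures/clean.tif --estimate restored.tif
```

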