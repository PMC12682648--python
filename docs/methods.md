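# Methods

## Model and assumptions

The degradation model is `y = A x + b + ε` with `x ≥ 0` the unknown image,
`A` spatially invariant convolution with a known, normalized, non-negative
PSF under **periodic boundary conditions** (BCCB structure; reflective or
zero-padded boundaries are deliberately not implemented), `b` an optional
constant background (default 0), and `ε` i.i.d. Gaussian noise. Under a
Gaussian likelihood and a Laplacian sparsity prior, the MAP estimate solves

    min_x  F(x) = 1/2 ‖A x + b − y‖² + λ‖x‖₁,   x ≥ 0.

`F` is convex; the smooth part has gradient `Aᵀ(Ax + b − y)` and Lipschitz
constant `‖AᵀA‖₂`, which equals exactly 1 for any unit-sum non-negative PSF
(the DC eigenvalue dominates). Images are processed on their **native
intensity scale** (0–255 for 8-bit input); PSNR assumes the 255 peak, and
no internal rescaling is performed.

A feasible point is stationary iff it is a fixed point of the
prox-projected gradient map; the solver's stopping measure is the relative
residual `‖x − T(x)‖ / max(1, ‖x‖)` of that map, with the `max(1, ·)` floor
for stability near the origin.

## Solver parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `alpha0` | 1.3 | — | first-iteration step before BB history exists |
| `alpha_min`, `alpha_max` | 1e−10, 1e5 | — | BB clamping band; degenerate BB values fall back to `alpha_max`, trusting the line search to shorten them |
| `tau` | 0.15 | — | SS* switching threshold on BB1/BB2* |
| `theta`, `beta` | 1e−4, 0.95 | — | Armijo sufficient-decrease weight and backtracking ratio |
| `memory` | 10 | iterations | nonmonotone window (standard choice in that literature) |
| `scale_bound` (L) | 10 | intensity | see below |
| `eta`, `variant` | 0.5, `nag` | — | momentum weight and flavour; `eta` is the knob users should tune per image class (see the momentum section) |
| `max_iter`, `tol` | 200, 1e−6 | — | fixed-budget protocol with optional early stop |
| `max_backtracks` | 50 | — | safeguard; exhausting it takes an `alpha_min` micro-step and flags the iteration as anomalous in the trace |
| `lam` | required | intensity | never defaulted: the right λ depends on noise level and image sparsity; the synthetic fixtures use 0.05 |

**Choice of the scaling bound.** The scaling `d_i = min(L, max(1/L, x_i))`
damps steps on dark/sparse pixels and caps preconditioning on bright ones.
`L` interacts with the line search: the first trial step on 8-bit-scale
images is accepted near `t ≈ 2/(alpha0·L)`, so the worst-case backtrack
count is roughly `ln(2/(alpha0·L))/ln(beta)` — about 37 for `L = 10`,
comfortably inside the safeguard, whereas `L ≥ 100` would overflow it on
the very first iteration. Hence the default `L = 10`.

## Line search: composite slope

The direction `d_k = y_k − x_k` produced by the prox-projection step is
**not** in general a descent direction of the smooth part alone when
`λ > 0`: soft-thresholding may move components against `∇f` while still
decreasing `F` (a one-line counterexample: `x = 1`, `∇f = −0.1`, threshold
0.5 moves the iterate down). What prox optimality does guarantee is
negativity of the composite slope

    Δ_k = ∇f(x_k)ᵀ d_k + λ(‖x_k + d_k‖₁ − ‖x_k‖₁) ≤ −(1/2α_k)‖d_k‖²_{D⁻¹},

so the backtracking test is taken on `F` against the nonmonotone reference
`F_max` with slope `Δ_k`. For `λ = 0` this reduces exactly to the classical
smooth nonmonotone Armijo rule, and in that projection-only regime the
smooth slope `∇fᵀd` is itself provably negative (the test suite asserts
both forms in their respective regimes). Convexity of `‖·‖₁` gives
`F(x + t d) ≤ F(x) + t Δ + O(t²)`, so the search terminates finitely on
every descent direction.

When the momentum correction spoils descent (`Δ ≥ 0` along `y_k − x_k`),
the solver falls back to the pre-momentum direction `y_kᵖ − x_k`, which is
always safe; the event is recorded in the trace.

## Momentum: what it does and does not buy

The unified momentum recursion is implemented exactly as specified
(extrapolated point, positive-part projected difference, `η`-weighted
correction), with a `momentum_projection="none"` switch to measure the
effect of the projection. Two structural properties matter in practice:

- for `s > 0` the carrier `v_k = Π≥0(m_k − m_{k−1})` contains
  `s(α_k D_k ∇f(x_k) − α_{k−1} D_{k−1} ∇f(x_{k−1}))`; BB step sizes
  fluctuate by design and `∇f ≠ 0` at a regularized stationary point, so
  this term does **not** vanish as the iterates converge;
- the positive-part projection injects only non-negative mass
  (`E[max(noise, 0)] > 0`), which slows the sparsification of dark
  backgrounds.

Consequently, on the 64×64 synthetic suite — where the momentum-free SGP*
run approaches stationarity within the 200-iteration budget — momentum does
not improve the final reconstruction (the acceptance script reports both
M-PSGP and SGP* errors side by side; the test suite records this
comparison as a known failure of the momentum variant at this scale).
Momentum is most useful far from convergence; heavy-ball (`s = 0`) with
small `η` is the most robust variant on sparse images because its carrier
is built purely from iterate differences, which do vanish. Users targeting
reconstruction quality at small problem sizes should run `sgp_star_solve`
or set `eta = 0`.

## Synthetic data

Phantoms are generated on the 0–255 scale by numpy's PCG64 generator
(recorded in the fixture manifest), in three flavours: `stars` (exact
isolated bright pixels — sparse, astronomy-like), `shapes`
(piecewise-constant rectangles/disks — edge-dominated), `cells`
(soft-edged sigmoid-profile disks — bioimage-like). Degradation convolves
with a sampled Gaussian kernel of variance σ² ∈ {5, 10} pixels² (support
truncated at ±3σ and renormalized, capturing > 99% of the mass) and adds
white Gaussian noise of **variance 0.01 in native intensity units**
(σ = 0.1 grey levels): with the 255 peak this is the blur-dominated regime
in which PSNRs in the 20–40 dB range are attainable, which is what the
measured restorations produce; a variance of 0.01 on a [0, 1]-normalized
scale would mean σ ≈ 25.5 grey levels and a noise-dominated problem
instead. The generator returns the PSF actually used (non-blind setting).

What the phantoms do *not* emulate: natural-image texture, correlated or
signal-dependent (Poisson) noise, saturation and quantization, boundary
effects of non-periodic optics. Passing tests therefore demonstrate
correctness of the operators and solver dynamics on controlled,
well-specified inputs, not restoration quality on real micrographs.

Problem sizes: unit tests use 4×4 to 32×32 grids (dense-matrix oracles are
exact there); the solver study and acceptance script use the 64×64 suite
with the full 200-iteration protocol, which keeps a complete run in
seconds while leaving each case measurably under-resolved (RRE of the
blurred input is 0.3–1.0).

## Numerical choices

- **Prox metric.** The prox is taken in the `D⁻¹` metric, giving the exact
  componentwise closed form `sign(u)·max(|u| − αλ d_i, 0)`; a 1-D
  golden-section oracle pins this interpretation in the tests. Thresholding
  writes exact zeros, so the active-set partition uses `zero_tol = 0` by
  default.
- **Order of prox and projection.** Prox first, projection second; for this
  separable problem the composition is componentwise order-insensitive
  (asserted by a test).
- **BB scaling ambiguity.** The BB1 denominator is read with the inverse of
  the *current* scaling matrix (`bb1_scaling="inverse"`); the alternative
  reading with the previous iteration's matrix is available as
  `bb1_scaling="previous"`.
- **Degenerate BB values.** Non-positive numerators/denominators or an
  empty active set make a rule undefined; the selector then uses the other
  branch of a switching rule if defined, else `alpha_max`.
- **SS approximation.** The classical alternating rule of the original SGP
  is not fully specified here; the implemented `ss-approx` token applies
  the same τ-switch to the unpartitioned (BB1, BB2) pair and is labelled an
  approximation.
- **Momentum initialization.** `m_{−1} = m_0`, so the first step carries no
  momentum (no history exists).
- **Stationarity detection.** Exact equality `y_kᵖ = x_k` (or a
  non-negative composite slope, which prox optimality permits only at
  machine precision) stops the run as stationary; otherwise the
  residual-based criterion governs.
- **Divergence guard.** If `F` exceeds ten times its starting value the run
  aborts with a diagnostic rather than continuing silently.
- **Feasibility.** Accepted candidates are clamped to the orthant; since
  `x_k` and `x_k + d_k` are both feasible and the step length is in (0, 1],
  this only removes floating-point dust.

## Known limitations

- Periodic boundaries only; real optics are not periodic, and bright
  structure near the frame edge will wrap.
- Single-channel 2-D images; no color, no z-stacks, no spatially varying
  PSF, no blind deconvolution.
- Gaussian noise model only; Poisson or mixed noise would need a different
  fidelity term.
- The global (non-windowed) SSIM implemented here follows the whole-image
  statistics formula and is **not** comparable to the sliding-window SSIM
  of standard imaging libraries.
- λ must be supplied by the user; no automatic selection (discrepancy
  principle, cross-validation) is provided.
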