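"""Momentum-accelerated proximal scaled gradient projection (M-PSGP) solver,
with scaled-gradient-projection (SGP) and FISTA baselines.

One M-PSGP iteration on ``min F(x) = 1/2||Ax + b - y||^2 + lam ||x||_1``
subject to ``x >= 0``:

1. build the diagonal scaling ``D_k`` from the current iterate;
2. pick the step ``alpha_k`` by the configured BB-type rule (partitioned
   BB2*/SS* by default), clamped to ``[alpha_min, alpha_max]``;
3. prox-projected gradient step ``y_k^p``;
4. momentum correction: extrapolated point ``m_k``, projected difference
   ``v_k``, candidate ``y_k = y_k^p + eta v_k``;
5. descent direction ``d_k = y_k - x_k``, falling back to the pre-momentum
   direction when the momentum correction spoils descent;
6. nonmonotone Armijo backtracking over ``beta^w``, then
   ``x_{k+1} = x_k + beta^w d_k``.

Line-search slope.  For the composite objective the correct directional
surrogate is

    Delta_k = grad f(x_k)^T d_k + lam * (||x_k + d_k||_1 - ||x_k||_1),

which prox optimality bounds by ``-(1/2 alpha_k) ||d_k||^2_{D^-1} < 0``
whenever ``y_k^p != x_k``; the smooth slope ``grad f^T d`` alone carries that
guarantee only when ``lam = 0`` (the projection-only setting), since l1
shrinkage may move components against the smooth gradient.  The backtracking
test is therefore taken on ``F`` against the maximum of the last ``M``
composite values,

    F(x_k + beta^w d_k) <= F_max + theta * beta^w * Delta_k,

which reduces exactly to the classical smooth nonmonotone Armijo rule when
``lam = 0``.

The iteration stops when the relative stationarity residual of the
prox-projected gradient map drops below ``tol`` or after ``max_iter``
iterations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .imaging_model import Problem, lipschitz_constant
from .momentum import (
    MomentumConfig,
    apply_momentum,
    intermediate_point,
    momentum_vector,
)
from .proximal_ops import (
    ScalingDiag,
    identity_scaling,
    prox_project_step,
    scaled_prox_l1,
)
from .step_rules import (
    StepHistory,
    partition_indices,
    scaling_matrix,
    select_step_size,
)

__all__ = [
    "SolverConfig",
    "SolverState",
    "TraceRecord",
    "SolveResult",
    "DivergenceError",
    "initial_point",
    "nonmonotone_armijo",
    "mpsgp_step",
    "mpsgp_solve",
    "sgp_star_solve",
    "fista_solve",
    "fista_t_sequence",
    "trace_frame",
    "init_state",
]

TRACE_COLUMNS = ["iter", "F", "f", "alpha", "rule_used", "w", "stationarity", "rre"]


class DivergenceError(RuntimeError):
    """Raised when the objective blows past ten times its starting value."""


@dataclass
class SolverConfig:
    """All scalars of the M-PSGP iteration.

    Defaults follow the standard experimental protocol for 8-bit-scale
    images: ``alpha0 = 1.3``, step bounds ``[1e-10, 1e5]``, switching
    threshold ``tau = 0.15``, Armijo parameters ``theta = 1e-4`` and
    ``beta = 0.95``, nonmonotone memory ``M = 10``, 200 iterations.
    """

    lam: float
    alpha0: float = 1.3
    alpha_min: float = 1e-10
    alpha_max: float = 1e5
    tau: float = 0.15
    theta: float = 1e-4
    beta: float = 0.95
    eta: float = 0.5
    s: float | None = None
    variant: str = "nag"
    scale_bound: float = 10.0
    memory: int = 10
    max_iter: int = 200
    tol: float = 1e-6
    max_backtracks: int = 50
    rule: str = "ssstar"
    zero_tol: float = 0.0
    bb1_scaling: str = "inverse"
    momentum_projection: str = "difference"

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be non-negative")
        if not (0 < self.alpha_min < self.alpha0 < self.alpha_max):
            raise ValueError("need 0 < alpha_min < alpha0 < alpha_max")
        if not (0 < self.beta < 1):
            raise ValueError("beta must lie in (0, 1)")
        if not (0 < self.theta < 1):
            raise ValueError("theta must lie in (0, 1)")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.memory < 1:
            raise ValueError("memory must be at least 1")
        if self.scale_bound <= 1:
            raise ValueError("scale_bound must exceed 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        if self.max_backtracks < 1:
            raise ValueError("max_backtracks must be at least 1")

    def momentum(self) -> MomentumConfig:
        return MomentumConfig.resolve(self.variant, self.eta, self.s)


@dataclass
class TraceRecord:
    """Per-iteration diagnostics; one record per accepted step."""

    k: int
    F: float
    f: float
    alpha: float
    rule_used: str
    w: int
    stationarity: float
    rre: float | None = None
    # extra diagnostics used by the invariant checks
    delta: float = math.nan  # composite slope along the accepted direction
    delta_pre: float = math.nan  # composite slope along the pre-momentum direction
    gTd: float = math.nan  # smooth slope along the accepted direction
    gTd_pre: float = math.nan  # smooth slope along the pre-momentum direction
    F_max: float = math.nan  # nonmonotone reference value
    e_norm: float = math.nan  # ||m_k - x_k||
    grad_norm: float = math.nan
    fallback_direction: bool = False
    safeguard: bool = False


@dataclass
class SolverState:
    """Mutable per-iteration state of the M-PSGP loop."""

    x: np.ndarray
    grad: np.ndarray
    k: int = 0
    history: StepHistory | None = None
    m_prev: np.ndarray | None = None
    D_prev: ScalingDiag | None = None
    obj_window: list[float] = field(default_factory=list)
    F0: float = math.nan


@dataclass
class SolveResult:
    """Final iterate plus the full iteration trace."""

    x: np.ndarray
    trace: list[TraceRecord]
    converged: bool
    stop_reason: str

    @property
    def niter(self) -> int:
        return len(self.trace)

    def trace_frame(self) -> pd.DataFrame:
        return trace_frame(self.trace)

    def __iter__(self):
        # allow ``x, trace = solve(...)`` tuple-style unpacking
        yield self.x
        yield self.trace


def trace_frame(trace: list[TraceRecord]) -> pd.DataFrame:
    """Convergence trace as a DataFrame with the canonical column set."""
    rows = [
        {
            "iter": t.k,
            "F": t.F,
            "f": t.f,
            "alpha": t.alpha,
            "rule_used": t.rule_used,
            "w": t.w,
            "stationarity": t.stationarity,
            "rre": np.nan if t.rre is None else t.rre,
        }
        for t in trace
    ]
    return pd.DataFrame(rows, columns=TRACE_COLUMNS)


def initial_point(y: np.ndarray) -> np.ndarray:
    """Constant starting image: every component equals ``mean(y)``."""
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("observation is empty")
    return np.full_like(y, y.mean())


class ArmijoResult(NamedTuple):
    w: int
    x_new: np.ndarray
    F_new: float
    safeguard: bool


def nonmonotone_armijo(
    problem: Problem,
    x: np.ndarray,
    d: np.ndarray,
    slope: float,
    ref_max: float,
    theta: float,
    beta: float,
    max_backtracks: int,
    safeguard_step: float = 1e-10,
) -> ArmijoResult:
    """Generalized nonmonotone backtracking line search on the composite ``F``.

    Finds the smallest integer ``w >= 0`` with
    ``F(x + beta^w d) <= ref_max + theta * beta^w * slope`` where ``ref_max``
    is the maximum of the last ``M`` composite values and ``slope`` is the
    composite directional surrogate ``Delta`` (for ``lam = 0`` this is the
    classical smooth rule with ``slope = grad^T d``).  Descent directions
    (``slope < 0``) terminate in finitely many trials; if ``max_backtracks``
    is exceeded anyway (an anomaly worth flagging) the tiny
    ``safeguard_step`` is taken instead.  Candidates are clamped to the
    orthant, which only removes floating-point dust since ``x`` and
    ``x + d`` are both feasible.
    """
    if slope >= 0:
        raise ValueError("line search requires a descent direction (slope < 0)")
    x = np.asarray(x, dtype=float)
    d = np.asarray(d, dtype=float)
    step = 1.0
    for w in range(max_backtracks + 1):
        cand = np.maximum(x + step * d, 0.0)
        F_cand = problem.objective(cand)
        if F_cand <= ref_max + theta * step * slope:
            return ArmijoResult(w=w, x_new=cand, F_new=F_cand, safeguard=False)
        step *= beta
    cand = np.maximum(x + safeguard_step * d, 0.0)
    return ArmijoResult(
        w=max_backtracks, x_new=cand, F_new=problem.objective(cand), safeguard=True
    )


def init_state(problem: Problem, config: SolverConfig, x0: np.ndarray | None) -> SolverState:
    x = initial_point(problem.observation) if x0 is None else np.maximum(
        np.asarray(x0, dtype=float), 0.0
    )
    x = problem.op._as_image(x)
    F0 = problem.objective(x)
    return SolverState(x=x, grad=problem.grad_f(x), obj_window=[F0], F0=F0)


def mpsgp_step(
    problem: Problem,
    config: SolverConfig,
    state: SolverState,
    truth: np.ndarray | None = None,
) -> tuple[TraceRecord | None, str | None]:
    """Advance the state by one M-PSGP iteration.

    Returns ``(record, stop_reason)``; ``record`` is ``None`` only when the
    iterate was recognized as stationary before taking a step (the
    prox-projected gradient map returned the iterate itself).
    """
    mc = config.momentum()
    x, g = state.x, state.grad
    lam = config.lam

    D = scaling_matrix(x, config.scale_bound)
    part = partition_indices(x, g, lam, config.zero_tol)

    if state.history is None:
        alpha, rule_used = config.alpha0, "A0"
    else:
        alpha, rule_used = select_step_size(
            config.rule,
            state.history,
            D,
            part,
            tau=config.tau,
            alpha_min=config.alpha_min,
            alpha_max=config.alpha_max,
            bb1_scaling=config.bb1_scaling,
            D_prev=state.D_prev,
        )

    y_p = prox_project_step(x, alpha, D, g, lam)
    m = intermediate_point(x, alpha, D, g, mc.s)
    if state.m_prev is None:
        state.m_prev = m  # v_0 = 0: no momentum before history exists
    v = momentum_vector(m, state.m_prev, config.momentum_projection)
    y = apply_momentum(y_p, v, mc.eta)
    e_norm = float(np.linalg.norm(m - x))

    l1_x = problem.l1(x)
    gTd_pre = float(np.vdot(g, y_p - x).real)
    delta_pre = gTd_pre + lam * (problem.l1(y_p) - l1_x)
    if np.array_equal(y_p, x) or delta_pre >= 0:
        # prox optimality forces delta_pre <= -(1/2a)||y_p - x||^2_{D^-1};
        # a non-negative value means y_p == x to machine precision
        return None, "stationary"

    d = y - x
    gTd = float(np.vdot(g, d).real)
    delta = gTd + lam * (problem.l1(y) - l1_x)
    fallback_dir = False
    if delta >= 0:
        # momentum spoiled descent; revert to the pre-momentum direction
        d = y_p - x
        gTd, delta = gTd_pre, delta_pre
        fallback_dir = True

    F_max = max(state.obj_window)
    ls = nonmonotone_armijo(
        problem,
        x,
        d,
        delta,
        F_max,
        config.theta,
        config.beta,
        config.max_backtracks,
        safeguard_step=config.alpha_min,
    )
    x_new, F_new = ls.x_new, ls.F_new
    g_new = problem.grad_f(x_new)

    mapped = prox_project_step(x_new, alpha, D, g_new, lam)
    resid = float(np.linalg.norm(x_new - mapped)) / max(
        1.0, float(np.linalg.norm(x_new))
    )
    if F_new > 10.0 * state.F0 and F_new > state.F0:
        raise DivergenceError(
            f"objective diverged at iteration {state.k}: "
            f"F = {F_new:.6g} > 10 x F(x0) = {10 * state.F0:.6g}"
        )

    record = TraceRecord(
        k=state.k,
        F=F_new,
        f=F_new - lam * problem.l1(x_new),
        alpha=alpha,
        rule_used=rule_used,
        w=ls.w,
        stationarity=resid,
        rre=None
        if truth is None
        else float(np.linalg.norm(x_new - truth) / np.linalg.norm(truth)),
        delta=delta,
        delta_pre=delta_pre,
        gTd=gTd,
        gTd_pre=gTd_pre,
        F_max=F_max,
        e_norm=e_norm,
        grad_norm=float(np.linalg.norm(g)),
        fallback_direction=fallback_dir,
        safeguard=ls.safeguard,
    )

    state.history = StepHistory(s_prev=x_new - x, z_prev=g_new - g, alpha_prev=alpha)
    state.D_prev = D
    state.m_prev = m
    state.obj_window.append(F_new)
    if len(state.obj_window) > config.memory:
        del state.obj_window[: len(state.obj_window) - config.memory]
    state.x = x_new
    state.grad = g_new
    state.k += 1

    stop = "converged" if resid <= config.tol else None
    return record, stop


def mpsgp_solve(
    problem: Problem,
    config: SolverConfig,
    x0: np.ndarray | None = None,
    truth: np.ndarray | None = None,
) -> SolveResult:
    """Run the full M-PSGP loop and return the final iterate plus trace."""
    state = init_state(problem, config, x0)
    trace: list[TraceRecord] = []
    stop_reason = "max_iter"
    converged = False
    for _ in range(config.max_iter):
        record, stop = mpsgp_step(problem, config, state, truth=truth)
        if record is not None:
            trace.append(record)
        if stop is not None:
            stop_reason = stop
            converged = True
            break
    return SolveResult(x=state.x, trace=trace, converged=converged, stop_reason=stop_reason)


def sgp_star_solve(
    problem: Problem,
    config: SolverConfig,
    x0: np.ndarray | None = None,
    truth: np.ndarray | None = None,
) -> SolveResult:
    """M-PSGP with momentum disabled (the SGP* baseline).

    With ``rule`` set to ``'bb1'``, ``'bb2'`` or ``'ss-approx'`` this is the
    plain SGP baseline under the corresponding classical step rule.
    """
    quiet = replace(config, eta=0.0, s=None, variant="none")
    return mpsgp_solve(problem, quiet, x0=x0, truth=truth)


def fista_t_sequence(n: int) -> list[float]:
    """First ``n`` values of the FISTA extrapolation sequence, ``t_1 = 1``."""
    ts = [1.0]
    while len(ts) < n:
        ts.append((1.0 + math.sqrt(1.0 + 4.0 * ts[-1] ** 2)) / 2.0)
    return ts[:n]


def fista_solve(
    problem: Problem,
    config: SolverConfig,
    x0: np.ndarray | None = None,
    truth: np.ndarray | None = None,
) -> SolveResult:
    """Constant-step FISTA baseline with step ``1/L``.

    The composite prox of ``lam||.||_1 + indicator(x >= 0)`` is the one-sided
    shrinkage ``max(u - lam/L, 0)``, i.e. soft-thresholding composed with the
    orthant projection.
    """
    L = lipschitz_constant(problem.op)
    step = 1.0 / L
    lam = config.lam
    x = initial_point(problem.observation) if x0 is None else np.maximum(
        np.asarray(x0, dtype=float), 0.0
    )
    x = problem.op._as_image(x)
    z = x.copy()
    t = 1.0
    eye = identity_scaling(x.shape)
    trace: list[TraceRecord] = []
    converged = False
    stop_reason = "max_iter"
    for k in range(config.max_iter):
        g = problem.grad_f(z)
        x_new = np.maximum(z - step * g - step * lam, 0.0)
        t_new = (1.0 + math.sqrt(1.0 + 4.0 * t * t)) / 2.0
        z = x_new + ((t - 1.0) / t_new) * (x_new - x)
        g_new = problem.grad_f(x_new)
        mapped = np.maximum(
            scaled_prox_l1(x_new - step * g_new, step, lam, eye), 0.0
        )
        resid = float(np.linalg.norm(x_new - mapped)) / max(
            1.0, float(np.linalg.norm(x_new))
        )
        f_new = problem.f(x_new)
        trace.append(
            TraceRecord(
                k=k,
                F=f_new + lam * problem.l1(x_new),
                f=f_new,
                alpha=step,
                rule_used="FISTA",
                w=0,
                stationarity=resid,
                rre=None
                if truth is None
                else float(np.linalg.norm(x_new - truth) / np.linalg.norm(truth)),
                grad_norm=float(np.linalg.norm(g)),
            )
        )
        x = x_new
        t = t_new
        if resid <= config.tol:
            converged = True
            stop_reason = "converged"
            break
    return SolveResult(x=x, trace=trace, converged=converged, stop_reason=stop_reason)
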