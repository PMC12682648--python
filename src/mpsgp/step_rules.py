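"""Barzilai-Borwein (BB) step-size rules for the scaled gradient projection
iteration, including index-partitioned variants for the l1-regularized
non-negative problem.

The classical scaled BB ratios built from ``s = x_k - x_{k-1}`` and
``z = grad_k - grad_{k-1}`` are

    BB1 = (s^T D^-1 D^-1 s) / (s^T D^-1 z),
    BB2 = (s^T D z) / (z^T D D z).

During the iteration the index set splits into ``J`` (components that are
exactly zero with the negative gradient inside the l1 subdifferential band
``[-lam, lam]``, i.e. optimally zero) and its complement ``I``.  Restricting
the BB quantities to ``I`` gives the partitioned rules; dropping the ``z_J``
contribution from the partitioned BB2 denominator gives the larger step BB2*,
and the SS* rule switches between the (partitioned) BB1 and BB2* candidates
by thresholding their ratio at ``tau``.

All rules may be *undefined* (non-positive curvature estimates); they then
return ``None`` and the caller falls back to ``alpha_max``, trusting the
nonmonotone line search to shorten overlong safeguarded steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .proximal_ops import ScalingDiag

__all__ = [
    "IndexPartition",
    "StepHistory",
    "scaling_matrix",
    "partition_indices",
    "bb1_step",
    "bb2_step",
    "bb_partitioned",
    "bb2_star_step",
    "ss_star_select",
    "clamp_alpha",
    "select_step_size",
    "STEP_RULES",
]

STEP_RULES = ("bb1", "bb2", "ss-approx", "bb2star", "ssstar")


@dataclass(frozen=True)
class IndexPartition:
    """Boolean masks for the optimally-zero set ``J`` and its complement ``I``."""

    J: np.ndarray
    I: np.ndarray

    def __post_init__(self) -> None:
        J = np.asarray(self.J, dtype=bool)
        I = np.asarray(self.I, dtype=bool)
        if J.shape != I.shape:
            raise ValueError("masks must share a shape")
        if np.any(J & I) or not np.all(J | I):
            raise ValueError("J and I must partition the index set")
        object.__setattr__(self, "J", J)
        object.__setattr__(self, "I", I)

    @property
    def n_zero(self) -> int:
        return int(self.J.sum())


@dataclass
class StepHistory:
    """Iterate and gradient differences from the previous accepted step."""

    s_prev: np.ndarray
    z_prev: np.ndarray
    alpha_prev: float


def scaling_matrix(x: np.ndarray, bound: float) -> ScalingDiag:
    """Diagonal scaling ``d_i = min(L, max(1/L, x_i))`` for a feasible iterate.

    Near-zero pixels get proportionally damped steps (which keeps sparse
    regions sparse); bright pixels are clamped at ``L`` so the
    preconditioning never exceeds the admissible band ``[1/L, L]``.
    """
    if bound <= 1.0:
        raise ValueError("bound must exceed 1")
    x = np.asarray(x, dtype=float)
    diag = np.minimum(bound, np.maximum(1.0 / bound, x))
    return ScalingDiag(diag=diag, bound=float(bound))


def partition_indices(
    x: np.ndarray, grad: np.ndarray, lam: float, zero_tol: float = 0.0
) -> IndexPartition:
    """Split indices into the optimally-zero set ``J`` and the active set ``I``.

    ``J = {i : |x_i| <= zero_tol and -grad_i in [-lam, lam]}``.  The default
    ``zero_tol = 0`` relies on soft-thresholding writing exact zeros.
    """
    x = np.asarray(x, dtype=float)
    grad = np.asarray(grad, dtype=float)
    if x.shape != grad.shape:
        raise ValueError("x and grad must share a shape")
    if zero_tol < 0:
        raise ValueError("zero_tol must be non-negative")
    in_band = (-grad >= -lam) & (-grad <= lam)
    J = (np.abs(x) <= zero_tol) & in_band
    return IndexPartition(J=J, I=~J)


def _bb1_weight(D: ScalingDiag, scaling: str, D_prev: ScalingDiag | None) -> np.ndarray:
    """Weight vector u so that BB1 = (s^T u u s) / (s^T u z).

    ``scaling='inverse'`` reads the rule with the inverse of the current
    scaling matrix; ``scaling='previous'`` uses the previous iteration's
    matrix directly (the alternative reading, kept for comparison).
    """
    if scaling == "inverse":
        return 1.0 / D.diag
    if scaling == "previous":
        return (D_prev if D_prev is not None else D).diag
    raise ValueError(f"unknown bb1 scaling {scaling!r}")


def _safe_ratio(num: float, den: float) -> float | None:
    if not np.isfinite(num) or not np.isfinite(den) or den == 0.0:
        return None
    return num / den


def bb1_step(
    h: StepHistory,
    D: ScalingDiag,
    scaling: str = "inverse",
    D_prev: ScalingDiag | None = None,
) -> float | None:
    """Scaled BB1 ratio; ``None`` when the curvature denominator is <= 0."""
    u = _bb1_weight(D, scaling, D_prev)
    s, z = h.s_prev, h.z_prev
    num = float(np.sum(s * s * u * u))
    den = float(np.sum(s * z * u))
    if den <= 0:
        return None
    return _safe_ratio(num, den)


def bb2_step(h: StepHistory, D: ScalingDiag) -> float | None:
    """Scaled BB2 ratio; ``None`` when the numerator is <= 0."""
    d = D.diag
    s, z = h.s_prev, h.z_prev
    num = float(np.sum(s * z * d))
    den = float(np.sum(z * z * d * d))
    if num <= 0 or den <= 0:
        return None
    return _safe_ratio(num, den)


def bb_partitioned(
    h: StepHistory,
    D: ScalingDiag,
    part: IndexPartition,
    which: str,
    scaling: str = "inverse",
    D_prev: ScalingDiag | None = None,
) -> float | None:
    """BB ratios restricted to the active set ``I``.

    ``which='bb1'``: numerator and denominator restricted to ``I``.
    ``which='bb2'``: numerator restricted to ``I``; the denominator keeps the
    ``z_J`` contribution as a separate term.
    """
    I, J = part.I, part.J
    if not np.any(I):
        return None
    s, z, d = h.s_prev, h.z_prev, D.diag
    if which == "bb1":
        u = _bb1_weight(D, scaling, D_prev)
        num = float(np.sum((s * s * u * u)[I]))
        den = float(np.sum((s * z * u)[I]))
        if den <= 0:
            return None
        return _safe_ratio(num, den)
    if which == "bb2":
        num = float(np.sum((s * z * d)[I]))
        den = float(np.sum((z * z * d * d)[I]) + np.sum((z * z * d * d)[J]))
        if num <= 0 or den <= 0:
            return None
        return _safe_ratio(num, den)
    raise ValueError(f"unknown partitioned rule {which!r}")


def bb2_star_step(h: StepHistory, D: ScalingDiag, part: IndexPartition) -> float | None:
    """The BB2* rule: partitioned BB2 with the ``z_J`` denominator term dropped.

    Dropping the optimally-zero components from the curvature estimate yields
    a step at least as large as the partitioned BB2, focusing the quasi-Newton
    approximation on the active subspace.
    """
    I = part.I
    if not np.any(I):
        return None
    s, z, d = h.s_prev, h.z_prev, D.diag
    num = float(np.sum((s * z * d)[I]))
    den = float(np.sum((z * z * d * d)[I]))
    if num <= 0 or den <= 0:
        return None
    return _safe_ratio(num, den)


def ss_star_select(bb1: float, bb2star: float, tau: float) -> tuple[float, str]:
    """Switching rule: BB1 when ``bb1/bb2star < tau``, else BB2* (inclusive)."""
    if bb1 <= 0 or bb2star <= 0:
        raise ValueError("candidates must be positive; apply fallback first")
    if tau <= 0:
        raise ValueError("tau must be positive")
    if bb1 / bb2star < tau:
        return bb1, "BB1"
    return bb2star, "BB2*"


def clamp_alpha(
    alpha: float | None, amin: float, amax: float, fallback: float
) -> float:
    """Clamp a candidate step to ``[amin, amax]``; ``None`` maps to ``fallback``."""
    if not (0 < amin < amax):
        raise ValueError("need 0 < amin < amax")
    if alpha is None:
        return float(fallback)
    return float(min(amax, max(amin, alpha)))


def select_step_size(
    rule: str,
    h: StepHistory,
    D: ScalingDiag,
    part: IndexPartition,
    *,
    tau: float,
    alpha_min: float,
    alpha_max: float,
    bb1_scaling: str = "inverse",
    D_prev: ScalingDiag | None = None,
) -> tuple[float, str]:
    """Evaluate the configured rule and return a clamped ``(alpha, rule_used)``.

    Undefined candidates fall back to ``alpha_max`` (reported as ``"FB"``);
    when only one branch of a switching rule is defined, that branch is used.
    """
    if rule == "bb1":
        cand: list[tuple[float | None, str]] = [
            (bb1_step(h, D, bb1_scaling, D_prev), "BB1")
        ]
    elif rule == "bb2":
        cand = [(bb2_step(h, D), "BB2")]
    elif rule == "bb2star":
        cand = [(bb2_star_step(h, D, part), "BB2*")]
    elif rule == "ssstar":
        a1 = bb_partitioned(h, D, part, "bb1", bb1_scaling, D_prev)
        a2 = bb2_star_step(h, D, part)
        if a1 is not None and a2 is not None:
            return _clamped(ss_star_select(a1, a2, tau), alpha_min, alpha_max)
        cand = [(a2, "BB2*"), (a1, "BB1")]
    elif rule == "ss-approx":
        a1 = bb1_step(h, D, bb1_scaling, D_prev)
        a2 = bb2_step(h, D)
        if a1 is not None and a2 is not None:
            alpha, used = ss_star_select(a1, a2, tau)
            used = "BB1" if used == "BB1" else "BB2"
            return _clamped((alpha, used), alpha_min, alpha_max)
        cand = [(a2, "BB2"), (a1, "BB1")]
    else:
        raise ValueError(f"unknown step rule {rule!r}; choose from {STEP_RULES}")

    for alpha, used in cand:
        if alpha is not None:
            return _clamped((alpha, used), alpha_min, alpha_max)
    return clamp_alpha(None, alpha_min, alpha_max, alpha_max), "FB"


def _clamped(pair: tuple[float, str], amin: float, amax: float) -> tuple[float, str]:
    alpha, used = pair
    return clamp_alpha(alpha, amin, amax, amax), used
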