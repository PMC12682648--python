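"""Unified momentum (UM) framework adapted to the projected proximal setting.

The unconstrained UM recursion with momentum weight ``eta`` and extrapolation
parameter ``s`` is the three-line scheme

    y_k   = x_k - alpha * grad(x_k)
    y_k^s = x_k - s * alpha * grad(x_k)
    x_{k+1} = y_k + eta * (y_k^s - y_{k-1}^s)

which specializes to heavy-ball (``s = 0``), Nesterov acceleration
(``s = 1``) and an accelerated gradient form (``s = 1/(1-eta)``).

Inside the constrained solver the same idea is realized in three pieces: an
intermediate (extrapolated) point ``m_k = x_k - s*alpha*D*grad``, a momentum
vector ``v_k`` obtained by projecting the difference of successive
intermediate points onto the non-negative orthant, and the momentum-corrected
candidate ``y_k = y_k^p + eta * v_k``.  Because ``y_k^p >= 0`` and
``v_k >= 0``, the candidate stays feasible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .proximal_ops import ScalingDiag

__all__ = [
    "MomentumConfig",
    "intermediate_point",
    "momentum_vector",
    "apply_momentum",
    "um_reference_run",
    "MOMENTUM_VARIANTS",
]

MOMENTUM_VARIANTS = ("hb", "nag", "gm", "none", "custom")


@dataclass(frozen=True)
class MomentumConfig:
    """Resolved momentum parameters ``(eta, s)`` and the variant they encode."""

    eta: float
    s: float
    variant: str = "custom"

    def __post_init__(self) -> None:
        if not (0.0 <= self.eta < 1.0):
            raise ValueError("eta must lie in [0, 1)")
        if self.s < 0:
            raise ValueError("s must be non-negative")
        expected = {"hb": 0.0, "nag": 1.0, "gm": 1.0 / (1.0 - self.eta)}
        if self.variant in expected and abs(self.s - expected[self.variant]) > 1e-12:
            raise ValueError(
                f"variant {self.variant!r} requires s = {expected[self.variant]}, got {self.s}"
            )
        if self.variant == "none" and (self.eta != 0.0 or self.s != 0.0):
            raise ValueError("variant 'none' requires eta = s = 0")

    @classmethod
    def resolve(
        cls, variant: str, eta: float, s: float | None = None
    ) -> "MomentumConfig":
        """Build a config from a variant token, filling in the implied ``s``."""
        variant = variant.lower()
        if variant == "hb":
            return cls(eta=eta, s=0.0, variant="hb")
        if variant == "nag":
            return cls(eta=eta, s=1.0, variant="nag")
        if variant == "gm":
            return cls(eta=eta, s=1.0 / (1.0 - eta), variant="gm")
        if variant == "none":
            return cls(eta=0.0, s=0.0, variant="none")
        if variant == "custom":
            if s is None:
                raise ValueError("variant 'custom' requires an explicit s")
            return cls(eta=eta, s=float(s), variant="custom")
        raise ValueError(
            f"unknown momentum variant {variant!r}; choose from {MOMENTUM_VARIANTS}"
        )


def intermediate_point(
    x: np.ndarray, alpha: float, D: ScalingDiag, grad: np.ndarray, s: float
) -> np.ndarray:
    """Extrapolated position ``m = x - s * alpha * D * grad`` (``s=0`` gives x)."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if s < 0:
        raise ValueError("s must be non-negative")
    x = np.asarray(x, dtype=float)
    grad = np.asarray(grad, dtype=float)
    if x.shape != grad.shape:
        raise ValueError("x and grad must share a shape")
    return x - s * alpha * D.diag * grad


def momentum_vector(
    m: np.ndarray, m_prev: np.ndarray, projection: str = "difference"
) -> np.ndarray:
    """Momentum carrier ``v = Pi_{>=0}(m - m_prev)``.

    Projecting the *difference* of intermediate points discards negative
    momentum components so the subsequent correction cannot leave the
    feasible set.  ``projection='none'`` keeps the raw difference (for
    measuring the effect of the projection).
    """
    m = np.asarray(m, dtype=float)
    m_prev = np.asarray(m_prev, dtype=float)
    if m.shape != m_prev.shape:
        raise ValueError("m and m_prev must share a shape")
    diff = m - m_prev
    if projection == "difference":
        return np.maximum(diff, 0.0)
    if projection == "none":
        return diff
    raise ValueError(f"unknown momentum projection {projection!r}")


def apply_momentum(y_prox: np.ndarray, v: np.ndarray, eta: float) -> np.ndarray:
    """Momentum-corrected candidate ``y = y_prox + eta * v``."""
    if not (0.0 <= eta < 1.0):
        raise ValueError("eta must lie in [0, 1)")
    return np.asarray(y_prox, dtype=float) + eta * np.asarray(v, dtype=float)


def um_reference_run(
    grad_fn: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    alpha: float,
    eta: float,
    s: float,
    n_steps: int,
) -> np.ndarray:
    """Run the unconstrained three-line UM recursion verbatim.

    Returns the trajectory ``[x_0, x_1, ..., x_n]``.  The virtual previous
    iterate is taken as ``x_{-1} = x_0``, so the first update carries no
    momentum.  This reference exists so the heavy-ball / Nesterov / gradient
    specializations can be verified against their explicit recursions.
    """
    x = np.asarray(x0, dtype=float).copy()
    ys_prev = x - s * alpha * np.asarray(grad_fn(x), dtype=float)
    traj = [x.copy()]
    for _ in range(n_steps):
        g = np.asarray(grad_fn(x), dtype=float)
        y = x - alpha * g
        ys = x - s * alpha * g
        x = y + eta * (ys - ys_prev)
        ys_prev = ys
        traj.append(x.copy())
    return np.array(traj)
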