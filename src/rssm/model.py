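"""The sparse-smooth decomposition objective and its smooth-part gradients.

An observed fluorescence image ``Y`` is modelled as foreground plus
background plus noise, ``Y = Is + B + N``, where the foreground ``Is``
(somas, neurites) is sparse and moderately smooth and the background ``B``
is smoother still.  Estimation solves the convex program

    min_{Is, B >= 0}  1/2 ||Y - Is - B||^2  +  lambda1 ||Is||_1
                      + 1/2 lambda2 ||D_{k0} Is||^2
                      + 1/2 lambda3 ||D_{k1} B||^2

with k-th order difference operators ``D_k`` along each in-plane axis and
``k0 < k1`` expressing that the background is the smoother component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import operators

__all__ = ["RSSMParams", "Decomposition", "objective", "grad_F_Is", "grad_F_B",
           "lipschitz_bounds"]


@dataclass(frozen=True)
class RSSMParams:
    """Model constants.  Defaults are the fixed values used for every
    experiment; they are not tuned per image.

    lambda1 : weight of the foreground L1 sparsity term.
    lambda2 : weight of the foreground smoothness term (order ``k0``).
    lambda3 : weight of the background smoothness term (order ``k1``).
    k0, k1  : difference orders; ``k0 < k1`` encodes the smoother background.
    floor   : hard threshold applied to the foreground each iteration
              (intensity units on an 8-bit-like scale).
    max_iter, tol : iteration cap and relative-change stopping tolerance.
    prox_mode : "floor" uses the hard floor threshold; "soft" uses the exact
              proximal map of ``lambda1 ||.||_1`` with non-negativity
              (soft shrinkage by ``lambda1 / Ls``).
    """

    lambda1: float = 0.1
    lambda2: float = 0.1
    lambda3: float = 0.5
    k0: int = 2
    k1: int = 5
    floor: float = 3.0
    max_iter: int = 200
    tol: float = 1e-3
    prox_mode: str = "floor"
    allow_k_override: bool = False

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "lambda3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.k0 < 1 or self.k1 < 1:
            raise ValueError("difference orders k0, k1 must be >= 1")
        if self.k0 >= self.k1:
            if self.allow_k_override:
                warnings.warn(
                    f"k0={self.k0} >= k1={self.k1}: the background is no "
                    "longer the smoother component", stacklevel=2)
            else:
                raise ValueError(
                    f"k0={self.k0} must be < k1={self.k1} (set "
                    "allow_k_override=True to run diagnostic configurations)")
        if self.floor < 0:
            raise ValueError("floor must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.prox_mode not in ("floor", "soft"):
            raise ValueError(f"unknown prox_mode {self.prox_mode!r}")


@dataclass
class Decomposition:
    """Result of one decomposition.

    ``foreground + background + residual`` reconstructs the input exactly by
    construction; both estimated components are non-negative.
    """

    foreground: np.ndarray
    background: np.ndarray
    residual: np.ndarray
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    iterations: int = 0
    converged: bool = False


def _check_shapes(*arrays: np.ndarray) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise ValueError(f"shape mismatch: {sorted(shapes)}")


def objective(Y: np.ndarray, Is: np.ndarray, B: np.ndarray,
              params: RSSMParams) -> float:
    """Evaluate the full objective (data term + all three penalties)."""
    Y, Is, B = (np.asarray(a, dtype=float) for a in (Y, Is, B))
    _check_shapes(Y, Is, B)
    r = Y - Is - B
    val = 0.5 * float(np.sum(r * r))
    val += params.lambda1 * float(np.sum(np.abs(Is)))
    val += 0.5 * params.lambda2 * operators.smooth_penalty(Is, params.k0)
    val += 0.5 * params.lambda3 * operators.smooth_penalty(B, params.k1)
    return val


def grad_F_Is(Y: np.ndarray, Is: np.ndarray, B: np.ndarray,
              params: RSSMParams) -> np.ndarray:
    """Gradient of the smooth part F with respect to the foreground:
    ``Is + B - Y + lambda2 (Dx^T Dx + Dy^T Dy) Is`` at order ``k0``.
    """
    Y, Is, B = (np.asarray(a, dtype=float) for a in (Y, Is, B))
    _check_shapes(Y, Is, B)
    g = Is + B - Y
    if params.lambda2 > 0:
        g = g + params.lambda2 * (operators.gram_apply(Is, params.k0, axis=0)
                                  + operators.gram_apply(Is, params.k0, axis=1))
    return g


def grad_F_B(Y: np.ndarray, Is: np.ndarray, B: np.ndarray,
             params: RSSMParams) -> np.ndarray:
    """Gradient of F with respect to the background (order ``k1``,
    weight ``lambda3``)."""
    Y, Is, B = (np.asarray(a, dtype=float) for a in (Y, Is, B))
    _check_shapes(Y, Is, B)
    g = Is + B - Y
    if params.lambda3 > 0:
        g = g + params.lambda3 * (operators.gram_apply(B, params.k1, axis=0)
                                  + operators.gram_apply(B, params.k1, axis=1))
    return g


def lipschitz_bounds(params: RSSMParams) -> tuple[float, float]:
    """Closed-form Lipschitz bounds for the two partial gradients.

    ``Ls = 1 + 2 lambda2 (k0^2 + k0)^2`` and
    ``LB = 1 + 2 lambda3 (k1^2 + k1)^2``; the leading 1 is the data term's
    identity Hessian, the factor 2 accounts for the two in-plane axes, and
    ``(k^2 + k)^2`` bounds the spectrum of each ``D_k^T D_k``.  Reciprocals
    are safe step sizes for proximal gradient descent.
    """
    Ls = 1.0 + 2.0 * params.lambda2 * operators.operator_norm_bound(params.k0)
    LB = 1.0 + 2.0 * params.lambda3 * operators.operator_norm_bound(params.k1)
    return Ls, LB
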