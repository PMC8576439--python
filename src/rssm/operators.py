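"""k-th order forward-difference operators and their adjoints.

The sparse-smooth decomposition penalises the squared k-th order finite
difference of an image along each in-plane axis.  The operator is defined by
a template vector ``tem`` of length ``k + 1`` whose first ``k`` entries are
-1 and whose last entry is ``k``::

    (D_k u)(t) = k * u(t) - sum_{i=1..k} u(t - i)

applied with implicit zero padding: an input of extent ``m`` along the
chosen axis yields an output of extent ``m + k`` whose first ``k`` and last
``k`` positions are identically zero.  Because the template sums to zero the
operator annihilates constant images, so penalising ``||D_k u||^2`` measures
roughness rather than brightness.

Two realisations are provided: a vectorised sliding-window form used in
production, and an explicit dense-matrix form (`forward_matrix`) used as a
brute-force cross-check and to study the operator spectrum.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "difference_template",
    "forward_difference",
    "adjoint_difference",
    "smooth_penalty",
    "operator_norm_bound",
    "forward_matrix",
    "gram_apply",
]


def difference_template(k: int) -> np.ndarray:
    """Coefficient vector ``[-1, ..., -1, k]`` of length ``k + 1``."""
    if k < 1:
        raise ValueError(f"difference order must be >= 1, got {k}")
    tem = -np.ones(k + 1)
    tem[-1] = float(k)
    return tem


def _check_axis(img: np.ndarray, axis: int) -> int:
    if img.ndim != 2:
        raise ValueError(f"expected a 2D image, got {img.ndim} axes")
    if axis not in (0, 1):
        raise ValueError(f"axis must be 0 or 1, got {axis}")
    return axis


def forward_difference(img: np.ndarray, k: int, axis: int = 0) -> np.ndarray:
    """Apply the k-th order difference along ``axis`` with zero padding.

    The output extent along ``axis`` is ``m + k`` where ``m`` is the input
    extent; positions ``0..k-1`` and ``m..m+k-1`` are zero.  Inputs with
    extent ``< k + 1`` along the axis produce an all-zero output (there are
    no valid positions), which lets high orders run on thin tiles.
    """
    tem = difference_template(k)
    img = np.asarray(img, dtype=float)
    _check_axis(img, axis)
    if axis == 1:
        return forward_difference(img.T, k, axis=0).T
    m, n = img.shape
    out = np.zeros((m + k, n))
    if m < k + 1:
        return out
    # out[i + k] = sum_l tem[l] * img[i + l],  i = 0..m-k-1
    for l in range(k + 1):
        out[k : m, :] += tem[l] * img[l : l + m - k, :]
    return out


def adjoint_difference(grad: np.ndarray, k: int, axis: int = 0) -> np.ndarray:
    """Exact adjoint of :func:`forward_difference` under the Frobenius inner
    product: correlation with the reversed template, restricted to the rows
    the forward operator can reach (its first and last ``k`` output rows are
    structurally zero and carry no adjoint contribution).
    """
    tem = difference_template(k)
    grad = np.asarray(grad, dtype=float)
    _check_axis(grad, axis)
    if axis == 1:
        return adjoint_difference(grad.T, k, axis=0).T
    mk, n = grad.shape
    m = mk - k
    if m < 1:
        raise ValueError(
            f"gradient extent {mk} too small for order {k} along axis {0}"
        )
    out = np.zeros((m, n))
    if m < k + 1:
        return out
    # Only rows k..m-1 of the gradient are in the range of the forward map.
    core = np.zeros_like(grad)
    core[k : m, :] = grad[k : m, :]
    # out[i] = sum_l core[i + l] * tem[k - l],  i = 0..m-1
    for l in range(k + 1):
        out += tem[k - l] * core[l : l + m, :]
    return out


def gram_apply(img: np.ndarray, k: int, axis: int = 0) -> np.ndarray:
    """Apply the composite operator ``D_k^T D_k`` along one axis."""
    return adjoint_difference(forward_difference(img, k, axis), k, axis)


def smooth_penalty(img: np.ndarray, k: int) -> float:
    """Squared difference penalty ``||D_k^x img||^2 + ||D_k^y img||^2``.

    Axes with extent ``< k + 1`` contribute zero.
    """
    img = np.asarray(img, dtype=float)
    gx = forward_difference(img, k, axis=0)
    gy = forward_difference(img, k, axis=1)
    return float(np.sum(gx * gx) + np.sum(gy * gy))


def operator_norm_bound(k: int) -> float:
    """Upper bound ``(k^2 + k)^2`` on the largest eigenvalue of ``D_k^T D_k``."""
    if k < 1:
        raise ValueError(f"difference order must be >= 1, got {k}")
    return float((k * k + k) ** 2)


def forward_matrix(m: int, k: int) -> np.ndarray:
    """Dense ``(m + k) x m`` matrix form of the 1-D forward difference.

    Exists for testing and spectral analysis; production code uses the
    sliding-window form.
    """
    tem = difference_template(k)
    A = np.zeros((m + k, m))
    for i in range(max(m - k, 0)):
        for l in range(k + 1):
            A[i + k, i + l] = tem[l]
    return A
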