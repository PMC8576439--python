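"""Initial foreground/background pair for the iteration.

The background guess is built by clipping the observed image from above at
its global median (bright structures are removed, the slowly varying floor
remains) and then smoothing repeatedly with a small normalised Gaussian
kernel.  The foreground guess is the non-negative part of what is left.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["initialize"]

# Separable 3x3 binomial kernel [1,2,1]/4 per axis; 20 passes approximate a
# single wide Gaussian.  Reflective boundaries preserve constants exactly.
_KERNEL_1D = np.array([1.0, 2.0, 1.0]) / 4.0


def initialize(Y: np.ndarray, n_smooth: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(Is0, B0)`` for a 2D image.

    ``B0`` is ``min(Y, median(Y))`` smoothed ``n_smooth`` times;
    ``Is0 = max(Y - B0, 0)``.  Both are non-negative for non-negative input.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError(f"expected a 2D image, got {Y.ndim} axes")
    if n_smooth < 0:
        raise ValueError("n_smooth must be >= 0")
    B0 = np.minimum(Y, np.median(Y))
    for _ in range(n_smooth):
        for axis in range(2):
            B0 = ndimage.correlate1d(B0, _KERNEL_1D, axis=axis, mode="reflect")
    Is0 = np.maximum(Y - B0, 0.0)
    return Is0, B0
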