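"""Regularized delta kernels for immersed-boundary coupling.

The standard 4-point kernel (support +-2 grid cells, value 1/2 at the
origin) is used for both force spreading and velocity interpolation; the
2D delta is the tensor product ``delta(x) = phi(x1/h) phi(x2/h) / h^2``.
The kernel satisfies the discrete partition of unity
``sum_j phi(r - j) = 1`` for every real ``r``, plus even symmetry and the
first-moment condition, which make spreading conservative and
interpolation exact for constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["phi4", "DeltaKernel"]


def phi4(r):
    """Peskin's 4-point kernel, vectorised.

    ``phi(0) = 1/2``, support ``|r| <= 2``, partition of unity within
    rounding error.
    """
    r = np.asarray(r, dtype=float)
    a = np.abs(r)
    out = np.zeros_like(a)
    m1 = a <= 1.0
    m2 = (a > 1.0) & (a < 2.0)
    a1 = a[m1]
    a2 = a[m2]
    out[m1] = 0.125 * (3.0 - 2.0 * a1 + np.sqrt(1.0 + 4.0 * a1 - 4.0 * a1 * a1))
    out[m2] = 0.125 * (5.0 - 2.0 * a2 - np.sqrt(-7.0 + 12.0 * a2 - 4.0 * a2 * a2))
    return out


@dataclass(frozen=True)
class DeltaKernel:
    """A compactly supported, even, partition-of-unity 1D kernel."""

    support: int = 2  # cells on each side

    def __call__(self, r):
        return phi4(r)

    def stencil_weights(self, x_over_h: np.ndarray):
        """Stencil indices and weights for points at grid coordinate ``x/h``.

        For each scalar coordinate (grid units, where sample ``j`` sits at
        coordinate ``j``) returns the ``2*support`` integer indices and the
        kernel weights; the weights of each point sum to 1 exactly (up to
        rounding) by the partition of unity.
        """
        x = np.atleast_1d(np.asarray(x_over_h, dtype=float))
        base = np.floor(x).astype(int)
        offs = np.arange(1 - self.support, self.support + 1)  # e.g. [-1, 0, 1, 2]
        idx = base[:, None] + offs[None, :]
        w = phi4(x[:, None] - idx)
        return idx, w
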