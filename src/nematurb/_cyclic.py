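"""Periodic (cyclic) tridiagonal solver for the implicit diffusion sweeps.

The operator is ``I - beta * D2`` with ``D2`` the periodic second-difference
stencil (1, -2, 1)/dx^2.  Writing ``a = beta/dx^2`` the cyclic matrix equals
``I + a*L_cycle`` with ``L_cycle`` the graph Laplacian of the n-cycle, which
splits as ``L_path + w w^T`` with ``w = e_0 - e_{n-1}``.  ``I + a*L_path`` is
symmetric positive definite and banded, so it is Cholesky-factorized once and
the cyclic solution is recovered with a Sherman-Morrison rank-one update.
This returns the exact solution of the periodic system (not the open-ended
tridiagonal one).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_solve_banded, cholesky_banded

__all__ = ["CyclicDiffusionSolver"]


class CyclicDiffusionSolver:
    """Solves (I - beta * D2_periodic) x = b along axis 0 of b.

    The factorization is computed once at construction; ``solve`` handles a
    single right-hand side or a matrix of them (one per column).
    """

    def __init__(self, n: int, beta: float, dx: float):
        if n < 3:
            raise ValueError("need at least 3 points for a cyclic stencil")
        if beta <= 0:
            raise ValueError("beta must be positive")
        a = beta / dx**2
        ab = np.zeros((2, n))
        ab[0, 1:] = -a                 # superdiagonal (upper banded storage)
        ab[1, :] = 1.0 + 2.0 * a
        ab[1, 0] -= a                  # path Laplacian: degree 1 at the ends
        ab[1, -1] -= a
        self._cho = cholesky_banded(ab, lower=False)
        w = np.zeros(n)
        w[0], w[-1] = 1.0, -1.0
        self._z = cho_solve_banded((self._cho, False), w)
        self._a = a
        self._denom = 1.0 + a * (self._z[0] - self._z[-1])

    def solve(self, b: np.ndarray) -> np.ndarray:
        y = cho_solve_banded((self._cho, False), b)
        corr = (self._a / self._denom) * (y[0] - y[-1])
        if y.ndim == 1:
            return y - self._z * corr
        return y - self._z[:, None] * corr[None, :]
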