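"""Fused explicit-update kernel for the ADI half steps.

One pass over the grid assembles

    out = theta + hdt * ( A*(-vx*dx(theta) + vy*dy(theta) + om/2)
                          + d2_explicit(theta) )

with centered periodic finite differences; ``explicit_axis`` selects which
axis carries the *explicit* second difference (the other axis is treated
implicitly by the caller).
"""

from __future__ import annotations

import numba as nb


@nb.njit(cache=True, fastmath=True)
def explicit_half_rhs(theta, vx, vy, om, A, hdt, invdx2, inv2dx,
                      explicit_axis, out):  # pragma: no cover - exercised via Stepper
    n = theta.shape[0]
    for i in range(n):
        im = i - 1 if i > 0 else n - 1
        ip = i + 1 if i < n - 1 else 0
        for j in range(n):
            jm = j - 1 if j > 0 else n - 1
            jp = j + 1 if j < n - 1 else 0
            dxt = (theta[ip, j] - theta[im, j]) * inv2dx
            dyt = (theta[i, jp] - theta[i, jm]) * inv2dx
            if explicit_axis == 1:
                d2 = (theta[i, jp] + theta[i, jm] - 2.0 * theta[i, j]) * invdx2
            else:
                d2 = (theta[ip, j] + theta[im, j] - 2.0 * theta[i, j]) * invdx2
            out[i, j] = theta[i, j] + hdt * (
                A * (-vx[i, j] * dxt + vy[i, j] * dyt + 0.5 * om[i, j]) + d2)
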