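"""Linear stability of the uniformly aligned state.

Linearizing the coupled Stokes/director equations about theta = 0 decouples
the Fourier modes; because the flow is slaved to the director, each mode
evolves with a single real rate (the primary spontaneous-flow instability is
non-oscillatory),

    s(k) = S (kx^2 - ky^2) / (2 k^2) - (R + 4) k^2 / (4 A)     [1/tau_a].

The first term is the active backflow drive (maximal for bend perturbations
transverse to the director when S = -1), the second combines elastic
relaxation and the viscous backflow correction.  On the unit square the
smallest wavenumber is 2*pi, giving the critical activity
A_c = (R + 4) k_min^2 / 2 (about 98.7 for R = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import TAU_R, ModelParams

__all__ = ["DispersionPoint", "growth_rate", "critical_activity", "dispersion_table"]


@dataclass(frozen=True)
class DispersionPoint:
    kx: float
    ky: float
    s: float  # growth rate, 1/tau_a


def growth_rate(kx: float, ky: float, p: ModelParams,
                fd_n: int | None = None) -> float:
    """Linear growth rate of a single-mode perturbation of the aligned state.

    Returned in 1/tau_a by default; multiplied by A when ``p.time_unit`` is
    'tau_r'.  With ``fd_n`` set, the elastic diffusion term uses the
    second-difference symbol of an n-point grid instead of -k^2, matching the
    mixed spectral/finite-difference discretization of the simulator.
    """
    k2 = kx * kx + ky * ky
    if k2 == 0:
        raise ValueError("zero wavevector has no growth rate")
    if fd_n is None:
        diff = k2
    else:
        dx = 1.0 / fd_n
        diff = (2 - 2 * np.cos(kx * dx)) / dx**2 + (2 - 2 * np.cos(ky * dx)) / dx**2
    s = p.S * (kx * kx - ky * ky) / (2.0 * k2) - (p.R * k2 + 4.0 * diff) / (4.0 * p.A)
    if p.time_unit == TAU_R:
        s *= p.A
    return float(s)


def critical_activity(p: ModelParams | None = None, k_min: float = 2.0 * np.pi,
                      R: float | None = None) -> float:
    """Smallest activity at which any periodic mode becomes marginal.

    At the optimal orientation the active drive is |S|/2 regardless of the
    stress sign, so A_c = (R + 4) k_min^2 / 2.
    """
    if R is None:
        R = 1.0 if p is None else p.R
    if R < 0:  # R = 0 is the vanishing-rotational-viscosity limit
        raise ValueError("R must be non-negative")
    return (R + 4.0) * k_min**2 / 2.0


def dispersion_table(p: ModelParams, k_max_index: int = 8) -> list[DispersionPoint]:
    """Growth rates on the integer mode lattice up to ``k_max_index`` per axis
    (excluding the zero mode); rates in 1/tau_a."""
    pa = ModelParams(A=p.A, R=p.R, S=p.S, time_unit="tau_a")
    pts = []
    for ix in range(0, k_max_index + 1):
        for iy in range(0, k_max_index + 1):
            if ix == 0 and iy == 0:
                continue
            kx, ky = 2 * np.pi * ix, 2 * np.pi * iy
            pts.append(DispersionPoint(kx, ky, growth_rate(kx, ky, pa)))
    return pts
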