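"""Spatial discretization and the instantaneous Stokes problem of a minimal
unconfined active nematic.

The model lives on the doubly periodic unit square and has a single dynamical
field: the director angle ``theta(r, t)``, with director ``n = (cos theta,
sin theta)`` of unit norm (deep nematic limit, defect-free).  The flow is
slaved to the director through a fourth-order Stokes problem for the stream
function ``psi``,

    -lap^2 psi = (R/2A) lap^2 theta
                 + S [ (1/2)(dxx - dyy) sin 2theta - dxy cos 2theta ],

with ``v = (dy psi, -dx psi)`` incompressible by construction.  Control
parameters are the activity number ``A = L^2/l_c^2`` (the sole bifurcation
parameter), the viscosity ratio ``R = gamma/eta`` and the sign of the active
stress ``S`` (-1 contractile, +1 extensile; the two are related by a global
pi/2 rotation of the director).

The Stokes solve and all derivatives of ``psi`` are pseudo-spectral with 2/3
dealiasing of the right-hand side; derivatives of ``theta`` in the director
dynamics are second-order centered finite differences (see
:func:`director_tendency`).  Lengths are in units of the box size ``L = 1``;
rates are returned in units of the active time ``tau_a`` or the nematic
relaxation time ``tau_r = A tau_a`` according to ``ModelParams.time_unit``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.fft as sfft

__all__ = [
    "GridSpec",
    "ModelParams",
    "PhysicalParameters",
    "DirectorField",
    "FlowFields",
    "make_grid",
    "solve_stream_function",
    "stream_function_hat",
    "velocity_from_stream",
    "vorticity_from_stream",
    "director_tendency",
    "fd_derivative",
    "fd_second_derivative",
    "check_resolution",
]

TAU_A = "tau_a"
TAU_R = "tau_r"


@dataclass(frozen=True)
class GridSpec:
    """Doubly periodic n-by-n grid on the unit square.

    Real arrays are indexed ``[ix, iy]``; spectral arrays use the half-complex
    rfft2 layout over axes ``(0, 1)`` (the y axis is the halved one).
    """

    n: int
    dx: float
    x: np.ndarray          # (n,) node coordinates
    y: np.ndarray          # (n,)
    kx: np.ndarray         # (n, 1) wavenumbers, 2*pi * integer frequencies
    ky: np.ndarray         # (1, n//2 + 1)
    k2: np.ndarray         # (n, n//2+1) |k|^2
    k4: np.ndarray         # |k|^4
    dealias_mask: np.ndarray = field(repr=False)  # bool, 2/3 rule

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n, self.n)


def make_grid(n: int) -> GridSpec:
    """Build the periodic unit-square grid with ``n`` points per side.

    ``n`` must be even and at least 16 so that the 2/3 dealiasing mask and the
    half-complex transforms are well defined.
    """
    if n % 2 != 0 or n < 16:
        raise ValueError(f"grid size must be even and >= 16, got n={n}")
    dx = 1.0 / n
    x = np.arange(n) * dx
    fx = np.fft.fftfreq(n, d=dx)            # integer frequencies (cycles / L)
    fy = np.fft.rfftfreq(n, d=dx)
    kx = (2.0 * np.pi * fx)[:, None]
    ky = (2.0 * np.pi * fy)[None, :]
    k2 = kx**2 + ky**2
    cutoff = n / 3.0                         # 2/3 of the Nyquist index n/2
    mask = (np.abs(fx)[:, None] < cutoff) & (np.abs(fy)[None, :] < cutoff)
    return GridSpec(n=n, dx=dx, x=x, y=x.copy(), kx=kx, ky=ky,
                    k2=k2, k4=k2**2, dealias_mask=mask)


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless control parameters.

    A : activity number L^2/l_c^2, > 0.
    R : viscosity ratio gamma/eta, > 0.
    S : sign of the active stress, -1 (contractile) or +1 (extensile).
    time_unit : 'tau_r' (nematic relaxation time, the default used in all
        diagnostics) or 'tau_a' (active time); 1 tau_r = A tau_a.
    """

    A: float
    R: float = 1.0
    S: int = -1
    time_unit: str = TAU_R

    def __post_init__(self):
        if not (self.A > 0):
            raise ValueError(f"activity number must be positive, got A={self.A}")
        if not (self.R > 0):
            raise ValueError(f"viscosity ratio must be positive, got R={self.R}")
        if self.S not in (-1, 1):
            raise ValueError(f"S must be exactly -1 or +1, got {self.S}")
        if self.time_unit not in (TAU_A, TAU_R):
            raise ValueError(f"unknown time unit {self.time_unit!r}")

    @property
    def ell_c(self) -> float:
        """Active length in units of L."""
        return self.A ** -0.5

    def with_activity(self, A: float) -> "ModelParams":
        return replace(self, A=A)


@dataclass(frozen=True)
class PhysicalParameters:
    """Dimensional material parameters; convenience wrapper producing
    :class:`ModelParams` via A = L^2 |zeta| R / K, R = gamma/eta."""

    eta: float    # shear viscosity
    zeta: float   # active stress coefficient (sign sets S)
    K: float      # Frank elastic constant (one-constant approximation)
    gamma: float  # rotational viscosity
    L: float = 1.0

    @property
    def R(self) -> float:
        return self.gamma / self.eta

    @property
    def ell_c(self) -> float:
        return np.sqrt(self.K / (abs(self.zeta) * self.R))

    @property
    def tau_a(self) -> float:
        return self.eta / abs(self.zeta)

    @property
    def tau_r(self) -> float:
        return self.gamma * self.L**2 / self.K

    def to_model_params(self, time_unit: str = TAU_R) -> ModelParams:
        A = self.L**2 / self.ell_c**2
        return ModelParams(A=A, R=self.R, S=int(np.sign(self.zeta)),
                           time_unit=time_unit)


@dataclass
class DirectorField:
    """Director angle field theta (radians, unwrapped real values) and the
    current time in the configured unit."""

    theta: np.ndarray
    time: float = 0.0

    def copy(self) -> "DirectorField":
        return DirectorField(self.theta.copy(), self.time)


@dataclass
class FlowFields:
    """Flow diagnosed from theta: stream function and its derived fields.

    Velocities are in units of L/tau_a (the natural gauge of the stream
    function); multiply by A for L/tau_r.  ``omega = -lap psi`` is the
    vorticity.
    """

    psi: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    omega: np.ndarray


def check_resolution(n: int, A: float, allow_underresolved: bool = False) -> None:
    """Require the grid to resolve the active length: n > 2 sqrt(A).

    l_c/L = A^(-1/2) is the scale of the most active structures; fewer than
    two grid points per active length is rejected unless explicitly overridden
    (then only a warning is emitted).
    """
    if n <= 2.0 * np.sqrt(A):
        msg = (f"grid n={n} under-resolves the active length at A={A:g} "
               f"(need n > 2*sqrt(A) = {2*np.sqrt(A):.1f})")
        if allow_underresolved:
            warnings.warn(msg, RuntimeWarning, stacklevel=2)
        else:
            raise ValueError(msg + "; pass allow_underresolved=True to override")


def _validate(theta: np.ndarray, g: GridSpec) -> None:
    if theta.shape != g.shape:
        raise ValueError(f"field shape {theta.shape} != grid {g.shape}")
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite values in field")


def stream_function_hat(theta: np.ndarray, p: ModelParams, g: GridSpec) -> np.ndarray:
    """Half-complex spectrum of the stream function solving the active Stokes
    problem for the given director angle field.

    The right-hand side (active forcing plus the elastic backflow term) is
    dealiased with the 2/3 mask; the undetermined zero mode of psi is fixed
    to zero.
    """
    _validate(theta, g)
    s2 = np.sin(2.0 * theta)
    c2 = np.cos(2.0 * theta)
    F = sfft.rfft2(np.stack((theta, s2, c2)), axes=(1, 2))
    rhs_hat = (
        (p.R / (2.0 * p.A)) * g.k4 * F[0]
        + p.S * (0.5 * (g.ky**2 - g.kx**2) * F[1] + (g.kx * g.ky) * F[2])
    )
    rhs_hat *= g.dealias_mask
    with np.errstate(divide="ignore", invalid="ignore"):
        psi_hat = -rhs_hat / g.k4
    psi_hat[0, 0] = 0.0  # gauge: zero spatial mean
    return psi_hat


def solve_stream_function(theta: DirectorField | np.ndarray,
                          p: ModelParams, g: GridSpec) -> FlowFields:
    """Diagnose the full flow state (psi, v, omega) from the director angle."""
    th = theta.theta if isinstance(theta, DirectorField) else theta
    psi_hat = stream_function_hat(th, p, g)
    spectra = np.stack((
        psi_hat,
        1j * g.ky * psi_hat,    # dy psi = vx
        -1j * g.kx * psi_hat,   # -dx psi = vy
        g.k2 * psi_hat,         # -lap psi = omega
    ))
    psi, vx, vy, omega = sfft.irfft2(spectra, s=g.shape, axes=(1, 2))
    return FlowFields(psi=psi, vx=vx, vy=vy, omega=omega)


def velocity_from_stream(psi: np.ndarray, g: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Spectral (vx, vy) = (dy psi, -dx psi); divergence-free to roundoff."""
    _validate(psi, g)
    psi_hat = sfft.rfft2(psi)
    vx = sfft.irfft2(1j * g.ky * psi_hat, s=g.shape)
    vy = sfft.irfft2(-1j * g.kx * psi_hat, s=g.shape)
    return vx, vy


def vorticity_from_stream(psi: np.ndarray, g: GridSpec) -> np.ndarray:
    """Spectral vorticity omega = dx vy - dy vx = -lap psi."""
    _validate(psi, g)
    return sfft.irfft2(g.k2 * sfft.rfft2(psi), s=g.shape)


def fd_derivative(f: np.ndarray, axis: int, dx: float) -> np.ndarray:
    """Second-order centered first derivative on the periodic grid."""
    return (np.roll(f, -1, axis) - np.roll(f, 1, axis)) / (2.0 * dx)


def fd_second_derivative(f: np.ndarray, axis: int, dx: float) -> np.ndarray:
    """Second-order centered second derivative on the periodic grid."""
    return (np.roll(f, -1, axis) + np.roll(f, 1, axis) - 2.0 * f) / dx**2


def director_tendency(theta: DirectorField | np.ndarray, flow: FlowFields,
                      p: ModelParams, g: GridSpec) -> np.ndarray:
    """Right-hand side of the director-angle dynamics.

    In active-time units,

        dtheta/dt = -(dy psi)(dx theta) + (dx psi)(dy theta)
                    - (1/2) lap psi + (1/A) lap theta,

    i.e. advection by the flow, co-rotation with the local vorticity, and
    elastic relaxation.  When ``p.time_unit == 'tau_r'`` the whole expression
    is multiplied by A, which makes the elastic diffusion coefficient exactly
    one.  theta derivatives are centered finite differences; psi derivatives
    are taken from ``flow`` (spectral).
    """
    th = theta.theta if isinstance(theta, DirectorField) else theta
    _validate(th, g)
    dxth = fd_derivative(th, 0, g.dx)
    dyth = fd_derivative(th, 1, g.dx)
    lapth = fd_second_derivative(th, 0, g.dx) + fd_second_derivative(th, 1, g.dx)
    # flow.omega = -lap psi, so -(1/2) lap psi = +omega/2
    advect = -flow.vx * dxth + flow.vy * dyth  # vx = dy psi, vy = -dx psi
    out = advect + 0.5 * flow.omega + lapth / p.A
    if p.time_unit == TAU_R:
        out *= p.A
    return out


def warn_if_underresolved_field(theta: np.ndarray, threshold: float = np.pi / 2) -> bool:
    """Warn when nearest-neighbour angle jumps exceed ``threshold``.

    Large jumps signal incipient winding that the defect-free representation
    cannot follow; returns True if the warning fired.
    """
    jump = max(
        np.abs(np.diff(theta, axis=0)).max() if theta.shape[0] > 1 else 0.0,
        np.abs(np.diff(theta, axis=1)).max() if theta.shape[1] > 1 else 0.0,
        np.abs(theta[0] - theta[-1]).max(),
        np.abs(theta[:, 0] - theta[:, -1]).max(),
    )
    if jump > threshold:
        warnings.warn(
            f"nearest-neighbour director-angle jump {jump:.3f} rad exceeds "
            f"{threshold:.3f}; the field is under-resolved or winding up",
            RuntimeWarning, stacklevel=2)
        return True
    return False
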