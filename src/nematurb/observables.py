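"""Scalar and spatio-temporal flow diagnostics.

Mean-squared velocity (MSV) and its x/y components quantify flow intensity
and distinguish flow patterns (pure shear has one vanishing component); the
enstrophy kymograph ``eps(x, t) = <|omega|^2>_y`` resolves whether chaos is
spatially localized or global; damped-oscillation fits extract the complex
stability eigenvalue of a perturbed laminar state; and a small heuristic
classifier labels trajectory windows as quiescent, steady or oscillatory
laminar, or chaotic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import argrelextrema, periodogram

from .model import TAU_A, TAU_R, FlowFields, GridSpec, ModelParams, vorticity_from_stream

__all__ = [
    "MsvSample",
    "Kymograph",
    "OscillationFit",
    "msv",
    "enstrophy_kymograph",
    "fit_oscillation",
    "classify_flow_state",
    "count_vortices",
]


@dataclass(frozen=True)
class MsvSample:
    """Grid-averaged squared velocity and components; msv = msv_x + msv_y."""

    time: float
    msv: float
    msv_x: float
    msv_y: float
    time_unit: str = TAU_R


def msv(flow: FlowFields, p: ModelParams | None = None,
        time: float = 0.0) -> MsvSample:
    """Mean-squared velocity of a diagnosed flow state.

    ``FlowFields`` velocities are in L/tau_a; when ``p.time_unit`` is 'tau_r'
    (the default convention of all recorded diagnostics) the squared
    velocities are multiplied by A^2.
    """
    scale = 1.0
    unit = TAU_A
    if p is not None and p.time_unit == TAU_R:
        scale = p.A * p.A
        unit = TAU_R
    mx = float(np.mean(flow.vx**2)) * scale
    my = float(np.mean(flow.vy**2)) * scale
    return MsvSample(time=time, msv=mx + my, msv_x=mx, msv_y=my, time_unit=unit)


@dataclass
class Kymograph:
    """Enstrophy averaged over y, as a function of x and time."""

    x: np.ndarray        # (nx,)
    times: np.ndarray    # (nt,)
    eps: np.ndarray      # (nt, nx), >= 0
    time_unit: str = TAU_R


def enstrophy_kymograph(traj, p: ModelParams, g: GridSpec) -> Kymograph:
    """Build the enstrophy kymograph eps(x, t) = <omega^2>_y from trajectory
    snapshots.

    Vorticity is diagnosed spectrally from each stored theta snapshot; with
    ``p.time_unit == 'tau_r'`` the enstrophy carries the A^2 unit conversion.
    Accepts a Trajectory with snapshots, or a list of (time, psi) pairs of
    precomputed stream-function fields.
    """
    from .model import solve_stream_function  # local import to avoid cycle

    if hasattr(traj, "snapshots"):
        if not traj.snapshots:
            raise ValueError("trajectory has no stored snapshots")
        pairs = zip(traj.snapshot_times, traj.snapshots)
        from_theta = True
    else:
        pairs = traj
        from_theta = False
    scale = p.A * p.A if p.time_unit == TAU_R else 1.0
    times, rows = [], []
    for t, f in pairs:
        if from_theta:
            omega = solve_stream_function(f, p, g).omega
        else:
            omega = vorticity_from_stream(f, g)
        rows.append(scale * np.mean(omega**2, axis=1))
        times.append(t)
    return Kymograph(x=g.x.copy(), times=np.asarray(times),
                     eps=np.asarray(rows),
                     time_unit=p.time_unit)


@dataclass(frozen=True)
class OscillationFit:
    """Damped-oscillation fit  a * exp(decay_rate * t) * sin(2 pi f t + phase).

    decay_rate maps to the real part of the leading stability eigenvalue,
    ``frequency`` to its imaginary part over 2 pi (both 1/tau_r); residual is
    the RMS misfit relative to the RMS of the series.  ``oscillatory`` is
    False when the series has no significant spectral peak, in which case the
    frequency is not meaningful.
    """

    decay_rate: float
    frequency: float
    amplitude: float
    phase: float
    residual: float
    oscillatory: bool = True


def _spectral_peak(t: np.ndarray, y: np.ndarray, peak_factor: float = 5.0):
    """Dominant positive frequency of a detrended series, or None when the
    peak is below ``peak_factor`` times the median periodogram level."""
    dt = float(np.median(np.diff(t)))
    yd = y - np.mean(y)
    freqs, power = periodogram(yd, fs=1.0 / dt)
    if len(freqs) < 3:
        return None
    freqs, power = freqs[1:], power[1:]
    med = np.median(power)
    i = int(np.argmax(power))
    # a genuine oscillation needs >= ~3 periods in the window; peaks in the
    # first two bins are indistinguishable from aperiodic drift or pure decay
    if i < 2 or med <= 0 or power[i] < peak_factor * med:
        return None
    return float(freqs[i])


def fit_oscillation(t: np.ndarray, y: np.ndarray,
                    peak_factor: float = 5.0) -> OscillationFit:
    """Least-squares fit of an exponentially damped sinusoid to a series such
    as <delta v^2>(t) after perturbing a laminar state.

    Initial guesses are deterministic: the frequency from the periodogram
    peak and the decay rate from the slope of the log-envelope, so identical
    inputs give identical fits.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size != y.size or t.size < 8:
        raise ValueError("need matching series with at least 8 samples")
    t0 = t[0]
    ts = t - t0
    f0 = _spectral_peak(t, y, peak_factor)
    if f0 is None:
        return OscillationFit(decay_rate=np.nan, frequency=0.0, amplitude=np.nan,
                              phase=np.nan, residual=np.nan, oscillatory=False)
    # log-envelope slope from |y| local maxima
    env_idx = argrelextrema(np.abs(y), np.greater)[0]
    if env_idx.size >= 2 and np.all(np.abs(y[env_idx]) > 0):
        lam0 = float(np.polyfit(ts[env_idx], np.log(np.abs(y[env_idx])), 1)[0])
    else:
        lam0 = 0.0
    a0 = float(np.max(np.abs(y)))

    def model(tt, a, lam, f, phase):
        return a * np.exp(lam * tt) * np.sin(2 * np.pi * f * tt + phase)

    popt, _ = curve_fit(model, ts, y, p0=[a0, lam0, f0, 0.0], maxfev=20000)
    a, lam, f, phase = popt
    if f < 0:  # sign convention: positive frequency
        f, phase = -f, -phase + np.pi
    resid = float(np.sqrt(np.mean((model(ts, *popt) - y) ** 2))
                  / max(np.sqrt(np.mean(y**2)), 1e-300))
    return OscillationFit(decay_rate=float(lam), frequency=float(f),
                          amplitude=float(a), phase=float(phase),
                          residual=resid, oscillatory=True)


def classify_flow_state(times: np.ndarray, msv_series: np.ndarray,
                        alpha: np.ndarray | None = None,
                        quiescent_msv: float = 1e-10,
                        alpha_zero_tol: float = 1.0,
                        peak_factor: float = 5.0) -> str:
    """Heuristic label for a trajectory window.

    quiescent : mean MSV below ``quiescent_msv``;
    chaotic : mean stretching number above ``alpha_zero_tol`` (1/tau_r);
    laminar_oscillatory : significant spectral peak in the MSV series;
    laminar_steady : otherwise.

    The window should span at least ~0.5 tau_r for the spectral test to be
    meaningful.
    """
    times = np.asarray(times, dtype=float)
    msv_series = np.asarray(msv_series, dtype=float)
    if times.size < 4:
        raise ValueError("window too short to classify")
    if float(np.mean(msv_series)) < quiescent_msv:
        return "quiescent"
    if alpha is not None and alpha.size and float(np.mean(alpha)) > alpha_zero_tol:
        return "chaotic"
    if _spectral_peak(times, msv_series, peak_factor) is not None:
        return "laminar_oscillatory"
    return "laminar_steady"


def count_vortices(psi: np.ndarray, floor: float = 0.01) -> int:
    """Count vortices as local extrema of psi above an amplitude floor.

    A node is an extremum when it beats its eight periodic neighbours; only
    extrema with |psi| >= floor * max|psi| count.  The laminar states are
    identified by their vortex count (2, 3, ...).
    """
    amp = np.abs(psi).max()
    if amp == 0:
        return 0
    neigh = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            neigh.append(np.roll(np.roll(psi, di, 0), dj, 1))
    neigh = np.stack(neigh)
    is_max = np.all(psi[None] > neigh, axis=0)
    is_min = np.all(psi[None] < neigh, axis=0)
    strong = np.abs(psi) >= floor * amp
    return int(np.sum((is_max | is_min) & strong))
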