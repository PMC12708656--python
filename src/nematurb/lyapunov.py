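"""Chaos quantification: maximal Lyapunov exponent, Lyapunov spectra,
stretching numbers, and the chaotic fraction.

Deviations are propagated as shadow trajectories: each companion field
``theta_tilde = theta + w`` is advanced through the full nonlinear map with
the same stepper as the reference, and the deviation ``w = theta_tilde -
theta`` is rescaled back to a small norm ``norm0`` at fixed intervals
(Benettin renormalization; Gram-Schmidt orthonormalization across companions
when more than one exponent is requested).  The norm is the Euclidean norm
over all grid nodes.  All rates are in 1/tau_r.

The maximal Lyapunov exponent of a run is the time average of the logarithmic
growth increments; stretching numbers (finite-time Lyapunov exponents) are
the same increments averaged over short windows, and the chaotic fraction of
an ensemble is the probability mass of the positive peak of the pooled
stretching-number distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelextrema
from scipy.stats import gaussian_kde

from .integrate import IntegratorConfig, Stepper, default_dt
from .model import DirectorField, GridSpec, ModelParams

__all__ = [
    "LyapunovConfig",
    "DeviationState",
    "StretchingRecord",
    "LyapunovSpectrum",
    "init_deviation",
    "evolve_with_deviation",
    "mle",
    "stretching_series",
    "lyapunov_spectrum",
    "chaotic_fraction",
]


@dataclass(frozen=True)
class LyapunovConfig:
    """Renormalization bookkeeping for deviation vectors.

    norm0 : deviation norm after each rescaling (default 1e-6).
    renorm_interval : time between rescalings, tau_r (default 1e-3).
    window : stretching-number window, tau_r (default 5e-3); must be an
        integer multiple of renorm_interval.
    m : number of exponents tracked (companions), >= 1.
    """

    norm0: float = 1e-6
    renorm_interval: float = 1e-3
    window: float = 5e-3
    m: int = 1
    seed: int | None = None

    def __post_init__(self):
        if self.norm0 <= 0 or self.renorm_interval <= 0:
            raise ValueError("norm0 and renorm_interval must be positive")
        ratio = self.window / self.renorm_interval
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError("window must be an integer multiple of renorm_interval")
        if self.m < 1:
            raise ValueError("need at least one deviation vector")

    @property
    def increments_per_window(self) -> int:
        return int(round(self.window / self.renorm_interval))


@dataclass
class DeviationState:
    """Reference field plus m shadow companions and their growth bookkeeping.

    ``increments[k, l]`` is log(||w_l|| / norm0) collected at the k-th
    renormalization for companion l (after Gram-Schmidt projection against
    companions 0..l-1).
    """

    theta: np.ndarray
    companions: np.ndarray          # (m, n, n): theta_tilde fields
    time: float = 0.0
    increments: list = field(default_factory=list)   # rows of length m

    @property
    def m(self) -> int:
        return self.companions.shape[0]

    def deviations(self) -> np.ndarray:
        return self.companions - self.theta[None]

    def increment_array(self) -> np.ndarray:
        return np.asarray(self.increments, dtype=float).reshape(-1, self.m)


def init_deviation(theta: np.ndarray | DirectorField, cfg: LyapunovConfig,
                   rng: np.random.Generator | None = None) -> DeviationState:
    """Attach m Gaussian random deviations of norm ``norm0`` to a reference
    field (orthonormalized across companions)."""
    th = theta.theta if isinstance(theta, DirectorField) else theta
    t0 = theta.time if isinstance(theta, DirectorField) else 0.0
    rng = rng or np.random.default_rng(cfg.seed)
    w = rng.normal(size=(cfg.m,) + th.shape)
    w = _orthonormalize(w)[0] * cfg.norm0
    return DeviationState(theta=th.copy(), companions=th[None] + w, time=t0)


def _orthonormalize(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Modified Gram-Schmidt over flattened fields; returns the orthonormal
    set and the pre-normalization norms (the growth factors)."""
    m = w.shape[0]
    flat = w.reshape(m, -1)
    norms = np.empty(m)
    for l in range(m):
        v = flat[l]
        for j in range(l):
            v -= (flat[j] @ v) * flat[j]
        norms[l] = np.linalg.norm(v)
        if norms[l] == 0:
            raise FloatingPointError("deviation vector collapsed to zero")
        v /= norms[l]
    return flat.reshape(w.shape), norms


def evolve_with_deviation(state: DeviationState, p: ModelParams, g: GridSpec,
                          cfg: LyapunovConfig,
                          icfg: IntegratorConfig | None = None,
                          until: float = 1.0,
                          stepper: Stepper | None = None,
                          observer=None,
                          allow_underresolved: bool = False) -> DeviationState:
    """Advance reference and companions to time ``until`` (tau_r), collecting
    log-growth increments at every renormalization.

    The reference trajectory is advanced by the same stepper regardless of m,
    so it is bitwise independent of the number of companions.  If a companion
    grows beyond the representable range between renormalizations, the
    interval is halved automatically (with a warning).
    """
    icfg = icfg or IntegratorConfig(dt=default_dt(g.n))
    st = stepper or Stepper(g, p, icfg, allow_underresolved)
    dt = icfg.dt
    renorm = cfg.renorm_interval
    steps_per_renorm = max(1, int(round(renorm / dt)))
    n_renorms = int(round((until - state.time) / (steps_per_renorm * dt)))
    norm0 = cfg.norm0

    theta = state.theta
    comps = state.companions
    for k in range(n_renorms):
        for _ in range(steps_per_renorm):
            theta = st.step(theta, t=state.time)
            for l in range(comps.shape[0]):
                comps[l] = st.step(comps[l], t=state.time)
            state.time += dt
        w = comps - theta[None]
        if not np.all(np.isfinite(w)) or np.abs(w).max() > 1e50:
            warnings.warn(
                "deviation overflow between renormalizations; halving the "
                "renormalization interval", RuntimeWarning)
            steps_per_renorm = max(1, steps_per_renorm // 2)
            renorm = steps_per_renorm * dt
            comps = theta[None] + _orthonormalize(
                np.nan_to_num(w, nan=1.0, posinf=1.0, neginf=-1.0))[0] * norm0
            continue
        w, norms = _orthonormalize(w)
        state.increments.append(np.log(norms / norm0))
        comps = theta[None] + w * norm0
        if observer is not None:
            observer(state.time, theta, st)
    state.theta = theta
    state.companions = comps
    return state


@dataclass
class StretchingRecord:
    """Finite-time Lyapunov exponents over uniform contiguous windows."""

    times: np.ndarray    # window right edges, tau_r
    alpha: np.ndarray    # stretching numbers, 1/tau_r
    window: float        # window length, tau_r


@dataclass
class LyapunovSpectrum:
    """Ordered finite-time Lyapunov exponent estimates (1/tau_r)."""

    exponents: np.ndarray
    total_time: float
    converged: bool = True


def mle(increments: np.ndarray | list, total_time: float) -> float:
    """Maximal Lyapunov exponent: summed log-growth over elapsed time.

    For multi-companion records only the first (largest) companion enters.
    """
    inc = np.asarray(increments, dtype=float)
    if inc.size == 0:
        raise ValueError("empty increment record")
    if total_time <= 0:
        raise ValueError("total_time must be positive")
    if inc.ndim == 2:
        inc = inc[:, 0]
    return float(inc.sum() / total_time)


def stretching_series(increments: np.ndarray | list, cfg: LyapunovConfig,
                      t0: float = 0.0) -> StretchingRecord:
    """Group per-renormalization increments into stretching numbers.

    Each window averages ``cfg.increments_per_window`` consecutive increments
    of the leading companion; a partial trailing window is dropped with a
    warning.
    """
    inc = np.asarray(increments, dtype=float)
    if inc.ndim == 2:
        inc = inc[:, 0]
    per = cfg.increments_per_window
    n_win = inc.size // per
    if inc.size % per:
        warnings.warn(f"dropping {inc.size % per} trailing increments not "
                      "filling a stretching window", RuntimeWarning)
    if n_win == 0:
        raise ValueError("record shorter than one stretching window")
    alpha = inc[:n_win * per].reshape(n_win, per).sum(axis=1) / cfg.window
    times = t0 + cfg.window * np.arange(1, n_win + 1)
    return StretchingRecord(times=times, alpha=alpha, window=cfg.window)


def lyapunov_spectrum(initial: np.ndarray | DirectorField, p: ModelParams,
                      g: GridSpec, cfg: LyapunovConfig, T: float,
                      icfg: IntegratorConfig | None = None,
                      rng: np.random.Generator | None = None,
                      allow_underresolved: bool = False,
                      drift_tol: float = 0.5) -> LyapunovSpectrum:
    """Estimate the m largest Lyapunov exponents over integration time T.

    Exponents are reported in descending order.  Convergence is flagged false
    when any exponent estimated from the last quarter of the run drifts from
    the full-run estimate by more than ``drift_tol * max(|spectrum|, 1/T)``.
    """
    state = init_deviation(initial, cfg, rng)
    t0 = state.time
    state = evolve_with_deviation(state, p, g, cfg, icfg, until=t0 + T,
                                  allow_underresolved=allow_underresolved)
    inc = state.increment_array()
    lam = inc.sum(axis=0) / (state.time - t0)
    k4 = max(1, 3 * inc.shape[0] // 4)
    lam_last = inc[k4:].sum(axis=0) / ((inc.shape[0] - k4) * cfg.renorm_interval)
    scale = max(np.abs(lam).max(), 1.0 / T)
    converged = bool(np.all(np.abs(lam_last - lam) <= drift_tol * scale))
    order = np.argsort(lam)[::-1]
    return LyapunovSpectrum(exponents=lam[order], total_time=T, converged=converged)


def chaotic_fraction(records, zero_tol: float = 1.0,
                     return_threshold: bool = False):
    """Fraction of stretching numbers in the chaotic (positive) peak.

    The pooled alpha values from all records are kernel-density smoothed
    (Gaussian kernel, Silverman bandwidth); the laminar/chaotic threshold is
    the minimum of the density between the peak nearest zero and the largest
    positive peak.  If the pooled distribution is unimodal the fraction is 0
    when the single peak sits within ``zero_tol`` (1/tau_r) of zero and 1
    when it lies above.
    """
    alphas = [r.alpha if isinstance(r, StretchingRecord) else np.asarray(r)
              for r in records]
    if not alphas or sum(a.size for a in alphas) == 0:
        raise ValueError("empty ensemble")
    pooled = np.concatenate(alphas)
    lo, hi = pooled.min(), pooled.max()
    if hi - lo < 1e-12:  # degenerate: all mass at one value
        f_c = 0.0 if abs(lo) <= zero_tol else 1.0
        return (f_c, None) if return_threshold else f_c
    kde = gaussian_kde(pooled)
    grid = np.linspace(lo, hi, 512)
    dens = kde(grid)
    peaks = argrelextrema(dens, np.greater, order=3)[0]
    # include the boundaries as candidate peaks
    if dens[0] > dens[1]:
        peaks = np.concatenate(([0], peaks))
    if dens[-1] > dens[-2]:
        peaks = np.concatenate((peaks, [dens.size - 1]))
    if peaks.size < 2:
        mode = grid[int(np.argmax(dens))]
        f_c = 0.0 if abs(mode) <= zero_tol else 1.0
        return (f_c, None) if return_threshold else f_c
    near_zero = peaks[int(np.argmin(np.abs(grid[peaks])))]
    if grid[near_zero] > zero_tol:
        # no laminar peak at all: every mode of the distribution is chaotic
        f_c = 1.0
        return (f_c, None) if return_threshold else f_c
    positive = peaks[peaks > near_zero]
    if positive.size == 0:
        f_c = 0.0
        return (f_c, None) if return_threshold else f_c
    top_pos = positive[int(np.argmax(dens[positive]))]
    valley = grid[near_zero + int(np.argmin(dens[near_zero:top_pos + 1]))]
    f_c = float(np.mean(pooled > valley))
    return (f_c, float(valley)) if return_threshold else f_c
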