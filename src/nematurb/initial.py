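"""Initial director-angle fields.

All study inputs are generated internally: the uniformly aligned nematic
(theta = 0, director along x), aligned fields with Gaussian white-noise
bursts layered on during early integration, exact single-Fourier-mode
perturbations for linear-theory tests, and band-limited random smooth fields.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as sfft

from .model import DirectorField, GridSpec

__all__ = ["initial_condition"]


def initial_condition(kind: str, g: GridSpec, rng=None, *, angle: float = 0.0,
                      mode: tuple[int, int] = (0, 1), amplitude: float = 1e-6,
                      phase: float = 0.0, k_cut: int = 4,
                      seed: int | None = None) -> DirectorField:
    """Build a reproducible initial director field.

    kinds:
      aligned       uniform theta = angle (default 0, director along x);
      single_mode   theta = angle + amplitude * sin(kx x + ky y + phase) with
                    (kx, ky) = 2*pi*mode, mode indices integer;
      aligned_noise theta = angle + amplitude * iid standard normals;
      random_smooth band-limited Gaussian field (modes up to k_cut per axis),
                    normalized to RMS ``amplitude``.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    shape = g.shape
    if kind == "aligned":
        theta = np.full(shape, angle, dtype=float)
    elif kind == "single_mode":
        ix, iy = mode
        if ix != int(ix) or iy != int(iy):
            raise ValueError("mode indices must be integers on the periodic grid")
        if amplitude <= 0:
            raise ValueError("amplitude must be positive")
        kx, ky = 2 * np.pi * int(ix), 2 * np.pi * int(iy)
        theta = angle + amplitude * np.sin(
            kx * g.x[:, None] + ky * g.y[None, :] + phase)
    elif kind == "aligned_noise":
        theta = angle + amplitude * rng.standard_normal(shape)
    elif kind == "random_smooth":
        spec = np.zeros((g.n, g.n // 2 + 1), dtype=complex)
        fx = np.fft.fftfreq(g.n, d=g.dx)[:, None]
        fy = np.fft.rfftfreq(g.n, d=g.dx)[None, :]
        band = (np.abs(fx) <= k_cut) & (fy <= k_cut)
        band[0, 0] = False
        vals = rng.standard_normal(band.sum()) + 1j * rng.standard_normal(band.sum())
        spec[band] = vals
        theta = sfft.irfft2(spec, s=shape)
        theta *= amplitude / max(np.sqrt(np.mean(theta**2)), 1e-300)
        theta += angle
    else:
        raise ValueError(f"unknown initial-condition kind {kind!r}")
    return DirectorField(theta=theta, time=0.0)
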