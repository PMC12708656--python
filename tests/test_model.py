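"""Spatial discretization, the spectral Stokes solve, and the director
tendency, checked against closed-form single-mode solutions and exact
symmetries of the periodic grid."""

import numpy as np
import pytest

from nematurb.model import (
    DirectorField,
    FlowFields,
    ModelParams,
    PhysicalParameters,
    director_tendency,
    make_grid,
    solve_stream_function,
    velocity_from_stream,
    vorticity_from_stream,
    warn_if_underresolved_field,
)
from conftest import smooth_random_field

TWO_PI = 2 * np.pi


class TestGrid:
    def test_spacing_and_wavenumbers(self):
        g = make_grid(256)
        assert g.dx == pytest.approx(1 / 256)
        assert g.n * g.dx == pytest.approx(1.0)
        g16 = make_grid(16)
        nonzero = np.sort(np.unique(np.abs(g16.kx[g16.kx != 0])))
        assert nonzero[0] == pytest.approx(TWO_PI)

    def test_dealias_keeps_below_two_thirds(self):
        g = make_grid(64)
        fx = np.fft.fftfreq(64, d=g.dx)[:, None]
        assert np.all(g.dealias_mask[np.abs(fx[:, 0]) > 64 / 3, :] == False)  # noqa: E712
        kept = np.abs(fx[g.dealias_mask[:, 0], 0])
        assert kept.max() == 21  # largest index below 64/3
        # symmetric under reflection k -> -k
        refl = (-np.arange(64)) % 64
        assert np.array_equal(g.dealias_mask, g.dealias_mask[refl, :])

    @pytest.mark.parametrize("n", [15, 8, 0, -4])
    def test_rejects_bad_sizes(self, n):
        with pytest.raises(ValueError):
            make_grid(n)


class TestParams:
    @pytest.mark.parametrize("kw", [dict(A=-1.0), dict(A=0.0),
                                    dict(A=1.0, R=0.0), dict(A=1.0, S=0),
                                    dict(A=1.0, time_unit="seconds")])
    def test_validation(self, kw):
        with pytest.raises(ValueError):
            ModelParams(**kw)

    def test_physical_parameters_reproduce_dimensionless_groups(self):
        ph = PhysicalParameters(eta=2.0, zeta=-3.0, K=0.5, gamma=4.0, L=1.0)
        p = ph.to_model_params()
        assert p.R == pytest.approx(2.0)
        assert p.S == -1
        assert p.A == pytest.approx(ph.L**2 / ph.ell_c**2)
        # tau_r / tau_a = A holds identically
        assert ph.tau_r / ph.tau_a == pytest.approx(p.A)


class TestStreamSolve:
    def test_uniform_director_is_flowless(self, grid64):
        for const in (0.0, 0.3, np.pi / 2):
            fl = solve_stream_function(np.full(grid64.shape, const),
                                       ModelParams(A=200.0), grid64)
            assert np.abs(fl.psi).max() < 1e-14
            assert np.abs(fl.vx).max() < 1e-14
            assert np.abs(fl.vy).max() < 1e-14

    @pytest.mark.parametrize("A,S,mode", [(500.0, -1, (0, 1)), (200.0, -1, (1, 0)),
                                          (500.0, 1, (0, 2))])
    def test_linear_single_mode_response(self, grid64, A, S, mode):
        # linearized closed form: psi_hat = [-R/(2A) + S(kx^2-ky^2)/k^4] theta_hat
        g = grid64
        eps = 1e-6
        kx, ky = TWO_PI * mode[0], TWO_PI * mode[1]
        theta = eps * np.sin(kx * g.x[:, None] + ky * g.y[None, :])
        p = ModelParams(A=A, S=S)
        coef = -p.R / (2 * A) + S * (kx**2 - ky**2) / (kx**2 + ky**2) ** 2
        fl = solve_stream_function(theta, p, g)
        assert np.abs(fl.psi - coef * theta).max() < 1e-11 * eps

    def test_worked_example_coefficient(self, grid64):
        # theta = eps sin(2 pi y), S=-1, R=1, A=500:
        # psi = [1/(4 pi^2) - 1/1000] theta to linear order
        g = grid64
        eps = 1e-6
        theta = eps * np.sin(TWO_PI * g.y)[None, :] * np.ones((g.n, 1))
        fl = solve_stream_function(theta, ModelParams(A=500.0), g)
        coef = 1 / (4 * np.pi**2) - 1 / (2 * 500.0)
        assert np.abs(fl.psi - coef * theta).max() < 1e-12 * eps

    def test_translation_equivariance(self, grid64, rng):
        g = grid64
        theta = smooth_random_field(g, rng)
        p = ModelParams(A=300.0)
        fl = solve_stream_function(theta, p, g)
        fl_shift = solve_stream_function(np.roll(theta, 1, axis=0), p, g)
        assert np.abs(fl_shift.psi - np.roll(fl.psi, 1, axis=0)).max() < 1e-12

    def test_rejects_nonfinite(self, grid64):
        theta = np.zeros(grid64.shape)
        theta[0, 0] = np.nan
        with pytest.raises(ValueError):
            solve_stream_function(theta, ModelParams(A=100.0), grid64)


class TestVelocityVorticity:
    def test_constant_stream_function(self, grid64):
        vx, vy = velocity_from_stream(np.full(grid64.shape, 2.0), grid64)
        assert np.abs(vx).max() < 1e-14 and np.abs(vy).max() < 1e-14
        assert np.abs(vorticity_from_stream(np.full(grid64.shape, 2.0),
                                            grid64)).max() < 1e-12

    def test_single_mode_derivatives(self, grid64):
        g = grid64
        psi = np.sin(TWO_PI * g.y)[None, :] * np.ones((g.n, 1))
        vx, vy = velocity_from_stream(psi, g)
        assert np.allclose(vx, TWO_PI * np.cos(TWO_PI * g.y)[None, :], atol=1e-10)
        assert np.abs(vy).max() < 1e-10
        omega = vorticity_from_stream(psi, g)
        assert np.allclose(omega, 4 * np.pi**2 * psi, atol=1e-9)

    def test_incompressibility_spectral(self, grid64, rng):
        g = grid64
        psi = smooth_random_field(g, rng)
        vx, vy = velocity_from_stream(psi, g)
        div = (np.fft.irfft2(1j * g.kx * np.fft.rfft2(vx), s=g.shape)
               + np.fft.irfft2(1j * g.ky * np.fft.rfft2(vy), s=g.shape))
        assert np.abs(div).max() <= 1e-10

    def test_vorticity_equivariance(self, grid64, rng):
        g = grid64
        psi = smooth_random_field(g, rng)
        shifted = vorticity_from_stream(np.roll(psi, 3, axis=1), g)
        assert np.allclose(shifted, np.roll(vorticity_from_stream(psi, g), 3, axis=1),
                           atol=1e-11)


class TestDirectorTendency:
    def test_uniform_fixed_point(self, grid64):
        zero_flow = FlowFields(*(np.zeros(grid64.shape) for _ in range(4)))
        out = director_tendency(np.full(grid64.shape, 0.4), zero_flow,
                                ModelParams(A=123.0), grid64)
        assert np.abs(out).max() == 0.0

    def test_pure_diffusion_mode(self, grid64):
        g = grid64
        eps = 1e-6
        theta = eps * np.sin(TWO_PI * g.x)[:, None] * np.ones((1, g.n))
        zero_flow = FlowFields(*(np.zeros(g.shape) for _ in range(4)))
        p = ModelParams(A=500.0, time_unit="tau_a")
        out = director_tendency(theta, zero_flow, p, g)
        k2_fd = (2 - 2 * np.cos(TWO_PI * g.dx)) / g.dx**2  # discrete Laplacian symbol
        assert np.allclose(out, -(k2_fd / 500.0) * theta, rtol=1e-10)

    def test_vortical_source(self, grid64):
        # theta = 0, psi = sin(2 pi y): tendency = -(1/2) lap psi = 2 pi^2 psi
        g = grid64
        psi = np.sin(TWO_PI * g.y)[None, :] * np.ones((g.n, 1))
        vx, vy = velocity_from_stream(psi, g)
        flow = FlowFields(psi=psi, vx=vx, vy=vy,
                          omega=vorticity_from_stream(psi, g))
        p = ModelParams(A=100.0, time_unit="tau_a")
        out = director_tendency(np.zeros(g.shape), flow, p, g)
        assert np.allclose(out, 2 * np.pi**2 * psi, atol=1e-8)

    def test_tau_r_rescaling(self, grid64, rng):
        g = grid64
        theta = smooth_random_field(g, rng)
        flow = solve_stream_function(theta, ModelParams(A=250.0), g)
        out_a = director_tendency(theta, flow, ModelParams(A=250.0, time_unit="tau_a"), g)
        out_r = director_tendency(theta, flow, ModelParams(A=250.0), g)
        assert np.allclose(out_r, 250.0 * out_a, rtol=1e-12)


def test_underresolution_warning(grid32):
    theta = np.zeros(grid32.shape)
    theta[5, 5] = 2.0  # > pi/2 jump to neighbours
    with pytest.warns(RuntimeWarning):
        assert warn_if_underresolved_field(theta)
    assert not warn_if_underresolved_field(np.zeros(grid32.shape))
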