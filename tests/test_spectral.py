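"""Spectral basis of the Fokker-Planck operator, theoretical finite-size
spectra and the reduced rate-equation integrator."""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import root

from spikefp.delays import DelayKernel
from spikefp.gain import rate
from spikefp.meanfield import (
    SynapticConfig,
    self_consistent_rate,
    total_moments,
)
from spikefp.spectral import (
    BasisLattice,
    build_basis,
    integrate_rate_equation,
    theoretical_psd,
    theoretical_psd_exact,
    _diffusion,
    _mu_ext_offset,
)


def _mu_eq(config, model, nu):
    return model.tau_m * config.J * config.C * nu * 1e-3


@pytest.fixture(scope="module")
def vif_dd_basis(vif, vif_dd_config):
    fp = self_consistent_rate(vif_dd_config, vif)
    mu_y = _mu_eq(vif_dd_config, vif, fp.nu)
    basis = build_basis(mu_y, vif_dd_config, vif, n_modes=32, grid_points=384,
                        with_modes=True)
    return fp, basis


class TestBasisStructure:
    def test_stationary_mode_and_gain_match(self, vif, vif_dd_config, vif_dd_basis):
        fp, basis = vif_dd_basis
        assert abs(basis.lambda00) < 1e-8
        phi_gain = rate(total_moments(fp.nu, vif_dd_config, vif), vif)
        assert basis.Phi0 == pytest.approx(phi_gain, rel=0.01)

    def test_stationary_density_normalized_and_nonnegative(self, vif_dd_basis):
        _, basis = vif_dd_basis
        assert basis.phi0.sum() * basis.dx == pytest.approx(1.0, rel=1e-10)
        assert basis.phi0.min() > -1e-8 * basis.phi0.max()

    def test_nonstationary_modes_decay_in_conjugate_pairs(self, vif_dd_basis):
        _, basis = vif_dd_basis
        assert np.all(basis.lam.real < 0)
        cplx = basis.lam[np.abs(basis.lam.imag) > 1e-12]
        paired = np.sort_complex(cplx)
        assert np.allclose(np.sort_complex(np.conj(cplx)), paired)

    def test_biorthonormality(self, vif_dd_basis):
        _, basis = vif_dd_basis
        G = (basis.psi.T @ basis.phi) * basis.dx
        assert np.abs(G - np.eye(G.shape[0])).max() < 1e-8

    def test_uncoupled_network_has_zero_synaptic_couplings(self, vif):
        cfg = SynapticConfig(N=1000, C=0, J=0.0, J_ext=0.02, C_ext=300,
                             nu_ext=10.0, I_DC=0.0)
        b = build_basis(0.0, cfg, vif, n_modes=8, grid_points=256)
        assert np.all(b.w0 == 0.0) and np.all(b.W0 == 0.0)

    def test_lif_basis_matches_siegert(self, lif, lif_dd_config):
        fp = self_consistent_rate(lif_dd_config, lif)
        mu_y = _mu_eq(lif_dd_config, lif, fp.nu)
        b = build_basis(mu_y, lif_dd_config, lif, n_modes=8, grid_points=384)
        assert b.Phi0 == pytest.approx(fp.nu, rel=0.01)

    def test_degenerate_diffusion_rejected(self, vif):
        cfg = SynapticConfig(N=1000, C=100, J=0.0075, sigma_ext=0.0)
        with pytest.raises(ValueError, match="degenerate|diffusion"):
            build_basis(-0.5, cfg, vif, n_modes=4, grid_points=128,
                        sigma_ext_floor=0.0)


class TestSlowestEigenvalueOracle:
    def test_vif_slowest_mode_matches_characteristic_equation(
            self, vif, vif_dd_config, vif_dd_basis):
        """The grid eigenvalue is checked against a grid-free shooting
        solution: for the constant-drift operator the eigenfunctions are
        exponentials exp(r x) with r(lambda) from the characteristic
        polynomial, and the absorbing + flux-conservation boundary
        conditions give a transcendental equation for lambda."""
        fp, basis = vif_dd_basis
        mu_y = basis.mu_y
        v = (mu_y + _mu_ext_offset(vif_dd_config, vif)) / vif.tau_m
        D = _diffusion(vif_dd_config, vif, mu_y, 1e-2)

        def det(lam):
            disc = np.sqrt(v * v + 4 * D * lam + 0j)
            r1, r2 = (v + disc) / (2 * D), (v - disc) / (2 * D)
            # phi(1) = 0 and F(0) = F(1) with F = v phi - D phi'
            m11, m12 = np.exp(r1), np.exp(r2)
            m21 = (v - D * r1) * (1 - np.exp(r1))
            m22 = (v - D * r2) * (1 - np.exp(r2))
            return m11 * m22 - m12 * m21

        lam0 = basis.lam[0]
        sol = root(lambda x: [det(x[0] + 1j * x[1]).real,
                              det(x[0] + 1j * x[1]).imag],
                   [lam0.real, lam0.imag], tol=1e-13)
        assert sol.success
        lam_exact = sol.x[0] + 1j * sol.x[1]
        assert abs(lam0 - lam_exact) < 0.02 * abs(lam_exact)


class TestTheoreticalPsd:
    def test_spectrum_real_positive_even(self, vif, vif_dd_config, vif_dd_basis):
        fp, basis = vif_dd_basis
        f = np.linspace(1.0, 200.0, 100)
        sp_pos = theoretical_psd(f, basis, fp.nu, 2000, vif_dd_config, vif,
                                 kernel=DelayKernel.fixed(10.0))
        sp_neg = theoretical_psd(-f, basis, fp.nu, 2000, vif_dd_config, vif,
                                 kernel=DelayKernel.fixed(10.0))
        assert np.all(np.isreal(sp_pos.P)) and np.all(sp_pos.P > 0)
        np.testing.assert_allclose(sp_pos.P, sp_neg.P, rtol=1e-10)

    def test_uncoupled_spectrum_is_pure_numerator(self, vif):
        cfg = SynapticConfig(N=1000, C=0, J=0.0, J_ext=0.02, C_ext=300,
                             nu_ext=10.0, I_DC=0.0)
        b = build_basis(0.0, cfg, vif, n_modes=16, grid_points=256)
        nu0 = b.Phi0
        f = np.linspace(1.0, 300.0, 60)
        sp = theoretical_psd(f, b, nu0, 1000, cfg, vif, slope=0.0)
        numer = 1.0 + 2.0 * np.real(np.sum(
            (b.f0 * 1e-3)[None, :] * b.psi0[None, :]
            / (2j * np.pi * f[:, None] * 1e-3 - b.lam[None, :]), axis=1))
        np.testing.assert_allclose(sp.P_normalized, numer, rtol=1e-12)
        np.testing.assert_allclose(sp.P, numer * nu0 / 1000, rtol=1e-12)

    def test_high_frequency_shot_noise_floor(self, vif, vif_nd_config):
        fp = self_consistent_rate(vif_nd_config, vif)
        f = np.linspace(3000.0, 6000.0, 20)
        sp = theoretical_psd_exact(f, vif_nd_config, vif, fp.nu, 2000,
                                   kernel=DelayKernel.exponential(4.0),
                                   grid_points=384)
        assert np.all(np.abs(sp.P_normalized - 1.0) < 0.02)

    def test_filter_and_exponential_delays_bitwise_equal(
            self, vif, vif_dd_config, vif_dd_basis):
        fp, basis = vif_dd_basis
        f = np.linspace(1.0, 200.0, 150)
        sp_filter = theoretical_psd(f, basis, fp.nu, 2000, vif_dd_config, vif,
                                    kernel=DelayKernel.none(), tau_s=32.0)
        sp_delay = theoretical_psd(f, basis, fp.nu, 2000, vif_dd_config, vif,
                                   kernel=DelayKernel.exponential(32.0), tau_s=0.0)
        assert np.array_equal(sp_filter.P, sp_delay.P)

    def test_invariant_under_biorthogonal_rescaling(
            self, vif, vif_dd_config, vif_dd_basis):
        fp, basis = vif_dd_basis
        rng = np.random.default_rng(5)
        c = rng.uniform(0.5, 2.0, basis.n_modes) * np.exp(
            1j * rng.uniform(-np.pi, np.pi, basis.n_modes))
        scaled = dataclasses.replace(
            basis,
            f0=basis.f0 * c,
            psi0=basis.psi0 / c,
            w0=basis.w0 / c,
            W0=basis.W0 * (c[None, :] / c[:, None]),
        )
        f = np.linspace(1.0, 100.0, 60)
        kern = DelayKernel.fixed_plus_exponential(10.0, 4.0)
        p1 = theoretical_psd(f, basis, fp.nu, 2000, vif_dd_config, vif, kernel=kern)
        p2 = theoretical_psd(f, scaled, fp.nu, 2000, vif_dd_config, vif, kernel=kern)
        np.testing.assert_allclose(p1.P, p2.P, rtol=1e-9)

    def test_resolvent_matches_mode_sum_when_converged(self, vif, vif_nd_config):
        # noise-dominated regime: the mode expansion converges quickly
        fp = self_consistent_rate(vif_nd_config, vif)
        mu_y = _mu_eq(vif_nd_config, vif, fp.nu)
        b = build_basis(mu_y, vif_nd_config, vif, n_modes=200, grid_points=384,
                        v_min=0.0)
        f = np.linspace(1.0, 200.0, 40)
        kern = DelayKernel.fixed(10.05)
        p_modes = theoretical_psd(f, b, fp.nu, 2000, vif_nd_config, vif, kernel=kern)
        p_res = theoretical_psd_exact(f, vif_nd_config, vif, fp.nu, 2000,
                                      kernel=kern, grid_points=384)
        np.testing.assert_allclose(p_modes.P_normalized, p_res.P_normalized,
                                   rtol=0.05)

    def test_transmission_resonance_position(self, vif, vif_dd_config):
        # delta = 10 ms with tau_s = 32 ms: lowest transmission resonance
        # expected near 1/(delta + tau_s) = 23.8 Hz
        from scipy.signal import find_peaks

        fp = self_consistent_rate(vif_dd_config, vif)
        f = np.linspace(12.0, 45.0, 331)
        sp = theoretical_psd_exact(f, vif_dd_config, vif, fp.nu, 2000,
                                   kernel=DelayKernel.fixed(10.0), tau_s=32.0,
                                   grid_points=384)
        peaks, _ = find_peaks(sp.P_normalized)
        assert any(abs(f[p] - 1000.0 / 42.0) < 2.5 for p in peaks)


@pytest.fixture(scope="module")
def vif_lattice(vif, vif_dd_config):
    fp = self_consistent_rate(vif_dd_config, vif)
    mu_eq = _mu_eq(vif_dd_config, vif, fp.nu)
    lat = BasisLattice(np.linspace(0.5 * mu_eq, 1.5 * mu_eq, 5),
                       vif_dd_config, vif, n_modes=8, grid_points=256)
    return fp, lat


def test_small_tau_limit_matches_white_noise_density_equation(vif, vif_dd_config):
    """For vanishing synaptic time constant the filtered mean current tracks
    mu_I instantaneously and the reduced rate equation reproduces the
    white-noise (instantaneous-feedback) 1-D FP response to a drive step."""
    from spikefp.fp1d import integrate_density
    from spikefp.meanfield import self_consistent_rate

    drive = lambda t: vif_dd_config.nu_ext * (1.0 if t < 100.0 else 1.03)
    fp = self_consistent_rate(vif_dd_config, vif)
    mu_eq = vif.tau_m * vif_dd_config.J * vif_dd_config.C * fp.nu * 1e-3
    lat = BasisLattice(np.linspace(0.6 * mu_eq, 2.0 * mu_eq, 8),
                       vif_dd_config, vif, n_modes=6, grid_points=320)
    tr = integrate_rate_equation(lat, vif_dd_config, vif, T=400.0, dt=0.01,
                                 N=None, tau=1e-3, drive=drive, nu0=fp.nu)
    # mu_y tracks mu_I of the (delay-buffered) feedback rate instantaneously
    mu_I_delayed = (vif.tau_m * vif_dd_config.J * vif_dd_config.C
                    * tr.nu_N[-1001] * 1e-3)
    assert abs(tr.mu_y[-1] - mu_I_delayed) < 1e-6
    ref = integrate_density(vif_dd_config, vif, T=400.0, dt=0.02,
                            grid_points=384, drive=drive, tau=0.0)
    nu_re = tr.nu.reshape(-1, 100).mean(axis=1)[150:]
    nu_fp = ref.nu.reshape(-1, 50).mean(axis=1)[150:]
    assert np.abs(nu_re - nu_fp).max() / nu_fp.max() < 0.05


def test_basis_cache_round_trip(tmp_path, vif_dd_basis):
    from spikefp.spectral import load_basis, save_basis

    _, basis = vif_dd_basis
    path = tmp_path / "basis.npz"
    save_basis(basis, path)
    loaded = load_basis(path)
    np.testing.assert_array_equal(loaded.lam, basis.lam)
    np.testing.assert_array_equal(loaded.w0, basis.w0)
    assert loaded.Phi0 == basis.Phi0 and loaded.mu_y == basis.mu_y


class TestRateEquation:
    def test_equilibrium_is_stationary(self, vif, vif_dd_config, vif_lattice):
        fp, lat = vif_lattice
        # start exactly at the lattice's own fixed point
        from scipy.optimize import brentq

        mu_I = lambda nu: _mu_eq(vif_dd_config, vif, nu)
        nu_eq = brentq(lambda nu: lat.at(mu_I(nu))[0] - nu, 5.0, 15.0, xtol=1e-10)
        tr = integrate_rate_equation(lat, vif_dd_config, vif, T=1000.0, dt=0.02,
                                     N=None, tau=32.0, seed=0, nu0=nu_eq)
        assert np.max(np.abs(tr.nu / nu_eq - 1.0)) < 1e-6
        assert tr.clipped_steps == 0

    def test_relaxation_back_to_equilibrium(self, vif, vif_dd_config, vif_lattice):
        fp, lat = vif_lattice
        tr = integrate_rate_equation(lat, vif_dd_config, vif, T=3000.0, dt=0.02,
                                     N=None, tau=4.0, seed=0, nu0=1.2 * fp.nu)
        assert tr.nu[-1] == pytest.approx(fp.nu, rel=0.02)

    def test_too_large_timestep_rejected(self, vif, vif_dd_config, vif_lattice):
        _, lat = vif_lattice
        lam_max = np.max(np.abs(lat.lam.real))
        with pytest.raises(ValueError, match="unstable"):
            integrate_rate_equation(lat, vif_dd_config, vif, T=10.0,
                                    dt=1.0 / lam_max, N=None, tau=4.0)

    def test_finite_size_noise_has_shot_noise_variance_scale(
            self, vif, vif_dd_config, vif_lattice):
        fp, lat = vif_lattice
        dt, N = 0.05, 2000
        tr = integrate_rate_equation(lat, vif_dd_config, vif, T=2000.0, dt=dt,
                                     N=N, tau=32.0, seed=3, nu0=fp.nu)
        eta = tr.nu_N - tr.nu
        expected_var = fp.nu / (N * dt * 1e-3)  # Hz^2 per bin
        assert np.var(eta[2000:]) == pytest.approx(expected_var, rel=0.1)
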