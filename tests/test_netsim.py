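"""Microscopic simulator: reproducibility, protocol equivalences at the
single-synapse level, external-drive statistics and network rates."""

import dataclasses

import numpy as np
import pytest

from spikefp.delays import DelayKernel
from spikefp.meanfield import SynapticConfig, self_consistent_rate
from spikefp.models import lif_neuron
from spikefp.netsim import (
    NetworkSpec,
    Population,
    Projection,
    build_multimodular,
    multimodular_J_ext,
    simulate,
    single_population_spec,
)


class TestContracts:
    def test_quiescent_without_input(self, lif):
        pop = Population("E", 50, lif)
        spec = NetworkSpec(populations=(pop,), dt=0.05, seed=0)
        out = simulate(spec, 200.0)
        assert out.meta["n_spikes"] == 0

    def test_bit_reproducible_given_seed(self, vif, vif_dd_config):
        spec = single_population_spec(vif_dd_config, vif, N=400, seed=11)
        a = simulate(spec, 1500.0)
        b = simulate(spec, 1500.0)
        assert np.array_equal(a.spikes, b.spikes)
        c = simulate(dataclasses.replace(spec, seed=12), 1500.0)
        assert not np.array_equal(a.spikes, c.spikes)

    def test_bin_integral_equals_spike_count(self, vif, vif_dd_config):
        spec = single_population_spec(vif_dd_config, vif, N=400, seed=2)
        out = simulate(spec, 1000.0)
        N = out.meta["N"][0]
        dt_bin = out.t_bins[1] - out.t_bins[0]
        total = out.nu[:, 0].sum() * N * dt_bin * 1e-3
        counted = np.sum(out.spikes[:, 0] < out.t_bins[-1] + dt_bin / 2)
        assert total == pytest.approx(counted, abs=0.5)

    def test_empty_population_rejected(self, lif):
        with pytest.raises(ValueError, match="empty"):
            simulate(NetworkSpec(populations=(Population("E", 0, lif),)), 10.0)


def test_network_spec_json_round_trip(vif, vif_dd_config):
    spec = single_population_spec(vif_dd_config, vif, N=100, protocol="cascade",
                                  tau=8.0, seed=5)
    again = NetworkSpec.from_json(spec.to_json())
    assert again == spec


class TestChargeEquivalence:
    @pytest.mark.parametrize("tau_s", [2.0, 5.0, 10.0])
    def test_single_psp_integral_matches_delta_jump(self, tau_s):
        """One presynaptic spike must deliver the same time-integrated
        depolarization J*tau_m through a delta synapse and through a
        first-order filtered synapse (tau_s <= tau_m/2)."""
        model = lif_neuron(tau_m=20.0, C_m=500.0, v_thr=1e6, v_res=0.0)
        J = 0.5
        src = Population("S", 1, model, C_ext=1, nu_ext=20.0, J_ext=2e6,
                         I_DC=0.0)  # forced to fire by huge external jumps
        integrals = {}
        for mode in ("delays", "filter"):
            tgt = Population("T", 1, model, tau_s=(tau_s if mode == "filter" else 0.0))
            proj = Projection("S", "T", C=1, J=J, mode=mode, delta_min=1.0)
            spec = NetworkSpec(populations=(src, tgt), projections=(proj,),
                               dt=0.005, seed=4, n_tagged=2, tag_stride=1)
            out = simulate(spec, 400.0)
            V_t = out.tagged_V[:, 1]
            integrals[mode] = np.trapezoid(V_t, dx=0.005)
        n_spk = np.sum(simulate(
            NetworkSpec(populations=(src,), dt=0.005, seed=4), 400.0).nu) * 0.1 * 1e-3
        assert integrals["delays"] > 0
        assert integrals["filter"] == pytest.approx(integrals["delays"], rel=0.01)


class TestExternalDrive:
    def test_filtered_current_has_ou_stationary_moments(self):
        """Isolated subthreshold LIF driven by filtered Poisson spikes: the
        synaptic current in voltage units (u = R*I) is an Ornstein-Uhlenbeck
        process with stationary mean mu_I = tau_m J C nu and variance
        tau_m sigma_I^2 / (2 tau_s) (Campbell's theorem for jumps
        tau_m J / tau_s relaxing with tau_s)."""
        model = lif_neuron(tau_m=10.0, C_m=500.0, v_thr=1e6, v_res=0.0)
        tau_s, J, C, src_hz = 4.0, 0.1, 20, 400.0
        n = 100
        n_src = 40 * n
        pop_src = Population("S", n_src, model, C_ext=1, nu_ext=src_hz, J_ext=1e7)
        pop = Population("T", n, model, tau_s=tau_s)
        proj = Projection("S", "T", C=C, J=J, mode="filter", delta_min=0.1)
        spec = NetworkSpec(populations=(pop_src, pop), projections=(proj,),
                           dt=0.01, seed=8, n_tagged=n_src + n, tag_stride=10)
        out = simulate(spec, 3000.0)
        u = out.tagged_u[out.tagged_t > 500.0, n_src:]
        rate_hz = C * src_hz
        mu_I = model.tau_m * J * rate_hz * 1e-3
        sigma_I2 = model.tau_m * J**2 * rate_hz * 1e-3
        var_expected = model.tau_m * sigma_I2 / (2 * tau_s)
        mean_se = u.mean(axis=0).std() / np.sqrt(n)
        assert abs(u.mean() - mu_I) < 3 * max(mean_se, 1e-3)
        var_per = u.var(axis=0)
        var_se = var_per.std() / np.sqrt(n)
        # allow for the O(lam) Bernoulli and O(dt/tau_s) Euler corrections of
        # the discrete-time process on top of the statistical error
        assert abs(var_per.mean() - var_expected) < 3 * var_se + 0.015 * var_expected

    def test_diffusion_and_poisson_drives_agree(self, lif, lif_dd_config):
        rates = {}
        for pois in (True, False):
            spec = single_population_spec(lif_dd_config, lif, N=1000, seed=21,
                                          poisson_ext=pois)
            out = simulate(spec, 6000.0)
            m = out.t_bins >= 1000.0
            per_bin = out.nu[m, 0]
            rates[pois] = (per_bin.mean(), per_bin.std() / np.sqrt(m.sum() / 500))
        diff = abs(rates[True][0] - rates[False][0])
        se = np.hypot(rates[True][1], rates[False][1])
        assert diff < 3 * max(se, 0.3)


class TestNetworkRates:
    def test_vif_dd_network_rate_near_design_point(self, vif, vif_dd_config):
        fp = self_consistent_rate(vif_dd_config, vif)
        spec = single_population_spec(vif_dd_config, vif, seed=3)
        out = simulate(spec, 8000.0)
        assert out.mean_rate(0) == pytest.approx(fp.nu, rel=0.15)

    def test_mean_rate_insensitive_to_time_step(self, vif, vif_dd_config):
        r = {}
        for dt in (0.05, 0.025):
            spec = single_population_spec(vif_dd_config, vif, seed=5, dt=dt)
            r[dt] = simulate(spec, 6000.0).mean_rate(0)
        assert r[0.025] == pytest.approx(r[0.05], rel=0.02)

    def test_delay_protocol_rate_invariant_in_tau(self, vif, vif_dd_config):
        """Under stationary conditions the delay-distribution network fires
        at the same mean rate for any tau_d (the delayed feedback rate
        coincides with the equilibrium rate)."""
        rates = []
        for tau in (0.0, 32.0):
            spec = single_population_spec(vif_dd_config, vif, protocol="delays",
                                          tau=tau, seed=6)
            rates.append(simulate(spec, 6000.0).mean_rate(0))
        assert rates[1] == pytest.approx(rates[0], rel=0.02)


class TestMultimodular:
    def test_external_efficacy_quadratic(self):
        assert multimodular_J_ext(0.0) == pytest.approx(0.0485, abs=1e-12)
        c = 50.0
        assert multimodular_J_ext(c) == pytest.approx(
            (9.56e-5 * c + 0.0234) * c + 0.0485, rel=1e-12)

    def test_structure_and_contact_replacement(self):
        spec = build_multimodular(50.0, tau=4.0, protocol="filter")
        labels = [p.label for p in spec.populations]
        assert labels == ["E", "I"]
        assert spec.populations[0].N == 4000 and spec.populations[1].N == 1000
        # recurrent E contacts replace external ones: C_EE + C_E,ext = 1800
        proj_EE = next(p for p in spec.projections
                       if p.source == "E" and p.target == "E")
        assert proj_EE.C + spec.populations[0].C_ext == 1800
        proj_EI = next(p for p in spec.projections
                       if p.source == "I" and p.target == "E")
        assert proj_EI.C == 500 and proj_EI.J == -0.05

    def test_exchange_variant_conserves_excitatory_indegree(self):
        spec = build_multimodular(1.0, tau=16.0, protocol="filter",
                                  ext_fraction=0.4)
        proj_IE = next(p for p in spec.projections
                       if p.source == "E" and p.target == "I")
        assert proj_IE.C + spec.populations[1].C_ext == 1800

    def test_out_of_range_percentage_rejected(self):
        with pytest.raises(ValueError):
            build_multimodular(120.0)

    def test_uncoupled_multimodular_runs_and_is_nearly_silent(self):
        # with the printed efficacy J_ext(c=0) = 0.0485 mV the mean external
        # drive is ~17.5 mV, 2.5 sigma below threshold: the uncoupled
        # network fires far below the nominal 10 Hz (the printed values
        # fail a mean-field audit; the pipeline contract is only that it
        # runs end to end)
        spec = build_multimodular(0.0, tau=4.0, protocol="filter",
                                  N_E=400, N_I=100, C_ext=1800)
        out = simulate(spec, 2000.0)
        assert out.nu.shape[1] == 2
        assert out.mean_rate(0) < 1.0
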