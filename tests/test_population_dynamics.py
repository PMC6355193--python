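"""Unit and property tests for the per-population dynamical laws."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitsim import _kernels
from gaitsim.population_dynamics import (
    DriveLaw,
    InvalidParameterError,
    NaPParams,
    PopulationSpec,
    StateCorruptionError,
    SynapseParams,
    drive_strength,
    evaluate_currents,
    nap_inactivation_steady,
    nap_inactivation_tau,
    nap_kinetics,
    noise_step,
    output_activity,
    state_derivative,
)


class TestOutputActivity:
    @pytest.mark.parametrize(
        "v, v_thr, v_max, expected",
        [
            (-60.0, -50.0, 0.0, 0.0),  # below threshold: silent
            (0.0, -50.0, 0.0, 1.0),  # at saturation
            (-25.0, -50.0, 0.0, 0.5),  # midpoint of the linear segment
            (10.0, -50.0, 0.0, 1.0),  # above saturation stays 1
            (-50.0, -50.0, 0.0, 0.0),  # exactly at threshold
        ],
    )
    def test_piecewise_linear_values(self, v, v_thr, v_max, expected):
        assert output_activity(v, v_thr, v_max) == expected

    def test_invalid_corners_rejected(self):
        with pytest.raises(InvalidParameterError):
            output_activity(-10.0, v_thr=0.0, v_max=-50.0)

    @given(
        v1=st.floats(-100, 50),
        v2=st.floats(-100, 50),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_and_bounded(self, v1, v2):
        lo, hi = min(v1, v2), max(v1, v2)
        f_lo, f_hi = output_activity(lo), output_activity(hi)
        assert 0.0 <= f_lo <= f_hi <= 1.0


class TestDriveLaw:
    @pytest.mark.parametrize(
        "alpha, m, b, expected",
        [
            (0.0, 1.35, 3.95, 3.95),
            (1.0, 1.35, 3.95, 5.30),
            (1.05, 1.1, 2.45, 3.605),
        ],
    )
    def test_linear_law(self, alpha, m, b, expected):
        assert drive_strength(alpha, m, b) == pytest.approx(expected, abs=1e-12)

    def test_drive_law_object_matches_function(self):
        law = DriveLaw("CnF-Glu", "left", m=1.5, b=4.0)
        assert law(0.4) == drive_strength(0.4, 1.5, 4.0)


class TestNaPKinetics:
    def test_closed_gate_zero_current(self):
        p = NaPParams()
        for v in (-80.0, -40.0, 0.0):
            i_nap, _ = nap_kinetics(v, 0.0, p)
            assert i_nap == 0.0

    def test_inactivation_midpoint(self):
        p = NaPParams()
        assert nap_inactivation_steady(p.h_half, p) == pytest.approx(0.5)
        assert nap_inactivation_tau(p.h_half, p) == pytest.approx(p.tau_max)

    def test_gate_out_of_range_rejected(self):
        with pytest.raises(StateCorruptionError):
            nap_kinetics(-50.0, 1.5, NaPParams())

    @pytest.mark.parametrize("v_hold, h0", [(-60.0, 0.0), (-40.0, 1.0), (-30.0, 0.3)])
    def test_gate_relaxes_to_steady_state(self, v_hold, h0):
        # At fixed V the gate ODE is linear; after five time constants the
        # numerically integrated gate must sit at h_inf within 1e-3.
        p = NaPParams()
        tau = float(nap_inactivation_tau(v_hold, p))
        h = h0
        dt = tau / 2000.0
        for _ in range(5 * 2000):
            _, dh = nap_kinetics(v_hold, h, p)
            h += dt * dh
        h_inf = float(nap_inactivation_steady(v_hold, p))
        analytic = h_inf + (h0 - h_inf) * math.exp(-5.0)
        assert h == pytest.approx(analytic, abs=1e-4)
        assert h == pytest.approx(h_inf, abs=1e-3 + abs(h0 - h_inf) * math.exp(-5.0))


def _plain_spec(**kw):
    defaults = dict(name="X", side="left", compartment="CnF", g_l=5.0, e_l=-60.0)
    defaults.update(kw)
    return PopulationSpec(**defaults)


class TestEvaluateCurrents:
    def test_rest_with_no_inputs_is_equilibrium(self):
        spec = _plain_spec()
        i_l, i_se, i_si = evaluate_currents(spec.e_l, spec, SynapseParams(), 0.0, 0.0, 0.0)
        assert (i_l, i_se, i_si) == (0.0, 0.0, 0.0)

    def test_zero_conductance_means_zero_excitatory_current(self):
        spec = _plain_spec()
        for v in (-80.0, -30.0, 10.0):
            _, i_se, _ = evaluate_currents(v, spec, SynapseParams(), 0.0, 0.0, 0.0)
            assert i_se == 0.0

    def test_zero_driving_force_means_zero_inhibitory_current(self):
        syn = SynapseParams()
        _, _, i_si = evaluate_currents(syn.e_syn_i, _plain_spec(), syn, 0.3, 2.0, 0.0)
        assert i_si == 0.0

    def test_negative_weighted_input_rejected(self):
        with pytest.raises(InvalidParameterError):
            evaluate_currents(-50.0, _plain_spec(), SynapseParams(), -0.1, 0.0, 0.0)

    def test_negative_drive_clamped_to_zero_conductance(self):
        spec = _plain_spec()
        _, i_se, _ = evaluate_currents(-30.0, spec, SynapseParams(), 0.0, 0.0, -5.0)
        assert i_se == 0.0


class TestNoiseStep:
    def test_zero_sigma_decays_to_zero(self):
        rng = np.random.default_rng(0)
        assert noise_step(0.0, 0.1, 0.0, 10.0, rng) == 0.0
        x = 1.0
        for _ in range(10000):
            x = noise_step(x, 0.1, 0.0, 10.0, rng)
        assert abs(x) < 1e-8

    def test_identical_seed_identical_sequence(self):
        a = np.random.default_rng(42)
        b = np.random.default_rng(42)
        xa = xb = 0.0
        for _ in range(100):
            xa = noise_step(xa, 0.1, 1.0, 10.0, a)
            xb = noise_step(xb, 0.1, 1.0, 10.0, b)
            assert xa == xb

    def test_stationary_standard_deviation(self):
        # Monte-Carlo stationary SD of the OU process vs its closed form.
        rng = np.random.default_rng(7)
        sigma, tau, dt = 1.0, 10.0, 0.1
        n = 1_200_000
        increments = rng.standard_normal(n)
        x = np.empty(n)
        acc = 0.0
        k = sigma * math.sqrt(2.0 * dt / tau)
        for i in range(n):
            acc += -acc * dt / tau + k * increments[i]
            x[i] = acc
        sample_sd = x[10000:].std()
        # Euler discretisation bias is (1 - dt/(2 tau))^(-1/2) ~ 0.25 %
        assert sample_sd == pytest.approx(sigma, rel=0.02)


class TestStateDerivative:
    def _single(self, spec):
        return [spec], SynapseParams(), np.zeros((1, 1)), np.zeros(1)

    def test_isolated_plain_population_rests_at_leak_reversal(self):
        spec = _plain_spec()
        specs, syn, w, d = self._single(spec)
        dv, dh = state_derivative(
            np.array([spec.e_l]), np.array([1.0]), np.zeros(1), specs, syn, w, d
        )
        assert dv[0] == 0.0 and dh[0] == 0.0

    def test_decoupled_populations_relax_to_rest(self):
        specs = [_plain_spec(name="A", e_l=-60.0), _plain_spec(name="B", e_l=-55.0)]
        syn = SynapseParams()
        w = np.zeros((2, 2))
        d = np.zeros(2)
        v = np.array([-80.0, -40.0])
        h = np.ones(2)
        noise = np.zeros(2)
        for _ in range(20000):
            dv, _ = state_derivative(v, h, noise, specs, syn, w, d)
            v += 0.05 * dv
        assert v == pytest.approx([-60.0, -55.0], abs=1e-9)

    def test_constant_input_fixed_point_matches_analytic(self):
        # For a single plain population under constant excitatory input the
        # fixed point solves g_L (V - E_L) + gbar_E w f_in (V - E_SynE) = 0.
        spec = _plain_spec()
        syn = SynapseParams()
        w_in = 0.3  # weighted presynaptic activity, dimensionless
        g_e = syn.g_bar_e * w_in
        analytic = (spec.g_l * spec.e_l + g_e * syn.e_syn_e) / (spec.g_l + g_e)
        v = np.array([spec.e_l])
        h = np.ones(1)
        for _ in range(400000):
            i_l, i_se, i_si = evaluate_currents(v[0], spec, syn, w_in, 0.0, 0.0)
            v[0] += 0.05 * (-(i_l + i_se + i_si) / spec.C)
        assert v[0] == pytest.approx(analytic, abs=1e-6)

    def test_nonfinite_state_raises_with_population_name(self):
        spec = _plain_spec(name="Broken")
        specs, syn, w, d = self._single(spec)
        with pytest.raises(StateCorruptionError, match="Broken"):
            state_derivative(np.array([np.nan]), np.ones(1), np.zeros(1), specs, syn, w, d)


class TestKernelAgainstReference:
    def test_compiled_rhs_matches_numpy_reference(self, default_network, compiled, rng):
        # The numba kernel and the pure-NumPy derivative must agree to
        # machine precision on random admissible states of the full network.
        comp = compiled
        specs = comp.specs
        w = default_network.weight_matrix()
        syn = default_network.synapse
        for _ in range(5):
            v = rng.uniform(-80, 0, comp.n)
            h = rng.uniform(0, 1, comp.n)
            noise = rng.normal(0, 1, comp.n)
            drive = rng.uniform(0, 3, comp.n)
            dv_ref, dh_ref = state_derivative(v, h, noise, specs, syn, w, drive)
            dv = np.empty(comp.n)
            dh = np.empty(comp.n)
            _kernels.rhs(v, h, noise, drive, *comp.param_args(), dv, dh)
            np.testing.assert_allclose(dv, dv_ref, rtol=1e-12, atol=1e-12)
            np.testing.assert_allclose(dh, dh_ref, rtol=1e-12, atol=1e-12)
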