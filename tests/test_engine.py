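"""Integration-engine tests: determinism, settling, convergence, calibration."""

import numpy as np
import pytest

import gaitsim
from gaitsim import engine
from gaitsim.population_dynamics import DriveLaw, NaPParams


class TestIntegrate:
    def test_same_seed_identical_traces(self, default_network):
        protocol = gaitsim.Protocol(duration=2.0, sigma_noise=1.0, seed=42, dt=0.1)
        a = gaitsim.integrate(default_network, protocol)
        b = gaitsim.integrate(default_network, protocol)
        np.testing.assert_array_equal(a.v, b.v)

    def test_different_seed_different_noise(self, default_network):
        a = gaitsim.integrate(
            default_network, gaitsim.Protocol(duration=2.0, sigma_noise=1.0, seed=1)
        )
        b = gaitsim.integrate(
            default_network, gaitsim.Protocol(duration=2.0, sigma_noise=1.0, seed=2)
        )
        assert not np.array_equal(a.v, b.v)

    def test_vn_drive_alone_keeps_extensors_tonic_and_flexors_silent(
        self, default_network
    ):
        # Without any brainstem stimulation the constant vestibular drive must
        # hold all extensor centres in a tonic (non-rhythmic, active) mode and
        # produce no flexor rhythm.
        result = gaitsim.integrate(
            default_network, gaitsim.Protocol(duration=8.0, sigma_noise=0.0)
        )
        tail = result.time > 3000.0
        for side in ("left", "right"):
            for girdle in ("fore", "hind"):
                rge = result.trace(f"RG-E:{side}:{girdle}")[tail]
                assert rge.min() > 0.1  # active
                assert rge.max() - rge.min() < 0.05  # tonic
                rgf = result.trace(f"RG-F:{side}:{girdle}")[tail]
                assert rgf.max() - rgf.min() < 0.05  # no rhythm

    def test_bilateral_cnf_drive_produces_flexor_rhythm(self, default_network):
        # Bilateral CnF excitation within the rhythmogenic range drives
        # sustained oscillations of all four flexor centres.
        protocol = gaitsim.Protocol(
            extra_drives={"CnF-Glu:left": 2.35, "CnF-Glu:right": 2.35},
            duration=10.0,
            sigma_noise=0.005,
            seed=3,
            dt=0.05,
        )
        result = gaitsim.integrate(default_network, protocol)
        tail = result.time > 4000.0
        for key in engine.RG_KEYS:
            trace = result.trace(key)[tail]
            assert trace.max() - trace.min() > 0.3

    def test_result_activity_bounded_and_time_increasing(self, default_network):
        result = gaitsim.integrate(default_network, gaitsim.Protocol(duration=1.0))
        assert np.all(result.f >= 0.0) and np.all(result.f <= 1.0)
        assert np.all(np.diff(result.time) > 0)

    def test_nap_gate_stays_in_unit_interval(self, default_network):
        protocol = gaitsim.Protocol(
            extra_drives={"CnF-Glu:left": 2.3, "CnF-Glu:right": 2.3},
            duration=5.0,
            sigma_noise=1.0,
            seed=11,
            dt=0.1,
        )
        comp = engine._Compiled(default_network)
        state = comp.initial_state()
        drive = engine._protocol_drive(default_network, protocol)
        engine._run_chunk(
            comp, state, drive, 5000.0, 0.1, np.full(comp.n, 1.0),
            np.empty(0, dtype=np.int64), 0, 7,
        )
        gates = state.h[comp.is_nap]
        assert np.all(gates >= 0.0) and np.all(gates <= 1.0)


class TestSettle:
    def test_subthreshold_stimulation_is_quiescent(self, default_network, ppn_stimulation):
        res = engine.settle_at_alpha(
            default_network, ppn_stimulation, 0.0, chunk_s=5.0, max_s=10.0, seed=1
        )
        assert res.status == "quiescent"
        assert np.isnan(res.frequency)
        assert res.gait == "quiescent"

    def test_converged_state_is_a_fixed_point(self, default_network, cnf_stimulation):
        # Re-settling a converged step from its own final state must
        # reproduce the phase differences within the convergence tolerance.
        first = engine.settle_at_alpha(
            default_network, cnf_stimulation, 0.6, chunk_s=10.0, max_s=40.0, seed=2
        )
        assert first.status == "converged"
        again = engine.settle_at_alpha(
            default_network,
            cnf_stimulation,
            0.6,
            first.state.copy(),
            chunk_s=10.0,
            max_s=40.0,
            seed=2,
        )
        for a, b in zip(first.phases, again.phases):
            d = abs(a - b)
            assert min(d, 1 - d) < 5e-3

    def test_stochastic_step_convergence(self, default_network, cnf_stimulation):
        # Halving the Euler-Maruyama step changes the settled frequency by
        # well under the calibration tolerance.
        coarse = engine.settle_at_alpha(
            default_network, cnf_stimulation, 0.9, chunk_s=10.0, max_s=30.0,
            dt=0.1, seed=5,
        )
        fine = engine.settle_at_alpha(
            default_network, cnf_stimulation, 0.9, chunk_s=10.0, max_s=30.0,
            dt=0.05, seed=5,
        )
        assert coarse.frequency == pytest.approx(fine.frequency, rel=0.02)


class TestIsolatedCentre:
    def test_midrange_drive_oscillates(self):
        net = engine.build_isolated_center()
        freq = engine.center_frequency(net, 0.25)
        assert not np.isnan(freq) and 2.0 < freq < 12.0
        # amplitude check: sustained limit cycle of the output
        res = gaitsim.integrate(
            net,
            gaitsim.Protocol(
                extra_drives={"RG-F:left:hind": 0.25}, duration=6.0, sigma_noise=0.0
            ),
        )
        tail = res.f[res.time > 2000.0, 0]
        assert tail.max() - tail.min() > 0.5

    def test_zero_drive_is_quiescent(self):
        net = engine.build_isolated_center()
        assert np.isnan(engine.center_frequency(net, 0.0))

    def test_frequency_increases_with_drive(self):
        net = engine.build_isolated_center()
        freqs = [engine.center_frequency(net, d) for d in (0.22, 0.3, 0.38)]
        assert freqs[0] < freqs[1] < freqs[2]


class TestCalibration:
    def test_infeasible_target_reported(self):
        report = engine.calibrate_rg_center(
            target_range=(15.0, 20.0),
            g_nap_grid=[2.7],
            tau_grid=[200.0],
            n_drives=5,
            drive_range=(0.1, 0.5),
        )
        assert not report.feasible
        assert report.nap is None

    def test_out_of_domain_target_rejected(self):
        with pytest.raises(Exception):
            engine.calibrate_rg_center(target_range=(100.0, 200.0))

    def test_calibration_deterministic_and_recovers_default_band(self):
        kwargs = dict(
            target_range=(4.0, 12.0),
            g_nap_grid=[2.4, 2.7],
            tau_grid=[200.0, 300.0],
            n_drives=8,
            drive_range=(0.15, 0.45),
        )
        a = engine.calibrate_rg_center(**kwargs)
        b = engine.calibrate_rg_center(**kwargs)
        assert a.feasible
        assert a.nap == b.nap
        assert a.frequency_curve.equals(b.frequency_curve)
        # the chosen curve is monotone over its oscillatory range
        f = a.frequency_curve["frequency_hz"].dropna().to_numpy()
        assert np.all(np.diff(f) > -0.1)


class TestLesionProtocols:
    def test_protocol_lesion_matches_explicit_lesion(self, default_network):
        protocol = gaitsim.Protocol(
            extra_drives={"CnF-Glu:left": 4.5},
            lesions=("PPN",),
            duration=2.0,
            sigma_noise=0.0,
        )
        via_protocol = gaitsim.integrate(default_network, protocol)
        lesioned = gaitsim.apply_lesion(default_network, "PPN")
        direct = gaitsim.integrate(
            lesioned,
            gaitsim.Protocol(
                extra_drives={"CnF-Glu:left": 4.5}, duration=2.0, sigma_noise=0.0
            ),
        )
        np.testing.assert_array_equal(via_protocol.v, direct.v)


class TestMirrorSymmetry:
    def test_left_and_right_stimulation_mirror_exactly(self, default_network):
        # With sigma = 0 and mirrored symmetry-breaking initial offsets,
        # stimulating the right CnF must mirror the left-stimulation rhythm:
        # identical frequency, left-right phases mapped phi -> 1 - phi.
        comp = engine._Compiled(default_network)
        alpha = 0.3
        results = {}
        for side, bias_key in (("left", "RG-F:left:hind"), ("right", "RG-F:right:hind")):
            stim = gaitsim.Stimulation(DriveLaw("CnF-Glu", side, m=1.35, b=3.95))
            state = comp.initial_state(bias={bias_key: 5.0})
            results[side] = engine.settle_at_alpha(
                comp, stim, alpha, state, chunk_s=10.0, max_s=30.0,
                sigma_noise=0.0, seed=0,
            )
        left, right = results["left"], results["right"]
        assert left.frequency == pytest.approx(right.frequency, abs=1e-3)
        for phi_l, phi_r in zip(left.phases[:2], right.phases[:2]):
            d = abs(((1.0 - phi_l) % 1.0) - phi_r)
            assert min(d, 1 - d) < 1e-3
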