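"""LIF dynamics against closed forms, delay/refractory contracts, Poisson
sources, perturbations, and checkpointed output equality."""

import h5py
import numpy as np
import pytest
from scipy import stats

from circuitkit.builder import ConnectionRule, EdgePropertySpec, NetworkBuilder
from circuitkit.config import SimulationConfig
from circuitkit.model import SpikeSet
from circuitkit.pointsim import (
    LIFParams,
    PerturbationSpec,
    SimulationError,
    lif_fi_rate,
    poisson_sources,
    rheobase,
    simulate,
)


def single_neuron(**lif):
    b = NetworkBuilder(seed=0)
    b.add_nodes(1, "n", model_type="point_process", **lif)
    return b.model


class TestPoissonSources:
    def test_zero_rate_empty(self):
        assert len(poisson_sources(10, 0.0, 1000.0, seed=1)) == 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            poisson_sources(1, -5.0, 100.0, seed=1)

    def test_pooled_rate_within_counting_error(self):
        n, rate, dur = 1000, 150.0, 10_000.0
        s = poisson_sources(n, rate, dur, seed=7)
        est = len(s) / (n * dur / 1000.0)
        sigma = np.sqrt(rate / (n * dur / 1000.0))
        assert abs(est - rate) < 3 * sigma

    def test_isi_exponential_ks(self):
        s = poisson_sources(1, 100.0, 200_000.0, seed=5)
        _, times = s.select("external")
        isi = np.diff(np.sort(times))
        stat = stats.kstest(isi, "expon", args=(0, 1000.0 / 100.0))
        assert stat.pvalue > 0.01

    def test_reproducible(self):
        a = poisson_sources(5, 20.0, 1000.0, seed=11)
        b = poisson_sources(5, 20.0, 1000.0, seed=11)
        assert a.equals_as_multiset(b)


class TestRheobase:
    def test_closed_form(self):
        p = LIFParams(v_rest=-70.0, v_th=-55.0, r_m=100.0)
        assert rheobase(p) == pytest.approx(150.0)

    @pytest.mark.parametrize("frac,spikes_expected", [(0.99, False), (1.01, True)])
    def test_threshold_behavior(self, frac, spikes_expected):
        p = LIFParams()
        net = single_neuron()
        cfg = SimulationConfig(tstop=10_000.0, dt=0.5, seed=0)
        spk, _ = simulate(net, cfg, baseline_current_pA=frac * rheobase(p))
        assert (len(spk) >= 1) == spikes_expected


class TestLIFDynamics:
    def test_no_input_no_output(self):
        net = single_neuron()
        cfg = SimulationConfig(tstop=500.0, dt=0.1, seed=0)
        spk, _ = simulate(net, cfg)
        assert len(spk) == 0

    @pytest.mark.parametrize("current", [200.0, 300.0, 600.0])
    def test_fi_curve_matches_closed_form(self, current):
        p = LIFParams()
        net = single_neuron()
        cfg = SimulationConfig(tstop=2000.0, dt=0.01, seed=0)
        spk, _ = simulate(net, cfg, baseline_current_pA=current)
        _, times = spk.select("n")
        sim_rate = 1000.0 / np.mean(np.diff(times))  # steady-state ISI
        assert sim_rate == pytest.approx(lif_fi_rate(p, current), rel=0.01)

    def test_delay_contract(self, two_neuron_builder):
        """Follower's PSC jumps exactly `delay` after the driver's spike."""
        net = two_neuron_builder(weight=100.0, delay=3.0)
        cfg = SimulationConfig(tstop=200.0, dt=0.1, seed=0)
        pert = PerturbationSpec("cells", onset=0.0, offset=200.0,
                                amplitude_pA=300.0, node_ids=np.array([0]))
        spk, rep = simulate(net, cfg, perturbations=[pert],
                            record_voltages={"cells": np.array([1])})
        ids, times = spk.select("cells")
        t_first = times[ids == 0][0]
        v1 = rep["membrane_voltage"].data[:, 0]
        # follower sits at rest until the delayed PSC arrives
        moved = np.nonzero(np.abs(v1 - v1[0]) > 1e-9)[0]
        t_moved = rep["membrane_voltage"].start + moved[0] * cfg.dt
        assert t_moved == pytest.approx(t_first + 3.0, abs=cfg.dt + 1e-9)

    def test_refractory_contract(self):
        net = single_neuron(t_ref=5.0)
        cfg = SimulationConfig(tstop=2000.0, dt=0.1, seed=0)
        spk, _ = simulate(net, cfg, baseline_current_pA=2000.0)
        _, times = spk.select("n")
        assert len(times) > 10
        assert np.min(np.diff(np.sort(times))) >= 5.0 - 1e-9

    def test_subthreshold_linearity(self, two_neuron_builder):
        """Doubling one input spike's weight doubles the peak PSP deflection."""
        def peak(weight):
            net = two_neuron_builder(weight=weight, delay=1.0)
            cfg = SimulationConfig(tstop=100.0, dt=0.1, seed=0)
            inp = SpikeSet.from_arrays("cells", [0], [0.0])  # not wired; drive cell 0
            pert = PerturbationSpec("cells", onset=0.0, offset=30.0,
                                    amplitude_pA=400.0, node_ids=np.array([0]))
            _, rep = simulate(net, cfg, perturbations=[pert],
                              record_voltages={"cells": np.array([1])})
            v = rep["membrane_voltage"].data[:, 0]
            return np.max(np.abs(v - v[0]))

        p1, p2 = peak(10.0), peak(20.0)
        assert p2 == pytest.approx(2 * p1, rel=1e-9)

    def test_dt_convergence(self):
        """Halving dt shifts single-neuron spike times by O(dt)."""
        net = single_neuron()
        times = {}
        for dt in (0.1, 0.05, 0.025):
            cfg = SimulationConfig(tstop=1000.0, dt=dt, seed=0)
            spk, _ = simulate(net, cfg, baseline_current_pA=300.0)
            times[dt] = spk.select("n")[1][:10]
        err_coarse = np.max(np.abs(times[0.1] - times[0.025]))
        err_fine = np.max(np.abs(times[0.05] - times[0.025]))
        assert err_coarse < 10 * 0.1  # O(dt) accumulated over 10 spikes
        assert err_fine <= err_coarse

    def test_delay_below_dt_rejected(self, two_neuron_builder):
        net = two_neuron_builder(delay=0.05)
        cfg = SimulationConfig(tstop=10.0, dt=0.1, seed=0)
        with pytest.raises(SimulationError, match="delay"):
            simulate(net, cfg)


class TestPerturbations:
    def test_rheobase_fraction_current(self):
        """fraction 0.5 of a 150 pA rheobase injects 75 pA: subthreshold alone,
        and the steady voltage sits at exactly half the rest-to-threshold gap."""
        net = single_neuron()
        cfg = SimulationConfig(tstop=1000.0, dt=0.1, seed=0)
        pert = PerturbationSpec("n", onset=0.0, offset=1000.0, rheobase_fraction=0.5)
        spk, rep = simulate(net, cfg, perturbations=[pert],
                            record_voltages={"n": np.array([0])})
        assert len(spk) == 0
        v_end = rep["membrane_voltage"].data[-1, 0]
        assert v_end == pytest.approx(-70.0 + 0.5 * 15.0, abs=1e-6)

    def test_silencing_suppresses_driven_cell(self):
        net = single_neuron()
        cfg = SimulationConfig(tstop=3000.0, dt=0.1, seed=0)
        drive = 2.0 * rheobase(LIFParams())
        pert = PerturbationSpec("n", onset=1000.0, offset=2000.0,
                                rheobase_fraction=-5.0)
        spk, _ = simulate(net, cfg, perturbations=[pert], baseline_current_pA=drive)
        _, times = spk.select("n")
        assert np.sum((times >= 1050.0) & (times < 2000.0)) == 0
        assert np.sum(times < 1000.0) > 0 and np.sum(times >= 2000.0) > 0

    def test_window_outside_simulation_is_noop(self):
        net = single_neuron()
        cfg = SimulationConfig(tstop=500.0, dt=0.1, seed=0)
        pert = PerturbationSpec("n", onset=900.0, offset=1000.0, amplitude_pA=1e5)
        ref, _ = simulate(net, cfg, baseline_current_pA=200.0)
        out, _ = simulate(net, cfg, perturbations=[pert], baseline_current_pA=200.0)
        assert out.equals_as_multiset(ref)

    def test_empty_selector_warns_noop(self, caplog):
        import logging
        net = single_neuron()
        cfg = SimulationConfig(tstop=100.0, dt=0.1, seed=0)
        pert = PerturbationSpec("n", onset=0.0, offset=100.0, amplitude_pA=100.0,
                                node_ids=np.array([], dtype=int))
        with caplog.at_level(logging.WARNING, logger="circuitkit.pointsim"):
            simulate(net, cfg, perturbations=[pert])
        assert any("zero cells" in r.message for r in caplog.records)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            PerturbationSpec("n", onset=10.0, offset=10.0, amplitude_pA=1.0)
        with pytest.raises(ValueError):
            PerturbationSpec("n", onset=0.0, offset=1.0)


class TestCheckpointing:
    def test_checkpointed_file_equals_uninterrupted(self, tmp_path):
        b = NetworkBuilder(seed=0)
        b.add_nodes(20, "cells", model_type="point_process")
        b.add_nodes(20, "ext", model_type="virtual")
        b.add_edges("ext", "cells", ConnectionRule("fixed_probability", p=0.4),
                    EdgePropertySpec(syn_weight=120.0, delay=1.0))
        inp = poisson_sources(20, 80.0, 1000.0, seed=5, population="ext")

        def run(interval, path):
            cfg = SimulationConfig(tstop=1000.0, dt=0.1, seed=0,
                                   checkpoint_interval=interval)
            simulate(b.model, cfg, inputs=[inp], spike_output_path=path)

        run(None, tmp_path / "plain.h5")
        run(100.0, tmp_path / "chk.h5")
        with h5py.File(tmp_path / "plain.h5") as fa, \
                h5py.File(tmp_path / "chk.h5") as fb:
            ga, gb = fa["spikes/cells"], fb["spikes/cells"]
            assert ga["timestamps"].shape == gb["timestamps"].shape
            assert np.array_equal(ga["timestamps"][()], gb["timestamps"][()])
            assert np.array_equal(ga["node_ids"][()], gb["node_ids"][()])
        # the run produced spikes at all
        with h5py.File(tmp_path / "plain.h5") as f:
            assert f["spikes/cells/timestamps"].shape[0] > 0

    def test_deterministic_given_seed(self):
        b = NetworkBuilder(seed=0)
        b.add_nodes(10, "cells", model_type="point_process")
        b.add_nodes(10, "ext", model_type="virtual")
        b.add_edges("ext", "cells", ConnectionRule("one_to_one"),
                    EdgePropertySpec(syn_weight=900.0, delay=1.0))
        inp = poisson_sources(10, 100.0, 500.0, seed=9, population="ext")
        cfg = SimulationConfig(tstop=500.0, dt=0.1, seed=0)
        s1, _ = simulate(b.model, cfg, inputs=[inp])
        s2, _ = simulate(b.model, cfg, inputs=[inp])
        assert s1.equals_as_multiset(s2) and len(s1) > 0
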