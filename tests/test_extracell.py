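"""Passive-cable currents, line-source potentials, LFP filtering, and
delta-source inverse CSD, each checked against an independent closed form
or oracle."""

import numpy as np
import pytest

from circuitkit.extracell import (
    CurrentMatrix,
    ElectrodeArray,
    Morphology,
    delta_icsd_forward_matrix,
    icsd_delta,
    line_source_potential,
    lowpass_lfp,
    simulate_passive_cable,
)
from circuitkit.fixtures import make_ballstick, make_planted_csd
from circuitkit.model import ReportSeries


class TestMorphology:
    def test_ballstick_is_path(self):
        m = make_ballstick(n_dend_segments=4)
        assert m.n_segments == 5
        assert list(m.parent) == [-1, 0, 1, 2, 3]
        assert m.lengths.sum() == pytest.approx(20.0 + 4 * 100.0)

    def test_disconnected_rejected(self):
        with pytest.raises(ValueError, match="disconnected"):
            Morphology(np.zeros((3, 3)), np.ones((3, 3)), np.ones(3),
                       parent=[-1, 0, 5])


class TestPassiveCable:
    def test_no_stimulus_no_current(self):
        m = make_ballstick(3)
        cm = simulate_passive_cable(m, {}, duration=20.0, dt=0.1)
        assert np.allclose(cm.currents, 0.0)

    def test_single_compartment_conservation(self):
        """With one compartment the transmembrane current must equal the
        injected current at every step (no axial pathways)."""
        m = Morphology(proximal=[[0, 0, 0]], distal=[[0, 0, 30.0]],
                       radius=[5.0], parent=[-1])
        i0 = 0.5
        cm = simulate_passive_cable(m, {0: np.full(2000, i0)}, 100.0, 0.05)
        assert np.allclose(cm.currents[0], i0, rtol=1e-10)

    def test_kirchhoff_closure_multi_segment(self):
        m = make_ballstick(6)
        stim = {0: 0.3 * np.sin(np.arange(4000) * 0.01) + 0.4}
        cm = simulate_passive_cable(m, stim, duration=200.0, dt=0.05)
        assert cm.kirchhoff_residual() < 1e-8

    def test_rc_membrane_voltage_against_closed_form(self):
        """Two-point check of the implicit scheme against the exact
        exponential for an isolated RC compartment (1% tolerance)."""
        m = Morphology(proximal=[[0, 0, 0]], distal=[[0, 0, 30.0]],
                       radius=[5.0], parent=[-1])
        tau = m.capacitance * m.membrane_resistance * 1e-3  # ms
        dt = tau / 2000
        n = 3000
        cm = simulate_passive_cable(m, {0: np.full(n, 1.0)}, n * dt, dt)
        g = m.areas_cm2[0] / m.membrane_resistance * 1e6
        # reconstruct V from leak current: I_leak = total - capacitive
        t = dt * (1 + np.arange(n))
        v_exact = (1.0 / g) * (1 - np.exp(-t / tau))
        i_cap_exact = 1.0 * np.exp(-t / tau)
        i_leak_sim = cm.currents[0] - i_cap_exact
        assert np.allclose(i_leak_sim / g, v_exact, rtol=0.01, atol=1e-4)


def _point_like_current(n_steps=5):
    """A 1 µm segment carrying 1 nA, electrode geometry helpers."""
    m = Morphology(proximal=[[0, 0, 0]], distal=[[0, 0, 1.0]],
                   radius=[0.5], parent=[-1])
    currents = np.ones((1, n_steps))
    return CurrentMatrix(currents=currents, dt=1.0, morphology=m,
                         injected=np.ones(n_steps))


class TestLineSource:
    def test_far_field_matches_point_source(self):
        cm = _point_like_current()
        r = 1000.0
        e = ElectrodeArray([[r, 0.0, 0.5]], sigma_e=0.3)
        phi = line_source_potential(cm, e)
        point = 1e-9 / (4 * np.pi * 0.3 * r * 1e-6) * 1e3  # mV
        assert phi.data[0, 0] == pytest.approx(point, rel=1e-3)

    def test_conductivity_scaling(self):
        cm = _point_like_current()
        e1 = ElectrodeArray([[50.0, 0, 0.5]], sigma_e=0.3)
        e2 = ElectrodeArray([[50.0, 0, 0.5]], sigma_e=0.6)
        p1 = line_source_potential(cm, e1).data[0, 0]
        p2 = line_source_potential(cm, e2).data[0, 0]
        assert p1 == pytest.approx(2 * p2, rel=1e-12)

    def test_superposition_of_segments(self):
        m2 = Morphology(proximal=[[0, 0, 0], [5, 0, 0]],
                        distal=[[0, 0, 1.0], [5, 0, 1.0]],
                        radius=[0.5, 0.5], parent=[-1, 0])
        cm2 = CurrentMatrix(np.ones((2, 1)), 1.0, m2, injected=2 * np.ones(1))
        e = ElectrodeArray([[100.0, 20.0, 0.0]])
        both = line_source_potential(cm2, e).data[0, 0]
        singles = 0.0
        for i in range(2):
            mi = Morphology(proximal=[m2.proximal[i]], distal=[m2.distal[i]],
                            radius=[0.5], parent=[-1])
            cmi = CurrentMatrix(np.ones((1, 1)), 1.0, mi, injected=np.ones(1))
            singles += line_source_potential(cmi, e).data[0, 0]
        assert both == pytest.approx(singles, rel=1e-12)

    def test_joint_translation_invariance(self):
        shift = np.array([123.0, -40.0, 7.0])
        m = make_ballstick(3)
        cur = np.random.default_rng(0).standard_normal((4, 6))
        cm = CurrentMatrix(cur, 1.0, m, injected=cur.sum(axis=0))
        e = ElectrodeArray([[200.0, 0.0, 100.0]])
        p0 = line_source_potential(cm, e).data
        m2 = Morphology(m.proximal + shift, m.distal + shift, m.radius, m.parent)
        cm2 = CurrentMatrix(cur, 1.0, m2, injected=cur.sum(axis=0))
        e2 = ElectrodeArray([np.array([200.0, 0.0, 100.0]) + shift])
        p1 = line_source_potential(cm2, e2).data
        assert np.allclose(p0, p1, rtol=1e-12)

    def test_invalid_conductivity(self):
        with pytest.raises(ValueError):
            ElectrodeArray([[0, 0, 10.0]], sigma_e=-1.0)


class TestLowpass:
    def test_dc_gain_unity(self):
        phi = ReportSeries("phi", dt=1.0, data=np.full((512, 2), 3.7))
        out = lowpass_lfp(phi, cutoff=100.0)
        assert np.allclose(out.data, 3.7, atol=1e-9)

    def test_passband_amplitude_preserved(self):
        t = np.arange(4096) * 1e-3  # dt=1 ms
        x = np.sin(2 * np.pi * 5.0 * t)
        out = lowpass_lfp(ReportSeries("phi", dt=1.0, data=x[:, None]), cutoff=400.0)
        mid = slice(500, 3500)
        assert np.max(np.abs(out.data[mid, 0] - x[mid])) < 0.01

    def test_stopband_attenuation(self):
        t = np.arange(8192) * 5e-5  # dt = 0.05 ms, fs 20 kHz
        x = np.sin(2 * np.pi * 2000.0 * t)
        out = lowpass_lfp(ReportSeries("phi", dt=0.05, data=x[:, None]), cutoff=500.0)
        atten = np.max(np.abs(out.data[1000:-1000, 0]))
        assert atten < 10 ** (-40 / 20)  # > 40 dB down

    def test_cutoff_above_nyquist_rejected(self):
        phi = ReportSeries("phi", dt=1.0, data=np.zeros((64, 1)))
        with pytest.raises(ValueError):
            lowpass_lfp(phi, cutoff=600.0)


class TestDeltaICSD:
    def test_recovers_planted_disk(self):
        depths, planted, lfp = make_planted_csd()
        prof = icsd_delta(lfp, depths, diameter_um=800.0, sigma_e=0.3)
        spacing_mm = 0.1
        recovered_planar = prof.values * spacing_mm
        scale = np.max(np.abs(planted))
        assert np.max(np.abs(recovered_planar - planted)) / scale < 1e-6

    def test_zero_lfp_zero_csd(self):
        depths = 100.0 * np.arange(8)
        lfp = ReportSeries("lfp", dt=1.0, data=np.zeros((5, 8)))
        prof = icsd_delta(lfp, depths)
        assert np.allclose(prof.values, 0.0)

    def test_forward_of_estimate_reproduces_lfp(self):
        rng = np.random.default_rng(1)
        depths = 50.0 * np.arange(12)
        lfp = ReportSeries("lfp", dt=1.0, data=rng.standard_normal((20, 12)) * 0.1)
        prof = icsd_delta(lfp, depths, diameter_um=500.0, sigma_e=0.3)
        F = delta_icsd_forward_matrix(depths, 500.0, 0.3)
        re_lfp = (F @ (prof.values * (50.0 * 1e-3))).T
        assert np.allclose(re_lfp, lfp.data, rtol=1e-8, atol=1e-12)

    def test_large_diameter_limit_is_second_difference(self):
        """As the disk diameter grows, the delta-source estimate approaches
        the standard second-spatial-difference CSD away from the edges."""
        h_um = 100.0
        depths, planted, _ = make_planted_csd(spacing_um=h_um)
        # regenerate the LFP with a huge-diameter forward model
        big = 100_000.0
        F = delta_icsd_forward_matrix(depths, big, 0.3)
        lfp_big = ReportSeries("lfp", dt=1.0, data=(F @ planted).T)
        prof = icsd_delta(lfp_big, depths, diameter_um=big, sigma_e=0.3)
        # finite-difference oracle: -sigma * d2phi/dz2
        phi = lfp_big.data.T  # [depth, time], mV
        h_mm = h_um * 1e-3
        d2 = (phi[:-2] + phi[2:] - 2 * phi[1:-1]) / h_mm ** 2
        csd_fd = -0.3 * d2 * 1e3  # mV/mm^2 * S/m -> nA/mm^3 (unit bookkeeping)
        interior = slice(3, len(depths) - 4)
        est = prof.values[1:-1]
        scale = np.max(np.abs(csd_fd))
        assert np.max(np.abs(est[interior] - csd_fd[interior])) / scale < 0.02

    def test_uneven_spacing_rejected(self):
        lfp = ReportSeries("lfp", dt=1.0, data=np.zeros((4, 3)))
        with pytest.raises(ValueError, match="evenly spaced"):
            icsd_delta(lfp, np.array([0.0, 100.0, 250.0]))
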