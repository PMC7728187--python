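"""Programmatic generators for example models and test inputs.

Everything here is deterministic under its seed and produces objects that
pass the validators of the consuming modules: the packaged
excitatory/inhibitory example network, movie stimuli, toy morphologies, and
planted CSD scenarios.  No external data are required.
"""

from __future__ import annotations

import numpy as np

from .builder import ConnectionRule, EdgePropertySpec, NetworkBuilder
from .config import SimulationConfig
from .extracell import Morphology, delta_icsd_forward_matrix
from .filtersim import Movie
from .model import NetworkModel, ReportSeries, SpikeSet
from .pointsim import poisson_sources
from .ratesim import PopulationConnection, PopulationNode, RateModel

__all__ = [
    "EI_PARAMS",
    "RATE_PARAMS",
    "make_ei_example",
    "make_rate_example",
    "ei_example_spec",
    "ei_example_inputs",
    "make_movie",
    "make_ballstick",
    "make_planted_csd",
    "make_toy_network",
]

# Packaged parameters of the two-population example network: 10,000
# excitatory + 2,500 inhibitory LIF neurons, recurrent connection
# probability 0.1, driven by 1,000 external Poisson sources at 150 Hz with
# feedforward in-degree 10.  The synaptic weights were tuned once to place
# the network in the synchronous-regular regime (population oscillation near
# 20 Hz with regular single-neuron firing) and are frozen here.
EI_PARAMS = {
    "n_exc": 10_000,
    "n_inh": 2_500,
    "n_external": 1_000,
    "p_connect": 0.1,
    "ff_indegree": 10,
    "external_rate_hz": 150.0,
    "delay_ms": 1.5,
    "w_exc_pA": 2.0,      # recurrent excitatory weight
    "w_inh_pA": -8.0,     # recurrent inhibitory weight
    "w_ext_pA": 80.0,     # feedforward weight per external synapse
    "lif": {"tau_m": 50.0, "v_rest": -70.0, "v_th": -55.0, "v_reset": -70.0,
            "t_ref": 2.0, "r_m": 100.0, "tau_syn": 2.0},
}


def make_ei_example(seed: int, scale: int = 1) -> NetworkModel:
    """Instantiate the packaged E/I example network.

    ``scale=1`` is the full 12,500-neuron network with Bernoulli(0.1)
    recurrent connectivity.  ``scale=k`` (k>1) divides the neuron counts by k
    and raises the connection probability to ``min(1, 0.1*k)`` so that every
    neuron keeps the full-scale recurrent in-degree (at scale 10 this becomes
    all-to-all); the 1,000 external sources and feedforward in-degree are
    kept, so the external drive is unchanged.  Deterministic given seed.
    """
    p = EI_PARAMS
    n_exc = p["n_exc"] // scale
    n_inh = p["n_inh"] // scale
    p_conn = min(1.0, p["p_connect"] * scale)

    b = NetworkBuilder(name="ei_example", seed=seed)
    exc_ids = b.add_nodes(n_exc, "internal", model_type="point_process", ei="e",
                          cell_class="exc", **p["lif"])
    inh_ids = b.add_nodes(n_inh, "internal", model_type="point_process", ei="i",
                          cell_class="inh", **p["lif"])
    b.add_nodes(p["n_external"], "external", model_type="virtual", ei="e",
                cell_class="external")

    exc_mask = np.zeros(n_exc + n_inh, dtype=bool)
    exc_mask[exc_ids] = True

    rule = (ConnectionRule("all_to_all") if p_conn >= 1.0
            else ConnectionRule("fixed_probability", p=p_conn))
    b.add_edges("internal", "internal", rule,
                EdgePropertySpec(syn_weight=p["w_exc_pA"], delay=p["delay_ms"], nsyns=1),
                source_filter=exc_mask, name="recurrent")
    b.add_edges("internal", "internal", rule,
                EdgePropertySpec(syn_weight=p["w_inh_pA"], delay=p["delay_ms"], nsyns=1),
                source_filter=~exc_mask, name="recurrent")
    b.add_edges("external", "internal",
                ConnectionRule("fixed_indegree", indegree=p["ff_indegree"]),
                EdgePropertySpec(syn_weight=p["w_ext_pA"], delay=p["delay_ms"], nsyns=1),
                name="feedforward")
    b.model.validate()
    return b.model


def ei_example_spec(seed: int, duration: float = 3000.0, dt: float = 0.1) -> dict:
    """The example as a serializable (build spec, simulation config) pair."""
    p = EI_PARAMS
    build_spec = {
        "name": "ei_example",
        "seed": seed,
        "nodes": [
            {"population": "internal", "n": p["n_exc"],
             "type_attrs": {"model_type": "point_process", "ei": "e",
                            "cell_class": "exc", **p["lif"]}},
            {"population": "internal", "n": p["n_inh"],
             "type_attrs": {"model_type": "point_process", "ei": "i",
                            "cell_class": "inh", **p["lif"]}},
            {"population": "external", "n": p["n_external"],
             "type_attrs": {"model_type": "virtual", "ei": "e",
                            "cell_class": "external"}},
        ],
        "edges": [],  # rules with node filters are applied by make_ei_example
    }
    config = {
        "run": {"tstop": duration, "dt": dt, "seed": seed},
        "inputs": {"external_spikes": {
            "input_type": "poisson", "population": "external",
            "n": p["n_external"], "rate_hz": p["external_rate_hz"]}},
        "output": {"spikes_file": "output/spikes.h5"},
    }
    return {"build": build_spec, "config": config}


def ei_example_inputs(seed: int, duration: float) -> SpikeSet:
    """The example's external drive: 1,000 Poisson trains at 150 Hz."""
    p = EI_PARAMS
    return poisson_sources(p["n_external"], p["external_rate_hz"], duration,
                           seed=seed, population="external")


def ei_example_config(duration: float = 3000.0, dt: float = 0.1, seed: int = 1,
                      checkpoint_interval: float | None = None) -> SimulationConfig:
    return SimulationConfig(tstop=duration, dt=dt, seed=seed,
                            checkpoint_interval=checkpoint_interval)


# Packaged three-node rate reduction of the example network: an excitatory
# and an inhibitory population in a delayed loop, plus a constant-rate
# external source.  Tuned once to a relaxation oscillation near 20 Hz whose
# excitatory rate drops close to zero between peaks, and frozen here.
RATE_PARAMS = {
    "tau_E": 8.0, "tau_I": 8.0,           # ms
    "w_EE": 1.3, "w_EI": -4.0, "w_IE": 2.0,
    "d_EE": 2.0, "d_EI": 5.0, "d_IE": 2.0,  # ms (d_EI: E->I, d_IE: I->E)
    "external_rate_hz": 150.0,
    "drive_E": 20.0,                       # w_XE * 150 Hz
}


def make_rate_example() -> RateModel:
    """The packaged 3-node (E, I, external) delayed rate model."""
    p = RATE_PARAMS
    return RateModel(
        nodes=[
            PopulationNode("E", tau_r=p["tau_E"]),
            PopulationNode("I", tau_r=p["tau_I"]),
            PopulationNode("X", is_source=True, source_rate=p["external_rate_hz"]),
        ],
        connections=[
            PopulationConnection("E", "E", p["w_EE"], p["d_EE"]),
            PopulationConnection("E", "I", p["w_IE"], p["d_EI"]),
            PopulationConnection("I", "E", p["w_EI"], p["d_IE"]),
            PopulationConnection("X", "E", p["drive_E"] / p["external_rate_hz"], 1.0),
        ],
    )


# ---------------------------------------------------------------------------
# movies
# ---------------------------------------------------------------------------

def make_movie(kind: str, shape: tuple[int, int, int] = (120, 32, 32),
               frame_rate: float = 60.0, seed: int = 0,
               degrees_per_pixel: float = 1.0,
               spatial_freq: float = 0.05, temporal_freq: float = 4.0,
               direction_deg: float = 0.0, contrast: float = 1.0,
               flash_onset_frame: int | None = None) -> Movie:
    """Deterministic movie stimuli: gray | grating | noise | flash.

    gray: constant mid-luminance (zero contrast).  grating: drifting sinusoid
    with the given spatial frequency (cycles/deg), temporal frequency (Hz)
    and direction.  noise: i.i.d. standard-normal pixels.  flash: gray, then
    a luminance step at ``flash_onset_frame`` (default halfway).
    """
    n_t, n_y, n_x = shape
    if min(shape) < 1:
        raise ValueError("shape entries must be positive")
    if kind == "gray":
        data = np.zeros(shape)
    elif kind == "grating":
        t = np.arange(n_t) / frame_rate
        ys = np.arange(n_y) * degrees_per_pixel
        xs = np.arange(n_x) * degrees_per_pixel
        theta = np.deg2rad(direction_deg)
        phase = 2 * np.pi * (spatial_freq * (np.cos(theta) * xs[None, None, :]
                                             + np.sin(theta) * ys[None, :, None])
                             - temporal_freq * t[:, None, None])
        data = contrast * np.sin(phase)
    elif kind == "noise":
        data = np.random.default_rng(seed).standard_normal(shape) * contrast
    elif kind == "flash":
        onset = n_t // 2 if flash_onset_frame is None else flash_onset_frame
        data = np.zeros(shape)
        data[onset:] = contrast
    else:
        raise ValueError(f"unknown movie kind {kind!r}")
    return Movie(data, frame_rate, degrees_per_pixel)


# ---------------------------------------------------------------------------
# morphologies
# ---------------------------------------------------------------------------

def make_ballstick(n_dend_segments: int = 5, soma_length: float = 20.0,
                   soma_radius: float = 10.0, dend_length: float = 100.0,
                   dend_radius: float = 1.0, **passive) -> Morphology:
    """Soma plus a straight dendrite of n segments along +z (a 'ball and
    stick'), for extracellular-signal tests."""
    if n_dend_segments < 1:
        raise ValueError("need at least one dendritic segment")
    n = n_dend_segments + 1
    proximal = np.zeros((n, 3))
    distal = np.zeros((n, 3))
    distal[0, 2] = soma_length
    for i in range(1, n):
        proximal[i, 2] = soma_length + (i - 1) * dend_length
        distal[i, 2] = soma_length + i * dend_length
    radius = np.full(n, dend_radius)
    radius[0] = soma_radius
    parent = np.arange(-1, n - 1)
    return Morphology(proximal, distal, radius, parent, **passive)


# ---------------------------------------------------------------------------
# planted CSD scenarios
# ---------------------------------------------------------------------------

def make_planted_csd(n_electrodes: int = 16, spacing_um: float = 100.0,
                     diameter_um: float = 800.0, sigma_e: float = 0.3,
                     sink_channel: int = 7, amplitude: float = -50.0,
                     n_samples: int = 40, dt: float = 1.0):
    """A known planar CSD profile and the LFP it generates.

    Plants a single-disk sink (negative, ``amplitude`` nA/mm²) whose
    amplitude follows one cycle of a raised cosine in time, forward-maps it
    to electrode potentials, and returns (depths µm, planted planar CSD
    [depth × time], LFP ReportSeries).
    """
    depths = spacing_um * np.arange(n_electrodes)
    planted = np.zeros((n_electrodes, n_samples))
    envelope = 0.5 * (1 - np.cos(2 * np.pi * np.arange(n_samples) / n_samples))
    planted[sink_channel] = amplitude * envelope
    F = delta_icsd_forward_matrix(depths, diameter_um, sigma_e)
    lfp = ReportSeries(variable="lfp", dt=dt, data=(F @ planted).T, units="mV")
    return depths, planted, lfp


# ---------------------------------------------------------------------------
# toy networks
# ---------------------------------------------------------------------------

def make_toy_network(seed: int = 0, n_a: int = 3, n_b: int = 4,
                     with_positions: bool = True) -> NetworkModel:
    """A tiny two-population network with an unused free-form edge column,
    for round-trip and reduction tests."""
    rng = np.random.default_rng(seed)
    b = NetworkBuilder(name="toy", seed=seed)
    per_node = None
    if with_positions:
        per_node = {"x": lambda r, n: 100 * r.random(n),
                    "y": lambda r, n: 100 * r.random(n),
                    "z": lambda r, n: 100 * r.random(n)}
    b.add_nodes(n_a, "alpha", per_node=per_node, model_type="point_process",
                ei="e", tau_m=20.0)
    b.add_nodes(n_b, "beta", per_node=per_node, model_type="point_process",
                ei="i", tau_m=10.0)
    n = b.add_edges("alpha", "beta", ConnectionRule("all_to_all"),
                    EdgePropertySpec(syn_weight=1.5, delay=1.0, nsyns=2,
                                     extra={"target_section": "dend"}))
    ep = b.model.edge_populations["alpha_to_beta"]
    ep.attributes["dendrite_offset_um"] = rng.random(n) * 50.0
    return b.model
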