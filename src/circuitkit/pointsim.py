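"""Clock-driven simulator for networks of leaky integrate-and-fire neurons.

Model: current-based LIF with exponential postsynaptic currents,

    tau_m dV/dt   = -(V - V_rest) + R_m (I_syn + I_ext)
    tau_syn dI/dt = -I_syn,        spike arrival: I_syn += w

integrated with the exact (exponential-propagator) update of the linear
(V, I_syn) system over each fixed step dt, so subthreshold dynamics carry no
discretization error; spikes are detected at step boundaries.  A spike
resets V to V_reset, starts an absolute refractory period, and schedules
weight delivery to all targets after the conduction delay via a ring buffer.

Units: ms, mV, pA, MOhm (so R_m * I / 1000 is in mV).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .config import SimulationConfig
from .model import NetworkModel, ReportSeries, SpikeSet
from .sonata import SpikeWriter

log = logging.getLogger(__name__)

__all__ = [
    "LIFParams",
    "PerturbationSpec",
    "poisson_sources",
    "rheobase",
    "simulate",
    "SimulationError",
]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire parameters.

    tau_m   membrane time constant, ms
    v_rest  resting potential, mV
    v_th    spike threshold, mV (> v_rest)
    v_reset post-spike reset, mV (< v_th)
    t_ref   absolute refractory period, ms
    r_m     membrane resistance, MOhm
    tau_syn exponential PSC decay time, ms
    """

    tau_m: float = 20.0
    v_rest: float = -70.0
    v_th: float = -55.0
    v_reset: float = -70.0
    t_ref: float = 2.0
    r_m: float = 100.0
    tau_syn: float = 2.0

    def __post_init__(self):
        if self.tau_m <= 0 or self.tau_syn <= 0:
            raise ValueError("tau_m and tau_syn must be positive")
        if not self.v_th > self.v_rest:
            raise ValueError("v_th must exceed v_rest")
        if not self.v_reset < self.v_th:
            raise ValueError("v_reset must be below v_th")
        if self.t_ref < 0:
            raise ValueError("t_ref must be >= 0")
        if self.r_m <= 0:
            raise ValueError("r_m must be positive")
        for v in (self.tau_m, self.v_rest, self.v_th, self.v_reset, self.t_ref,
                  self.r_m, self.tau_syn):
            if not math.isfinite(v):
                raise ValueError("LIF parameters must be finite")

    @classmethod
    def from_type_row(cls, row: dict) -> "LIFParams":
        kwargs = {f: float(row[f]) for f in
                  ("tau_m", "v_rest", "v_th", "v_reset", "t_ref", "r_m", "tau_syn")
                  if f in row}
        return cls(**kwargs)


def rheobase(p: LIFParams) -> float:
    """Minimal constant current (pA) driving the neuron from rest to threshold.

    For the LIF the steady-state voltage under constant I is
    V_rest + R_m I, so the rheobase is (v_th - v_rest) / r_m.
    """
    return 1000.0 * (p.v_th - p.v_rest) / p.r_m  # mV / MOhm -> nA -> pA


def lif_fi_rate(p: LIFParams, current_pA: float) -> float:
    """Closed-form steady firing rate (Hz) of a LIF under constant current.

    Zero below rheobase; above it
    f = 1000 / (t_ref + tau_m * ln((IR + v_rest - v_reset)/(IR + v_rest - v_th))).
    """
    ir = p.r_m * current_pA / 1000.0  # mV
    if ir + p.v_rest <= p.v_th:
        return 0.0
    period = p.t_ref + p.tau_m * math.log((ir + p.v_rest - p.v_reset) /
                                          (ir + p.v_rest - p.v_th))
    return 1000.0 / period


@dataclass
class PerturbationSpec:
    """A rectangular current injection into a set of cells.

    Amplitude is either absolute (``amplitude_pA``) or a per-cell fraction of
    rheobase (``rheobase_fraction``); exactly one must be given.  Applied on
    [onset, offset) ms.  ``node_ids=None`` targets the whole population.
    """

    population: str
    onset: float
    offset: float
    amplitude_pA: float | None = None
    rheobase_fraction: float | None = None
    node_ids: np.ndarray | None = None
    node_type_id: int | None = None

    def __post_init__(self):
        if not self.onset < self.offset:
            raise ValueError("perturbation onset must precede offset")
        if (self.amplitude_pA is None) == (self.rheobase_fraction is None):
            raise ValueError("specify exactly one of amplitude_pA, rheobase_fraction")
        if self.node_ids is not None:
            self.node_ids = np.asarray(self.node_ids, dtype=np.int64)


def poisson_sources(n: int, rate: float, duration: float, seed: int,
                    population: str = "external") -> SpikeSet:
    """n independent homogeneous Poisson spike trains of given rate (Hz).

    Spike count per train is Poisson(rate * duration); times are i.i.d.
    uniform on [0, duration) ms, which is the standard order-statistics
    construction of a homogeneous Poisson process.
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rate * duration / 1000.0, size=n)
    total = int(counts.sum())
    node_ids = np.repeat(np.arange(n, dtype=np.int64), counts)
    times = rng.random(total) * duration
    return SpikeSet.from_arrays(population, node_ids, times, sort="by_time")


# ---------------------------------------------------------------------------
# network compilation
# ---------------------------------------------------------------------------

class _CompiledNetwork:
    """Flattened view of a NetworkModel for the clock-driven loop.

    Simulated (point_process) populations are concatenated into one global
    neuron index; virtual populations get their own source index range.
    Synapses are grouped by conduction-delay step into CSR matrices
    [global source x neuron] holding effective weights (syn_weight * nsyns).
    """

    def __init__(self, net: NetworkModel, dt: float):
        self.dt = dt
        self.neuron_offsets: dict[str, int] = {}
        params_rows: list[LIFParams] = []
        offset = 0
        for name, pop in net.node_populations.items():
            model_types = {str(net.node_types.row(t).get("model_type"))
                           for t in np.unique(pop.node_type_ids)}
            if model_types == {"point_process"}:
                self.neuron_offsets[name] = offset
                for t in pop.node_type_ids:
                    params_rows.append(LIFParams.from_type_row(net.node_types.row(int(t))))
                offset += pop.n_nodes
            elif "point_process" in model_types:
                raise SimulationError(
                    f"population {name!r} mixes point_process with other model types")
        self.n_neurons = offset
        if self.n_neurons == 0:
            raise SimulationError("network contains no point_process nodes")

        # virtual sources appended after the simulated neurons
        self.source_offsets = dict(self.neuron_offsets)
        for name, pop in net.node_populations.items():
            if name in self.neuron_offsets:
                continue
            self.source_offsets[name] = offset
            offset += pop.n_nodes
        self.n_sources = offset

        self.tau_m = np.array([p.tau_m for p in params_rows])
        self.v_rest = np.array([p.v_rest for p in params_rows])
        self.v_th = np.array([p.v_th for p in params_rows])
        self.v_reset = np.array([p.v_reset for p in params_rows])
        self.r_m = np.array([p.r_m for p in params_rows])
        self.tau_syn = np.array([p.tau_syn for p in params_rows])
        self.t_ref_steps = np.round(np.array([p.t_ref for p in params_rows]) / dt).astype(np.int64)
        self.rheobase = 1000.0 * (self.v_th - self.v_rest) / self.r_m

        self._build_synapses(net)

    def _build_synapses(self, net: NetworkModel) -> None:
        rows, cols, data, delay_steps = [], [], [], []
        for ep in net.edge_populations.values():
            if ep.target_population not in self.neuron_offsets:
                continue  # edges onto non-simulated nodes are ignored here
            if ep.source_population not in self.source_offsets:
                raise SimulationError(
                    f"edge population {ep.name!r}: unknown source {ep.source_population!r}")
            n = ep.n_edges
            if n == 0:
                continue
            w = _edge_values(ep, net, "syn_weight", default=0.0)
            nsyns = _edge_values(ep, net, "nsyns", default=1.0)
            delay = _edge_values(ep, net, "delay", default=self.dt)
            if float(np.min(delay)) < self.dt - 1e-12:
                raise SimulationError(
                    f"edge population {ep.name!r}: delay below dt={self.dt} ms")
            rows.append(ep.source_node_ids + self.source_offsets[ep.source_population])
            cols.append(ep.target_node_ids + self.neuron_offsets[ep.target_population])
            data.append(w * nsyns)
            delay_steps.append(np.round(delay / self.dt).astype(np.int64))

        self.delay_groups: dict[int, sparse.csr_matrix] = {}
        self.max_delay_steps = 1
        if rows:
            rows = np.concatenate(rows)
            cols = np.concatenate(cols)
            data = np.concatenate(data)
            delay_steps = np.concatenate(delay_steps)
            for d in np.unique(delay_steps):
                m = delay_steps == d
                mat = sparse.csr_matrix(
                    (data[m], (rows[m], cols[m])),
                    shape=(self.n_sources, self.n_neurons))
                self.delay_groups[int(d)] = mat
            self.max_delay_steps = int(delay_steps.max())

    def global_neuron_ids(self, population: str, node_ids: np.ndarray) -> np.ndarray:
        return np.asarray(node_ids, dtype=np.int64) + self.neuron_offsets[population]


def _edge_values(ep, net: NetworkModel, key: str, default: float) -> np.ndarray:
    if key in ep.attributes:
        return np.asarray(ep.attributes[key], dtype=float)
    # constant per edge type
    out = np.full(ep.n_edges, default, dtype=float)
    for t in np.unique(ep.edge_type_ids):
        row = net.edge_types.row(int(t))
        if key in row:
            out[ep.edge_type_ids == t] = float(row[key])
    return out


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _perturbation_schedule(net: _CompiledNetwork, model: NetworkModel,
                           perturbations, n_steps: int, dt: float):
    """Per-spec (step_on, step_off, neuron ids, per-neuron amplitude pA)."""
    out = []
    for spec in perturbations or []:
        if spec.population not in net.neuron_offsets:
            log.warning("perturbation targets unknown/non-simulated population %r; no-op",
                        spec.population)
            continue
        pop = model.node_populations[spec.population]
        if spec.node_ids is not None:
            ids = spec.node_ids
        elif spec.node_type_id is not None:
            ids = np.nonzero(pop.node_type_ids == spec.node_type_id)[0]
        else:
            ids = pop.node_ids
        if len(ids) == 0:
            log.warning("perturbation selector matched zero cells; no-op")
            continue
        gids = net.global_neuron_ids(spec.population, ids)
        if spec.amplitude_pA is not None:
            amp = np.full(len(gids), float(spec.amplitude_pA))
        else:
            amp = float(spec.rheobase_fraction) * net.rheobase[gids]
        on = max(0, int(round(spec.onset / dt)))
        off = min(n_steps, int(round(spec.offset / dt)))
        if on < off:
            out.append((on, off, gids, amp))
    return out


def simulate(net: NetworkModel, config: SimulationConfig,
             inputs: list[SpikeSet] | None = None,
             perturbations: list[PerturbationSpec] | None = None,
             record_voltages: dict[str, np.ndarray] | None = None,
             baseline_current_pA: float = 0.0,
             spike_output_path=None,
             output_population: str | None = None,
             ) -> tuple[SpikeSet, dict[str, ReportSeries]]:
    """Run the clock-driven LIF network simulation.

    inputs            SpikeSets whose population names match virtual node
                      populations wired into the network
    perturbations     rectangular current injections (optogenetics analog)
    record_voltages   population name -> node ids whose membrane voltage is
                      recorded every step into a ReportSeries
    spike_output_path if given, spikes stream to this HDF5 file, flushed
                      every ``config.checkpoint_interval`` ms

    Returns the emitted spikes (population names preserved) and any reports.
    Deterministic: the loop itself draws no random numbers.
    """
    dt = config.dt
    n_steps = config.n_steps
    comp = _CompiledNetwork(net, dt)
    n = comp.n_neurons

    # exact propagator coefficients (per neuron)
    alpha = np.exp(-dt / comp.tau_m)
    beta = np.exp(-dt / comp.tau_syn)
    # particular solution of the driven membrane for an exponentially
    # decaying PSC: V_p(t) = c * I_syn(t) with c = R tau_s / (tau_s - tau_m)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(np.abs(comp.tau_m - comp.tau_syn) > 1e-12,
                     (comp.r_m / 1000.0) * comp.tau_syn / (comp.tau_syn - comp.tau_m),
                     0.0)
    degenerate = np.abs(comp.tau_m - comp.tau_syn) <= 1e-12
    r_over = comp.r_m / 1000.0  # mV per pA

    v = comp.v_rest.copy()
    i_syn = np.zeros(n)
    refrac = np.zeros(n, dtype=np.int64)

    # ring buffer of future synaptic deliveries
    horizon = comp.max_delay_steps + 1
    ring = np.zeros((horizon, n))

    # pre-bin virtual input spikes by emission step
    input_events: dict[int, list[np.ndarray]] = {}
    for spk in inputs or []:
        for pop in spk.population_names():
            if pop not in comp.source_offsets or pop in comp.neuron_offsets:
                if pop not in comp.source_offsets:
                    log.warning("input population %r not wired into network; ignored", pop)
                    continue
            ids, times = spk.select(pop)
            steps = np.floor(times / dt).astype(np.int64)
            keep = (steps >= 0) & (steps < n_steps)
            ids, steps = ids[keep] + comp.source_offsets[pop], steps[keep]
            order = np.argsort(steps, kind="stable")
            ids, steps = ids[order], steps[order]
            if len(steps):
                uniq = np.unique(steps)
                splits = np.searchsorted(steps, uniq)
                chunks = np.split(ids, splits[1:])
                for s, chunk in zip(uniq, chunks):
                    input_events.setdefault(int(s), []).append(chunk)

    pert = _perturbation_schedule(comp, net, perturbations, n_steps, dt)
    i_ext = np.full(n, float(baseline_current_pA))
    # step -> list of (gids, delta) applied at that step boundary
    ext_events: dict[int, list[tuple[np.ndarray, np.ndarray]]] = {}
    for on, off, gids, amp in pert:
        ext_events.setdefault(on, []).append((gids, amp))
        ext_events.setdefault(off, []).append((gids, -amp))

    # voltage recording
    rec_gids = np.empty(0, dtype=np.int64)
    if record_voltages:
        rec_gids = np.concatenate([comp.global_neuron_ids(p, ids)
                                   for p, ids in record_voltages.items()])
    v_trace = np.empty((n_steps, len(rec_gids))) if len(rec_gids) else None

    writer = None
    checkpoint_steps = None
    if output_population is None:
        output_population = (next(iter(comp.neuron_offsets))
                             if len(comp.neuron_offsets) == 1 else "point")
    if spike_output_path is not None:
        writer = SpikeWriter(spike_output_path, output_population)
        if config.checkpoint_interval:
            checkpoint_steps = max(1, int(round(config.checkpoint_interval / dt)))

    out_ids: list[np.ndarray] = []
    out_times: list[np.ndarray] = []
    delays = sorted(comp.delay_groups)

    for t in range(n_steps):
        if t in ext_events:
            for gids, delta in ext_events[t]:
                np.add.at(i_ext, gids, delta)

        # deliver events scheduled for this step
        slot = t % horizon
        i_syn += ring[slot]
        ring[slot] = 0.0

        # exact update over [t, t+1] dt
        drive = r_over * i_ext
        v_new = (comp.v_rest + drive
                 + (v - comp.v_rest - drive - c * i_syn) * alpha
                 + c * i_syn * beta)
        if degenerate.any():
            # tau_m == tau_syn: particular solution picks up a t*exp term
            idx = degenerate
            v_new[idx] = (comp.v_rest[idx] + drive[idx]
                          + (v[idx] - comp.v_rest[idx] - drive[idx]) * alpha[idx]
                          + r_over[idx] * i_syn[idx] * (dt / comp.tau_m[idx]) * alpha[idx])
        i_syn *= beta
        v = v_new

        # refractory clamp
        in_ref = refrac > 0
        if in_ref.any():
            v[in_ref] = comp.v_reset[in_ref]
            refrac[in_ref] -= 1

        if not np.all(np.isfinite(v)):
            raise SimulationError(f"non-finite membrane state at step {t}")

        spiked = np.nonzero((v >= comp.v_th) & ~in_ref)[0]
        if len(spiked):
            v[spiked] = comp.v_reset[spiked]
            refrac[spiked] = comp.t_ref_steps[spiked]
            out_ids.append(spiked)
            out_times.append(np.full(len(spiked), (t + 1) * dt))

        # schedule deliveries from this step's emitters (recurrent + virtual)
        emitters = [spiked] if len(spiked) else []
        if t in input_events:
            emitters.extend(input_events[t])
        if emitters and comp.delay_groups:
            all_src = np.concatenate(emitters) if len(emitters) > 1 else emitters[0]
            for d in delays:
                mat = comp.delay_groups[d]
                contrib = np.asarray(mat[all_src].sum(axis=0)).ravel()
                ring[(t + d) % horizon] += contrib

        if v_trace is not None:
            v_trace[t] = v[rec_gids]

        if writer is not None:
            if len(spiked):
                writer.append(spiked, np.full(len(spiked), (t + 1) * dt))
            if checkpoint_steps and (t + 1) % checkpoint_steps == 0:
                writer.checkpoint()

    if writer is not None:
        writer.close()

    if out_ids:
        gids = np.concatenate(out_ids)
        times = np.concatenate(out_times)
        if len(comp.neuron_offsets) == 1:
            pop_name = next(iter(comp.neuron_offsets))
            spikes = SpikeSet.from_arrays(pop_name, gids, times, sort="by_time")
        else:
            # map global indices back to (population, local id)
            pops = np.empty(len(gids), dtype=object)
            local = gids.copy()
            for name, off in comp.neuron_offsets.items():
                n_pop = net.node_populations[name].n_nodes
                m = (gids >= off) & (gids < off + n_pop)
                pops[m] = name
                local[m] = gids[m] - off
            spikes = SpikeSet(pops, local, times).sorted("by_time")
    else:
        spikes = SpikeSet(sort_order="by_time")

    reports: dict[str, ReportSeries] = {}
    if v_trace is not None:
        reports["membrane_voltage"] = ReportSeries(
            variable="membrane_voltage", dt=dt, start=dt, data=v_trace,
            channel_ids=rec_gids, units="mV")
    return spikes, reports
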