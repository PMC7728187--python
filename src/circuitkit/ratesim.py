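"""Delayed firing-rate dynamics for small graphs of neuronal populations.

Each population a follows Wilson–Cowan-type relaxation dynamics

    tau_a dr_a/dt = -r_a + F_a( sum_b w_ab r_b(t - d_ab) + I_ext_a )

with monotone nonnegative gain F (threshold-linear or logistic), signed
coupling weights w_ab (Hz-to-drive units), and per-connection transmission
delays handled by ring buffers.  Integration is explicit Euler at fixed dt.
External stimulus populations are modeled as constant-rate sources: their
pooled output is treated as stationary even though the underlying source
neurons fire irregularly.

This is a rate-equation reduction, not a population-density (master
equation) solver: it tracks mean rates only, with no finite-size noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import NetworkModel, ReportSeries

__all__ = [
    "PopulationNode",
    "PopulationConnection",
    "RateModel",
    "reduce_network",
    "simulate_rates",
    "fixed_point",
]


@dataclass
class PopulationNode:
    """One population: relaxation time constant, gain function, drive.

    gain: "threshold_linear" -> F(x) = slope * max(0, x - threshold)
          "logistic"         -> F(x) = max_rate / (1 + exp(-slope*(x - threshold)))
    external_drive is in the same drive units as w*r.
    """

    name: str
    tau_r: float = 10.0
    gain: str = "threshold_linear"
    threshold: float = 0.0
    slope: float = 1.0
    max_rate: float = 1000.0
    external_drive: float = 0.0
    is_source: bool = False  # constant-rate external population
    source_rate: float = 0.0

    def __post_init__(self):
        if self.tau_r <= 0:
            raise ValueError("tau_r must be positive")
        if self.gain not in ("threshold_linear", "logistic"):
            raise ValueError(f"unknown gain {self.gain!r}")

    def F(self, x: np.ndarray | float) -> np.ndarray | float:
        if self.gain == "threshold_linear":
            return self.slope * np.maximum(0.0, x - self.threshold)
        return self.max_rate / (1.0 + np.exp(-self.slope * (x - self.threshold)))


@dataclass
class PopulationConnection:
    """Directed rate coupling source -> target with weight and delay (ms)."""

    source: str
    target: str
    weight: float
    delay: float = 0.0

    def __post_init__(self):
        if self.delay < 0:
            raise ValueError("delay must be >= 0")


@dataclass
class RateModel:
    nodes: list[PopulationNode] = field(default_factory=list)
    connections: list[PopulationConnection] = field(default_factory=list)

    def node_index(self) -> dict[str, int]:
        return {n.name: i for i, n in enumerate(self.nodes)}

    def validate(self, dale: bool = False) -> None:
        idx = self.node_index()
        if len(idx) != len(self.nodes):
            raise ValueError("duplicate population names")
        for c in self.connections:
            if c.source not in idx or c.target not in idx:
                raise ValueError(f"connection {c.source}->{c.target} references unknown node")
        if dale:
            sign: dict[str, int] = {}
            for c in self.connections:
                s = int(np.sign(c.weight))
                if s == 0:
                    continue
                if sign.setdefault(c.source, s) != s:
                    raise ValueError(f"population {c.source!r} emits mixed-sign weights")


def reduce_network(net: NetworkModel, grouping: dict[int, str],
                   sign_by_group: dict[str, int] | None = None) -> RateModel:
    """Collapse a spiking network to one rate node per group.

    ``grouping`` maps node_type_id -> group name; every node type used in the
    network must be mapped, and every group must be non-empty.  The coupling
    weight between groups is (mean |syn_weight * nsyns| over edges) x (mean
    in-degree per target-group neuron), signed by the source group
    (``sign_by_group``, default +1); delays are averaged.  Virtual groups
    become constant-rate source nodes.
    """
    used_types = set()
    for pop in net.node_populations.values():
        used_types.update(int(t) for t in np.unique(pop.node_type_ids))
    unmapped = used_types - set(grouping)
    if unmapped:
        raise ValueError(f"node types not mapped to any group: {sorted(unmapped)}")

    group_sizes: dict[str, int] = {}
    group_virtual: dict[str, bool] = {}
    node_to_group: dict[str, np.ndarray] = {}
    for pname, pop in net.node_populations.items():
        groups = np.array([grouping[int(t)] for t in pop.node_type_ids], dtype=object)
        node_to_group[pname] = groups
        for g in np.unique(groups):
            group_sizes[g] = group_sizes.get(g, 0) + int(np.sum(groups == g))
            mt = {str(net.node_types.row(int(t)).get("model_type"))
                  for t in np.unique(pop.node_type_ids[groups == g])}
            group_virtual[g] = group_virtual.get(g, True) and mt <= {"virtual", "filter"}
    empty = [g for g, n in group_sizes.items() if n == 0]
    if empty:
        raise ValueError(f"empty groups: {empty}")

    sign_by_group = sign_by_group or {}
    # accumulate per (source group, target group): total weight, count, delays
    acc: dict[tuple[str, str], list] = {}
    for ep in net.edge_populations.values():
        src_groups = node_to_group[ep.source_population][ep.source_node_ids]
        tgt_groups = node_to_group[ep.target_population][ep.target_node_ids]
        w = _edge_attr(ep, net, "syn_weight", 0.0) * _edge_attr(ep, net, "nsyns", 1.0)
        d = _edge_attr(ep, net, "delay", 0.0)
        s_names, s_codes = np.unique(src_groups.astype(str), return_inverse=True)
        t_names, t_codes = np.unique(tgt_groups.astype(str), return_inverse=True)
        combo = s_codes * len(t_names) + t_codes
        for code in np.unique(combo):
            m = combo == code
            sg = str(s_names[code // len(t_names)])
            tg = str(t_names[code % len(t_names)])
            entry = acc.setdefault((sg, tg), [0.0, 0, 0.0])
            entry[0] += float(np.abs(w[m]).sum())
            entry[1] += int(m.sum())
            entry[2] += float(d[m].sum())

    model = RateModel()
    for g in sorted(group_sizes):
        model.nodes.append(PopulationNode(name=g, is_source=group_virtual[g]))
    for (sg, tg), (w_total, n_edges, d_total) in sorted(acc.items()):
        mean_w = w_total / n_edges
        mean_indegree = n_edges / group_sizes[tg]
        sign = sign_by_group.get(sg, 1)
        model.connections.append(PopulationConnection(
            source=sg, target=tg, weight=sign * mean_w * mean_indegree,
            delay=d_total / n_edges))
    model.validate()
    return model


def _edge_attr(ep, net, key, default):
    if key in ep.attributes:
        return np.asarray(ep.attributes[key], dtype=float)
    out = np.full(ep.n_edges, default, dtype=float)
    for t in np.unique(ep.edge_type_ids):
        row = net.edge_types.row(int(t))
        if key in row:
            out[ep.edge_type_ids == t] = float(row[key])
    return out


def simulate_rates(model: RateModel, duration: float, dt: float = 0.1,
                   initial_rates: dict[str, float] | None = None) -> ReportSeries:
    """Integrate the delayed rate equations; returns rates (Hz) per node.

    Explicit Euler with per-connection delay ring buffers; dt must not exceed
    any positive delay.  Source nodes stay clamped at their constant rate.
    Rates are nonnegative at every step by construction of the gain.
    """
    model.validate()
    if dt <= 0:
        raise ValueError("dt must be positive")
    pos_delays = [c.delay for c in model.connections if c.delay > 0]
    if pos_delays and dt > min(pos_delays) + 1e-12:
        raise ValueError(f"dt={dt} exceeds minimum positive delay {min(pos_delays)}")
    idx = model.node_index()
    n = len(model.nodes)
    n_steps = int(round(duration / dt))

    delay_steps = np.array([int(round(c.delay / dt)) for c in model.connections])
    horizon = int(delay_steps.max()) + 1 if len(delay_steps) else 1
    src = np.array([idx[c.source] for c in model.connections], dtype=np.int64)
    tgt = np.array([idx[c.target] for c in model.connections], dtype=np.int64)
    w = np.array([c.weight for c in model.connections])

    r = np.zeros(n)
    for i, node in enumerate(model.nodes):
        if node.is_source:
            r[i] = node.source_rate
        elif initial_rates and node.name in initial_rates:
            r[i] = initial_rates[node.name]
    source_mask = np.array([node.is_source for node in model.nodes])
    drive_ext = np.array([node.external_drive for node in model.nodes])
    tau = np.array([node.tau_r for node in model.nodes])

    history = np.tile(r, (horizon, 1))  # constant pre-history
    out = np.empty((n_steps, n))

    for t in range(n_steps):
        delayed = np.where(delay_steps == 0, r[src],
                           history[(t - delay_steps) % horizon, src])
        drive = drive_ext.copy()
        np.add.at(drive, tgt, w * delayed)
        F = np.array([model.nodes[i].F(drive[i]) for i in range(n)])
        r = r + (dt / tau) * (-r + F)
        r = np.maximum(r, 0.0)
        r[source_mask] = np.array([node.source_rate for node in model.nodes])[source_mask]
        if not np.all(np.isfinite(r)):
            raise RuntimeError(f"rate dynamics diverged at t={t * dt:.3f} ms")
        history[t % horizon] = r
        out[t] = r

    return ReportSeries(variable="firing_rate", dt=dt, start=dt, data=out,
                        channel_ids=np.arange(n), units="Hz")


def fixed_point(model: RateModel, max_iter: int = 10_000, tol: float = 1e-12,
                damping: float = 0.5) -> tuple[dict[str, float], bool]:
    """Solve r = F(W r + I) by damped fixed-point iteration.

    Returns (rates by name, converged flag); on non-convergence the last
    iterate is returned with the flag False.
    """
    model.validate()
    idx = model.node_index()
    n = len(model.nodes)
    W = np.zeros((n, n))
    for c in model.connections:
        W[idx[c.target], idx[c.source]] += c.weight
    drive_ext = np.array([node.external_drive for node in model.nodes])
    source_mask = np.array([node.is_source for node in model.nodes])
    source_rates = np.array([node.source_rate for node in model.nodes])

    r = source_rates * source_mask
    converged = False
    for _ in range(max_iter):
        F = np.array([model.nodes[i].F((W @ r + drive_ext)[i]) for i in range(n)])
        F[source_mask] = source_rates[source_mask]
        r_new = (1 - damping) * r + damping * F
        if np.max(np.abs(r_new - r)) < tol:
            r = r_new
            converged = True
            break
        r = r_new
    return {node.name: float(r[i]) for i, node in enumerate(model.nodes)}, converged
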