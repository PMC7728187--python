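"""Declarative network construction.

A :class:`NetworkBuilder` accumulates ``add_nodes`` / ``add_edges`` calls and
instantiates them into a :class:`~circuitkit.model.NetworkModel`.  Edges are
drawn as independent Bernoulli trials per ordered (source, target) pair, with
the connection probability supplied by a :class:`ConnectionRule` —
fixed probability, Gaussian fall-off with intersomatic distance, all-to-all,
one-to-one, fixed in-degree, or a user callable.

Determinism contract: the whole build is a pure function of the declarative
spec and the master seed.  Each ``add_edges`` call draws from its own RNG
sub-stream keyed by (master seed, call index), so adding a later rule never
perturbs the edges an earlier rule produced.  Edges are emitted in
(source, target) lexicographic order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .model import (
    EdgePopulation,
    IntegrityError,
    NetworkModel,
    NodePopulation,
)
from .sonata import write_network

log = logging.getLogger(__name__)

__all__ = [
    "ConnectionRule",
    "EdgePropertySpec",
    "NetworkBuilder",
    "positions_cylinder",
    "build_from_spec",
]

RULE_KINDS = ("fixed_probability", "gaussian_distance", "all_to_all", "one_to_one",
              "fixed_indegree", "custom")

# Bernoulli draws are evaluated in blocks of source rows to bound peak memory
# (a 12,500^2 pair matrix would otherwise need ~1.2 GB of uniforms at once).
_BLOCK_PAIRS = 8_000_000


@dataclass
class ConnectionRule:
    """Probability rule deciding, per ordered (source, target) pair, whether
    an edge exists.

    kinds
    -----
    fixed_probability : connect with probability ``p``
    gaussian_distance : connect with probability ``amplitude *
        exp(-d^2 / (2 sigma_d^2))`` where d is the 3-D intersomatic distance (µm)
    all_to_all        : probability 1
    one_to_one        : i-th selected source to i-th selected target
    fixed_indegree    : every target receives exactly ``indegree`` sources
        drawn uniformly without replacement
    custom            : ``func(source_attrs, target_attrs, distance) -> p``,
        a pure function returning probabilities in [0, 1]
    """

    kind: str
    p: float | None = None
    amplitude: float | None = None
    sigma_d: float | None = None
    indegree: int | None = None
    func: Callable | None = None
    allow_autapses: bool = False

    def __post_init__(self):
        if self.kind not in RULE_KINDS:
            raise ValueError(f"unknown connection rule kind {self.kind!r}")
        if self.kind == "fixed_probability":
            if self.p is None or not (0.0 <= self.p <= 1.0):
                raise ValueError(f"fixed_probability requires p in [0,1], got {self.p}")
        if self.kind == "gaussian_distance":
            if self.amplitude is None or not (0.0 <= self.amplitude <= 1.0):
                raise ValueError("gaussian_distance requires amplitude in [0,1]")
            if self.sigma_d is None or self.sigma_d <= 0:
                raise ValueError("gaussian_distance requires sigma_d > 0 (µm)")
        if self.kind == "fixed_indegree" and (self.indegree is None or self.indegree < 0):
            raise ValueError("fixed_indegree requires indegree >= 0")
        if self.kind == "custom" and self.func is None:
            raise ValueError("custom rule requires func")


@dataclass
class EdgePropertySpec:
    """Per-edge properties attached by one ``add_edges`` call.

    ``syn_weight`` / ``delay`` / ``nsyns`` may be scalars (stored on the edge
    type, not per edge) or callables ``f(rng, n) -> array`` for per-edge
    generation.  Extra constant columns go in ``extra``.
    """

    syn_weight: float | Callable = 1.0
    delay: float | Callable = 1.0
    nsyns: int | Callable = 1
    extra: dict = field(default_factory=dict)

    def validate(self):
        if not callable(self.delay) and self.delay < 0:
            raise ValueError("delay must be >= 0 ms")
        if not callable(self.nsyns) and self.nsyns < 1:
            raise ValueError("nsyns must be >= 1")


def positions_cylinder(n: int, radius: float, height: float,
                       seed: int | np.random.Generator = 0) -> np.ndarray:
    """n points i.i.d. uniform in a cylinder of given radius/height (µm).

    The cylinder axis is the depth axis z, spanning [0, height]; returns an
    (n, 3) array of (x, y, z).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if radius <= 0 or height <= 0:
        raise ValueError("radius and height must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r = radius * np.sqrt(rng.random(n))
    theta = 2 * np.pi * rng.random(n)
    z = height * rng.random(n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


class NetworkBuilder:
    """Incrementally assemble a network, then instantiate and save it."""

    def __init__(self, name: str = "network", seed: int = 0):
        self.name = name
        self.seed = int(seed)
        self.model = NetworkModel(metadata={"builder_seed": self.seed, "name": name})
        self._next_node_type_id = 100
        self._next_edge_type_id = 100
        self._edge_call_index = 0

    # -- nodes -------------------------------------------------------------

    def add_nodes(self, n: int, population: str, per_node: dict | None = None,
                  **type_attrs) -> np.ndarray:
        """Append ``n`` nodes of a fresh node type to ``population``.

        ``type_attrs`` become one row of the node-type table (``model_type``
        required).  ``per_node`` maps attribute name → array of length n or
        callable ``f(rng, n) -> array``; generators are evaluated on the
        builder's node RNG stream.  Returns the new node ids.
        """
        if n < 1:
            raise ValueError("n must be >= 1")
        type_id = self._next_node_type_id
        self._next_node_type_id += 1
        self.model.node_types.add(type_id, **type_attrs)

        rng = np.random.default_rng(np.random.SeedSequence((self.seed, 0, type_id)))
        attrs: dict[str, np.ndarray] = {}
        for key, gen in (per_node or {}).items():
            values = np.asarray(gen(rng, n) if callable(gen) else gen)
            if len(values) != n:
                raise ValueError(f"per-node generator {key!r} produced {len(values)} values, expected {n}")
            attrs[key] = values

        if population in self.model.node_populations:
            pop = self.model.node_populations[population]
            old_n = pop.n_nodes
            merged_types = np.concatenate([pop.node_type_ids, np.full(n, type_id, dtype=np.int64)])
            merged_attrs: dict[str, np.ndarray] = {}
            for key in set(pop.attributes) | set(attrs):
                old = pop.attributes.get(key)
                new = attrs.get(key)
                if old is None:
                    old = np.full(old_n, np.nan)
                if new is None:
                    new = np.full(n, np.nan)
                merged_attrs[key] = np.concatenate([np.asarray(old, dtype=float) if
                                                    np.asarray(old).dtype.kind in "fi" and
                                                    np.asarray(new).dtype.kind in "fi"
                                                    else np.asarray(old, dtype=object),
                                                    np.asarray(new)])
            self.model.node_populations[population] = NodePopulation(
                population, merged_types, merged_attrs)
            return np.arange(old_n, old_n + n, dtype=np.int64)

        self.model.add_node_population(NodePopulation(population, np.full(n, type_id,
                                                                          dtype=np.int64), attrs))
        return np.arange(n, dtype=np.int64)

    # -- edges -------------------------------------------------------------

    def add_edges(self, source_population: str, target_population: str,
                  rule: ConnectionRule, props: EdgePropertySpec | None = None,
                  source_filter: Callable | np.ndarray | None = None,
                  target_filter: Callable | np.ndarray | None = None,
                  name: str | None = None) -> int:
        """Draw edges under ``rule`` between filtered node sets; returns count.

        Filters are either explicit node-id arrays or callables taking the
        node population and returning a boolean mask / id array.  Autapses
        (source == target within the same population) are excluded unless the
        rule's ``allow_autapses`` flag is set.
        """
        props = props or EdgePropertySpec()
        props.validate()
        src_pop = self._require_population(source_population)
        tgt_pop = self._require_population(target_population)
        src_ids = _resolve_filter(src_pop, source_filter)
        tgt_ids = _resolve_filter(tgt_pop, target_filter)
        if len(src_ids) == 0 or len(tgt_ids) == 0:
            raise ValueError("source and target filters must each select at least one node")

        rng = np.random.default_rng(
            np.random.SeedSequence((self.seed, 1, self._edge_call_index)))
        self._edge_call_index += 1

        sources, targets = _draw_edges(rule, src_pop, tgt_pop, src_ids, tgt_ids,
                                       source_population == target_population, rng)
        n_edges = len(sources)

        edge_type_id = self._next_edge_type_id
        self._next_edge_type_id += 1
        type_row = {"source_population": source_population,
                    "target_population": target_population}
        edge_attrs: dict[str, np.ndarray] = {}
        for key, value in (("syn_weight", props.syn_weight), ("delay", props.delay),
                           ("nsyns", props.nsyns)):
            if callable(value):
                edge_attrs[key] = np.asarray(value(rng, n_edges))
            else:
                type_row[key] = value
        type_row.update(props.extra)
        self.model.edge_types.add(edge_type_id, **type_row)

        pop_name = name or f"{source_population}_to_{target_population}"
        new = EdgePopulation(
            name=pop_name,
            source_population=source_population,
            target_population=target_population,
            source_node_ids=sources,
            target_node_ids=targets,
            edge_type_ids=np.full(n_edges, edge_type_id, dtype=np.int64),
            attributes=edge_attrs,
        )
        if pop_name in self.model.edge_populations:
            self.model.edge_populations[pop_name] = _concat_edges(
                self.model.edge_populations[pop_name], new)
        else:
            self.model.add_edge_population(new)
        return n_edges

    def _require_population(self, name: str) -> NodePopulation:
        if name not in self.model.node_populations:
            raise IntegrityError(f"unknown node population {name!r}")
        return self.model.node_populations[name]

    # -- instantiation -----------------------------------------------------

    def instantiate_and_save(self, directory) -> list[str]:
        """Persist the built network; deterministic given (spec, seed)."""
        if not self.model.node_populations:
            raise IntegrityError("cannot save a network with no node populations")
        return write_network(self.model, directory)


def _resolve_filter(pop: NodePopulation, flt) -> np.ndarray:
    if flt is None:
        return pop.node_ids
    if callable(flt):
        out = np.asarray(flt(pop))
        if out.dtype == bool:
            return np.nonzero(out)[0]
        return out.astype(np.int64)
    out = np.asarray(flt)
    if out.dtype == bool:
        return np.nonzero(out)[0]
    return out.astype(np.int64)


def _positions(pop: NodePopulation, ids: np.ndarray) -> np.ndarray:
    cols = []
    for axis in ("x", "y", "z"):
        if axis in pop.attributes:
            cols.append(np.asarray(pop.attributes[axis], dtype=float)[ids])
        else:
            cols.append(np.zeros(len(ids)))
    return np.column_stack(cols)


def _draw_edges(rule: ConnectionRule, src_pop, tgt_pop, src_ids, tgt_ids,
                recurrent: bool, rng: np.random.Generator):
    ns, nt = len(src_ids), len(tgt_ids)

    if rule.kind == "one_to_one":
        if ns != nt:
            raise ValueError(f"one_to_one requires equal set sizes, got {ns} and {nt}")
        return src_ids.copy(), tgt_ids.copy()

    if rule.kind == "fixed_indegree":
        k = rule.indegree
        if k > ns:
            raise ValueError(f"fixed_indegree {k} exceeds source count {ns}")
        sources = np.empty(nt * k, dtype=np.int64)
        targets = np.repeat(tgt_ids, k)
        for j in range(nt):
            pool = src_ids
            if recurrent and not rule.allow_autapses:
                pool = src_ids[src_ids != tgt_ids[j]]
                if k > len(pool):
                    raise ValueError("fixed_indegree too large after autapse exclusion")
            sources[j * k:(j + 1) * k] = np.sort(rng.choice(pool, size=k, replace=False))
        order = np.lexsort((targets, sources))
        return sources[order], targets[order]

    # probability-matrix kinds, evaluated in source-row blocks
    rows_per_block = max(1, _BLOCK_PAIRS // max(nt, 1))
    out_s, out_t = [], []
    need_dist = rule.kind in ("gaussian_distance", "custom")
    tgt_xyz = _positions(tgt_pop, tgt_ids) if need_dist else None

    for lo in range(0, ns, rows_per_block):
        hi = min(ns, lo + rows_per_block)
        block_src = src_ids[lo:hi]
        if rule.kind == "all_to_all":
            mask = np.ones((hi - lo, nt), dtype=bool)
        else:
            if rule.kind == "fixed_probability":
                p = rule.p
                mask = rng.random((hi - lo, nt)) < p
            else:
                d = np.linalg.norm(_positions(src_pop, block_src)[:, None, :] -
                                   tgt_xyz[None, :, :], axis=2)
                if rule.kind == "gaussian_distance":
                    p = rule.amplitude * np.exp(-d * d / (2.0 * rule.sigma_d ** 2))
                else:
                    p = np.asarray(rule.func(
                        {k: v[block_src] for k, v in src_pop.attributes.items()},
                        {k: v[tgt_ids] for k, v in tgt_pop.attributes.items()}, d),
                        dtype=float)
                    bad = (p < 0) | (p > 1)
                    if bad.any():
                        i, j = np.argwhere(bad)[0]
                        raise ValueError(
                            f"custom rule probability {p[i, j]} outside [0,1] for pair "
                            f"(source {block_src[i]}, target {tgt_ids[j]})")
                mask = rng.random((hi - lo, nt)) < p
        if recurrent and not rule.allow_autapses:
            same = block_src[:, None] == tgt_ids[None, :]
            mask &= ~same
        si, ti = np.nonzero(mask)
        out_s.append(block_src[si])
        out_t.append(tgt_ids[ti])

    sources = np.concatenate(out_s) if out_s else np.empty(0, dtype=np.int64)
    targets = np.concatenate(out_t) if out_t else np.empty(0, dtype=np.int64)
    return sources, targets


def _concat_edges(a: EdgePopulation, b: EdgePopulation) -> EdgePopulation:
    if (a.source_population, a.target_population) != (b.source_population, b.target_population):
        raise IntegrityError(
            f"cannot merge edge population {a.name!r}: endpoint populations differ")
    attrs = {}
    for key in set(a.attributes) | set(b.attributes):
        x = a.attributes.get(key, np.full(a.n_edges, np.nan))
        y = b.attributes.get(key, np.full(b.n_edges, np.nan))
        attrs[key] = np.concatenate([np.asarray(x), np.asarray(y)])
    return EdgePopulation(
        name=a.name,
        source_population=a.source_population,
        target_population=a.target_population,
        source_node_ids=np.concatenate([a.source_node_ids, b.source_node_ids]),
        target_node_ids=np.concatenate([a.target_node_ids, b.target_node_ids]),
        edge_type_ids=np.concatenate([a.edge_type_ids, b.edge_type_ids]),
        attributes=attrs,
    )


# ---------------------------------------------------------------------------
# declarative build specs
# ---------------------------------------------------------------------------

def build_from_spec(spec: dict, seed: int | None = None) -> NetworkBuilder:
    """Build a network from a declarative (JSON-compatible) spec.

    Spec layout::

        {"name": ..., "seed": ...,
         "nodes": [{"population", "n", "type_attrs": {...},
                    "positions": {"kind": "cylinder", "radius", "height"}}, ...],
         "edges": [{"source", "target", "rule": {"kind", ...},
                    "props": {"syn_weight", "delay", "nsyns"}}, ...]}

    ``seed`` overrides the spec's seed when given.
    """
    builder = NetworkBuilder(name=spec.get("name", "network"),
                             seed=int(spec["seed"] if seed is None else seed))
    for block in spec.get("nodes", []):
        per_node = None
        pos = block.get("positions")
        if pos:
            if pos.get("kind") != "cylinder":
                raise ValueError(f"unknown position kind {pos.get('kind')!r}")
            radius, height = float(pos["radius"]), float(pos["height"])

            def gen_positions(rng, n, _r=radius, _h=height):
                return positions_cylinder(n, _r, _h, rng)

            per_node = {"_xyz": gen_positions}
        ids = builder.add_nodes(int(block["n"]), block["population"],
                                **block.get("type_attrs", {}))
        if per_node:
            pop = builder.model.node_populations[block["population"]]
            rng = np.random.default_rng(
                np.random.SeedSequence((builder.seed, 0, int(pop.node_type_ids[ids[0]]))))
            xyz = per_node["_xyz"](rng, len(ids))
            for i, axis in enumerate(("x", "y", "z")):
                col = pop.attributes.get(axis, np.full(pop.n_nodes, np.nan))
                col = np.asarray(col, dtype=float)
                col[ids] = xyz[:, i]
                pop.attributes[axis] = col
    for block in spec.get("edges", []):
        rule = ConnectionRule(**block["rule"])
        props = EdgePropertySpec(**block.get("props", {}))
        builder.add_edges(block["source"], block["target"], rule, props,
                          name=block.get("name"))
    return builder
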