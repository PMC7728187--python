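"""In-memory containers for network models, spikes, and report time series.

The on-disk dialect (HDF5 node/edge tables, delimited-text type tables,
HDF5 spike files) lives in :mod:`circuitkit.sonata`; this module holds the
containers those readers and writers round-trip.

Conventions fixed across the whole package: node/edge ids are 0-based
integers, times are in milliseconds, positions in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NodeTypeTable",
    "EdgeTypeTable",
    "NodePopulation",
    "EdgePopulation",
    "NetworkModel",
    "SpikeSet",
    "ReportSeries",
    "IntegrityError",
]

#: model_type values understood by the simulators.
MODEL_TYPES = ("point_process", "rate_population", "filter", "virtual", "compartmental_toy")


class IntegrityError(ValueError):
    """A referential-integrity violation in a network model or file."""


class _TypeTable:
    """A table of shared parameters keyed by a type id.

    Wraps a :class:`pandas.DataFrame` indexed by the type-id column.  Unknown
    columns are carried verbatim so that attributes used by one level of
    resolution survive a round-trip through another.
    """

    id_column: str = "type_id"

    def __init__(self, frame: pd.DataFrame | None = None):
        if frame is None:
            frame = pd.DataFrame(index=pd.Index([], name=self.id_column, dtype=np.int64))
        if frame.index.name != self.id_column:
            if self.id_column not in frame.columns:
                raise ValueError(f"type table needs a {self.id_column!r} column")
            frame = frame.set_index(self.id_column)
        if frame.index.has_duplicates:
            dup = frame.index[frame.index.duplicated()].tolist()
            raise IntegrityError(f"duplicate {self.id_column} values: {dup}")
        if (frame.index < 0).any():
            raise IntegrityError(f"{self.id_column} must be non-negative")
        self.frame = frame

    def __contains__(self, type_id: int) -> bool:
        return type_id in self.frame.index

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def ids(self) -> np.ndarray:
        return self.frame.index.to_numpy()

    def row(self, type_id: int) -> dict:
        """Parameters of one type as a plain dict (NaN/None entries dropped)."""
        row = self.frame.loc[type_id]
        return {k: v for k, v in row.items() if not _is_null(v)}

    def add(self, type_id: int, **attrs) -> None:
        if type_id in self.frame.index:
            raise IntegrityError(f"{self.id_column} {type_id} already defined")
        new = pd.DataFrame([attrs], index=pd.Index([type_id], name=self.id_column))
        self.frame = new if self.frame.empty else pd.concat([self.frame, new])

    def equals(self, other: "_TypeTable") -> bool:
        a = self.frame.sort_index().sort_index(axis=1)
        b = other.frame.sort_index().sort_index(axis=1)
        if a.shape != b.shape or list(a.columns) != list(b.columns):
            return False
        if not a.index.equals(b.index):
            return False
        for col in a.columns:
            x, y = a[col].to_numpy(), b[col].to_numpy()
            both_null = [_is_null(u) and _is_null(v) for u, v in zip(x, y)]
            eq = [bn or _scalar_eq(u, v) for u, v, bn in zip(x, y, both_null)]
            if not all(eq):
                return False
        return True


def _is_null(v) -> bool:
    if v is None:
        return True
    try:
        return bool(pd.isna(v))
    except (TypeError, ValueError):
        return False


def _scalar_eq(u, v) -> bool:
    if isinstance(u, float) or isinstance(v, float):
        try:
            return bool(np.isclose(float(u), float(v), rtol=0, atol=0)) or u == v
        except (TypeError, ValueError):
            return u == v
    return u == v


class NodeTypeTable(_TypeTable):
    """Shared node parameters keyed by ``node_type_id``.

    Every row must carry ``model_type`` (one of ``point_process``,
    ``rate_population``, ``filter``, ``virtual``, ``compartmental_toy``);
    all other columns — dynamics parameters, free-form labels such as
    ``cell_class`` or ``ei`` — are arbitrary.
    """

    id_column = "node_type_id"

    def __init__(self, frame: pd.DataFrame | None = None):
        super().__init__(frame)
        if len(self.frame) and "model_type" not in self.frame.columns:
            raise IntegrityError("node type table must have a model_type column")
        if len(self.frame):
            missing = self.frame.index[self.frame["model_type"].map(_is_null)]
            if len(missing):
                raise IntegrityError(f"model_type missing for node_type_id {missing.tolist()}")

    def add(self, type_id: int, **attrs) -> None:
        if "model_type" not in attrs:
            raise IntegrityError("node type requires model_type")
        if attrs["model_type"] not in MODEL_TYPES:
            raise IntegrityError(f"unknown model_type {attrs['model_type']!r}")
        super().add(type_id, **attrs)


class EdgeTypeTable(_TypeTable):
    """Shared edge parameters keyed by ``edge_type_id``."""

    id_column = "edge_type_id"


@dataclass
class NodePopulation:
    """A named set of nodes with contiguous 0-based ids.

    ``attributes`` maps column name → array of length ``n_nodes``; reserved
    names used elsewhere are ``x``/``y``/``z`` (µm) and ``tuning_angle``
    (degrees), but any column may be attached.
    """

    name: str
    node_type_ids: np.ndarray
    attributes: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.node_type_ids = np.asarray(self.node_type_ids, dtype=np.int64)
        self.attributes = {k: np.asarray(v) for k, v in self.attributes.items()}
        for k, v in self.attributes.items():
            if len(v) != self.n_nodes:
                raise IntegrityError(
                    f"attribute {k!r} has length {len(v)} != {self.n_nodes} in population {self.name!r}"
                )

    @property
    def n_nodes(self) -> int:
        return len(self.node_type_ids)

    @property
    def node_ids(self) -> np.ndarray:
        return np.arange(self.n_nodes, dtype=np.int64)

    def validate_types(self, types: NodeTypeTable) -> None:
        unknown = np.setdiff1d(np.unique(self.node_type_ids), types.ids)
        if unknown.size:
            raise IntegrityError(
                f"population {self.name!r} references undefined node_type_id {unknown.tolist()}"
            )

    def equals(self, other: "NodePopulation") -> bool:
        if self.name != other.name or self.n_nodes != other.n_nodes:
            return False
        if not np.array_equal(self.node_type_ids, other.node_type_ids):
            return False
        if set(self.attributes) != set(other.attributes):
            return False
        return all(_array_eq(self.attributes[k], other.attributes[k]) for k in self.attributes)


@dataclass
class EdgePopulation:
    """Directed edges between two node populations.

    Reserved per-edge attributes: ``syn_weight`` (model-specific units),
    ``delay`` (ms, ≥ 0) and ``nsyns`` (positive integer count of synapses the
    edge stands for).  Arbitrary extra columns (e.g. dendritic targeting
    descriptors) are carried through unchanged even though the point and rate
    simulators ignore them.
    """

    name: str
    source_population: str
    target_population: str
    source_node_ids: np.ndarray
    target_node_ids: np.ndarray
    edge_type_ids: np.ndarray
    attributes: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.source_node_ids = np.asarray(self.source_node_ids, dtype=np.int64)
        self.target_node_ids = np.asarray(self.target_node_ids, dtype=np.int64)
        self.edge_type_ids = np.asarray(self.edge_type_ids, dtype=np.int64)
        n = self.n_edges
        if len(self.target_node_ids) != n or len(self.edge_type_ids) != n:
            raise IntegrityError(f"edge population {self.name!r}: column lengths disagree")
        self.attributes = {k: np.asarray(v) for k, v in self.attributes.items()}
        for k, v in self.attributes.items():
            if len(v) != n:
                raise IntegrityError(
                    f"edge attribute {k!r} has length {len(v)} != {n} in population {self.name!r}"
                )
        if "delay" in self.attributes and n and float(np.min(self.attributes["delay"])) < 0:
            raise IntegrityError(f"negative delay in edge population {self.name!r}")

    @property
    def n_edges(self) -> int:
        return len(self.source_node_ids)

    def equals(self, other: "EdgePopulation") -> bool:
        if (
            self.name != other.name
            or self.source_population != other.source_population
            or self.target_population != other.target_population
            or self.n_edges != other.n_edges
        ):
            return False
        for a, b in (
            (self.source_node_ids, other.source_node_ids),
            (self.target_node_ids, other.target_node_ids),
            (self.edge_type_ids, other.edge_type_ids),
        ):
            if not np.array_equal(a, b):
                return False
        if set(self.attributes) != set(other.attributes):
            return False
        return all(_array_eq(self.attributes[k], other.attributes[k]) for k in self.attributes)


def _array_eq(a: np.ndarray, b: np.ndarray) -> bool:
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        return False
    if a.dtype.kind == "f" or b.dtype.kind == "f":
        return np.array_equal(a.astype(float), b.astype(float), equal_nan=True)
    return np.array_equal(a.astype(str) if a.dtype.kind in "US" else a,
                          b.astype(str) if b.dtype.kind in "US" else b)


@dataclass
class NetworkModel:
    """A complete network: node/edge populations plus their type tables."""

    node_populations: dict[str, NodePopulation] = field(default_factory=dict)
    edge_populations: dict[str, EdgePopulation] = field(default_factory=dict)
    node_types: NodeTypeTable = field(default_factory=NodeTypeTable)
    edge_types: EdgeTypeTable = field(default_factory=EdgeTypeTable)
    metadata: dict = field(default_factory=dict)

    def add_node_population(self, pop: NodePopulation) -> None:
        if pop.name in self.node_populations:
            raise IntegrityError(f"node population {pop.name!r} already exists")
        self.node_populations[pop.name] = pop

    def add_edge_population(self, pop: EdgePopulation) -> None:
        if pop.name in self.edge_populations:
            raise IntegrityError(f"edge population {pop.name!r} already exists")
        self.edge_populations[pop.name] = pop

    @property
    def n_nodes(self) -> int:
        return sum(p.n_nodes for p in self.node_populations.values())

    @property
    def n_edges(self) -> int:
        return sum(p.n_edges for p in self.edge_populations.values())

    def validate(self) -> None:
        """Raise :class:`IntegrityError` on any dangling reference."""
        for pop in self.node_populations.values():
            pop.validate_types(self.node_types)
        for ep in self.edge_populations.values():
            for role, pname, ids in (
                ("source", ep.source_population, ep.source_node_ids),
                ("target", ep.target_population, ep.target_node_ids),
            ):
                if pname not in self.node_populations:
                    raise IntegrityError(
                        f"edge population {ep.name!r} references unknown {role} population {pname!r}"
                    )
                n = self.node_populations[pname].n_nodes
                if ids.size and (ids.min() < 0 or ids.max() >= n):
                    raise IntegrityError(
                        f"edge population {ep.name!r}: {role} node id out of range for {pname!r} (n={n})"
                    )
            unknown = np.setdiff1d(np.unique(ep.edge_type_ids), self.edge_types.ids)
            if unknown.size:
                raise IntegrityError(
                    f"edge population {ep.name!r} references undefined edge_type_id {unknown.tolist()}"
                )

    def equals(self, other: "NetworkModel") -> bool:
        """Field-by-field equality (metadata excluded)."""
        if set(self.node_populations) != set(other.node_populations):
            return False
        if set(self.edge_populations) != set(other.edge_populations):
            return False
        if not self.node_types.equals(other.node_types):
            return False
        if not self.edge_types.equals(other.edge_types):
            return False
        for k in self.node_populations:
            if not self.node_populations[k].equals(other.node_populations[k]):
                return False
        for k in self.edge_populations:
            if not self.edge_populations[k].equals(other.edge_populations[k]):
                return False
        return True


SORT_ORDERS = ("by_time", "by_id", "none")


class SpikeSet:
    """Spike events as parallel (population, node_id, time-ms) columns.

    The universal activity currency between modules: Poisson sources, filter
    outputs, and simulator spike output are all SpikeSets.
    """

    def __init__(self, populations=None, node_ids=None, times=None, sort_order: str = "none"):
        self.populations = np.asarray(populations if populations is not None else [], dtype=object)
        self.node_ids = np.asarray(node_ids if node_ids is not None else [], dtype=np.int64)
        self.times = np.asarray(times if times is not None else [], dtype=np.float64)
        if not (len(self.populations) == len(self.node_ids) == len(self.times)):
            raise ValueError("populations, node_ids, times must have equal length")
        if self.times.size and self.times.min() < 0:
            raise ValueError("spike times must be non-negative")
        if not np.all(np.isfinite(self.times)):
            raise ValueError("spike times must be finite")
        if sort_order not in SORT_ORDERS:
            raise ValueError(f"sort_order must be one of {SORT_ORDERS}")
        self.sort_order = sort_order
        if sort_order != "none":
            self.check_sorted()

    @classmethod
    def from_arrays(cls, population: str, node_ids, times, sort: str = "none") -> "SpikeSet":
        node_ids = np.asarray(node_ids, dtype=np.int64)
        pops = np.full(len(node_ids), population, dtype=object)
        s = cls(pops, node_ids, times)
        return s.sorted(sort) if sort != "none" else s

    def __len__(self) -> int:
        return len(self.times)

    def check_sorted(self) -> None:
        """Verify that the declared sort order actually holds."""
        for pop in set(self.populations.tolist()):
            m = self.populations == pop
            if self.sort_order == "by_time" and not _nondecreasing(self.times[m]):
                raise ValueError(f"spikes for population {pop!r} not sorted by time as declared")
            if self.sort_order == "by_id" and not _nondecreasing(self.node_ids[m]):
                raise ValueError(f"spikes for population {pop!r} not sorted by id as declared")

    def sorted(self, order: str = "by_time") -> "SpikeSet":
        if order == "by_time":
            idx = np.lexsort((self.node_ids, self.times))
        elif order == "by_id":
            idx = np.lexsort((self.times, self.node_ids))
        else:
            raise ValueError("order must be by_time or by_id")
        return SpikeSet(self.populations[idx], self.node_ids[idx], self.times[idx], sort_order=order)

    def select(self, population: str) -> tuple[np.ndarray, np.ndarray]:
        """(node_ids, times) of one population."""
        m = self.populations == population
        return self.node_ids[m], self.times[m]

    def population_names(self) -> list[str]:
        return sorted(set(self.populations.tolist()))

    def concat(self, other: "SpikeSet") -> "SpikeSet":
        return SpikeSet(
            np.concatenate([self.populations, other.populations]),
            np.concatenate([self.node_ids, other.node_ids]),
            np.concatenate([self.times, other.times]),
        )

    def equals_as_multiset(self, other: "SpikeSet") -> bool:
        """Order-insensitive event equality."""
        if len(self) != len(other):
            return False
        a = sorted(zip(self.populations, self.node_ids, np.round(self.times, 9)))
        b = sorted(zip(other.populations, other.node_ids, np.round(other.times, 9)))
        return a == b


def _nondecreasing(x: np.ndarray) -> bool:
    return x.size < 2 or bool(np.all(np.diff(x) >= 0))


@dataclass
class ReportSeries:
    """A regularly sampled multichannel time series (voltage, rate, LFP...).

    ``data`` is [time × channel]; sample k is at ``start + k*dt`` ms.
    """

    variable: str
    dt: float
    data: np.ndarray
    start: float = 0.0
    channel_ids: np.ndarray | None = None
    units: str = ""

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float64))
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D [time x channel]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"non-finite values in report {self.variable!r}")
        if self.channel_ids is None:
            self.channel_ids = np.arange(self.data.shape[1])
        self.channel_ids = np.asarray(self.channel_ids)
        if len(self.channel_ids) != self.data.shape[1]:
            raise ValueError("channel_ids length must match channel count")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.start + self.dt * np.arange(self.n_samples)

    def channel(self, cid) -> np.ndarray:
        idx = int(np.nonzero(self.channel_ids == cid)[0][0])
        return self.data[:, idx]
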