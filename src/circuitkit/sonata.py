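"""Readers and writers for the SONATA-subset file dialect.

Networks are stored as HDF5 node/edge tables plus space-delimited text type
tables; spikes and report time series as HDF5.  The dialect restricts the
full convention to a single group (id 0) per population, which covers the
models this package builds while keeping files readable by generic SONATA
tooling.

Layout
------
nodes file:   /nodes/<pop>/{node_id, node_type_id, node_group_id,
                            node_group_index, 0/<attr datasets>}
edges file:   /edges/<pop>/{source_node_id, target_node_id, edge_type_id,
                            edge_group_id, edge_group_index, 0/<attrs>}
              source/target datasets carry a "node_population" attribute
spikes file:  /spikes/<pop>/{timestamps, node_ids}, "sorting" attribute
type tables:  text, one header row, space-delimited, "NULL" for missing
"""

from __future__ import annotations

import os
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .model import (
    EdgePopulation,
    EdgeTypeTable,
    NetworkModel,
    NodePopulation,
    NodeTypeTable,
    ReportSeries,
    SpikeSet,
)

__all__ = [
    "write_network",
    "read_network",
    "write_spikes",
    "read_spikes",
    "SpikeWriter",
    "write_report",
    "read_report",
    "ParseError",
]

_STR = h5py.string_dtype(encoding="utf-8")


class ParseError(ValueError):
    """A malformed or incomplete SONATA-subset file."""


# ---------------------------------------------------------------------------
# type tables (delimited text)
# ---------------------------------------------------------------------------

def _write_type_table(table, path: Path) -> None:
    df = table.frame.reset_index()
    df.to_csv(path, sep=" ", index=False, na_rep="NULL")


def _read_type_table(path: Path, cls):
    try:
        df = pd.read_csv(path, sep=r"\s+", na_values=["NULL"], keep_default_na=False,
                         float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse type table {path}: {exc}") from exc
    if cls.id_column not in df.columns:
        raise ParseError(f"type table {path} lacks column {cls.id_column!r}")
    return cls(df)


# ---------------------------------------------------------------------------
# attribute datasets
# ---------------------------------------------------------------------------

def _write_attr(group: h5py.Group, name: str, values: np.ndarray) -> None:
    values = np.asarray(values)
    if values.dtype.kind in ("U", "O", "S"):
        group.create_dataset(name, data=values.astype(str).astype(object), dtype=_STR)
    else:
        group.create_dataset(name, data=values)


def _read_attr(ds: h5py.Dataset) -> np.ndarray:
    values = ds[()]
    if values.dtype.kind in ("O", "S"):
        return np.asarray([v.decode() if isinstance(v, bytes) else str(v) for v in values],
                          dtype=object)
    return values


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def write_network(model: NetworkModel, directory: str | os.PathLike) -> list[str]:
    """Write a network to ``directory``; returns the list of files written.

    Files: ``nodes.h5``, ``node_types.csv``, ``edges.h5``, ``edge_types.csv``
    (type tables are space-delimited despite the conventional extension).
    Referential integrity is validated before anything is written.
    """
    model.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    nodes_path = directory / "nodes.h5"
    with h5py.File(nodes_path, "w") as f:
        root = f.create_group("nodes")
        for name, pop in model.node_populations.items():
            g = root.create_group(name)
            n = pop.n_nodes
            g.create_dataset("node_id", data=pop.node_ids)
            g.create_dataset("node_type_id", data=pop.node_type_ids)
            g.create_dataset("node_group_id", data=np.zeros(n, dtype=np.int64))
            g.create_dataset("node_group_index", data=np.arange(n, dtype=np.int64))
            attrs = g.create_group("0")
            for col in sorted(pop.attributes):
                _write_attr(attrs, col, pop.attributes[col])

    edges_path = directory / "edges.h5"
    with h5py.File(edges_path, "w") as f:
        root = f.create_group("edges")
        for name, ep in model.edge_populations.items():
            g = root.create_group(name)
            n = ep.n_edges
            src = g.create_dataset("source_node_id", data=ep.source_node_ids)
            src.attrs["node_population"] = ep.source_population
            tgt = g.create_dataset("target_node_id", data=ep.target_node_ids)
            tgt.attrs["node_population"] = ep.target_population
            g.create_dataset("edge_type_id", data=ep.edge_type_ids)
            g.create_dataset("edge_group_id", data=np.zeros(n, dtype=np.int64))
            g.create_dataset("edge_group_index", data=np.arange(n, dtype=np.int64))
            attrs = g.create_group("0")
            for col in sorted(ep.attributes):
                _write_attr(attrs, col, ep.attributes[col])

    nt_path = directory / "node_types.csv"
    et_path = directory / "edge_types.csv"
    _write_type_table(model.node_types, nt_path)
    _write_type_table(model.edge_types, et_path)
    return [str(p) for p in (nodes_path, nt_path, edges_path, et_path)]


def read_network(directory: str | os.PathLike) -> NetworkModel:
    """Lossless inverse of :func:`write_network` (all columns preserved)."""
    directory = Path(directory)
    for fname in ("nodes.h5", "node_types.csv", "edges.h5", "edge_types.csv"):
        if not (directory / fname).exists():
            raise ParseError(f"missing network file {directory / fname}")

    node_types = _read_type_table(directory / "node_types.csv", NodeTypeTable)
    edge_types = _read_type_table(directory / "edge_types.csv", EdgeTypeTable)
    model = NetworkModel(node_types=node_types, edge_types=edge_types)

    with h5py.File(directory / "nodes.h5", "r") as f:
        if "nodes" not in f:
            raise ParseError(f"{directory/'nodes.h5'}: missing /nodes group")
        for name, g in f["nodes"].items():
            for ds in ("node_id", "node_type_id"):
                if ds not in g:
                    raise ParseError(f"{directory/'nodes.h5'}: /nodes/{name}/{ds} missing")
            attrs = {}
            if "0" in g:
                attrs = {col: _read_attr(g["0"][col]) for col in g["0"]}
            pop = NodePopulation(name=name, node_type_ids=g["node_type_id"][()], attributes=attrs)
            node_ids = g["node_id"][()]
            if not np.array_equal(node_ids, np.arange(len(node_ids))):
                raise ParseError(f"/nodes/{name}: node_id not 0-based contiguous")
            model.add_node_population(pop)

    with h5py.File(directory / "edges.h5", "r") as f:
        if "edges" not in f:
            raise ParseError(f"{directory/'edges.h5'}: missing /edges group")
        for name, g in f["edges"].items():
            for ds in ("source_node_id", "target_node_id", "edge_type_id"):
                if ds not in g:
                    raise ParseError(f"{directory/'edges.h5'}: /edges/{name}/{ds} missing")
            attrs = {}
            if "0" in g:
                attrs = {col: _read_attr(g["0"][col]) for col in g["0"]}
            ep = EdgePopulation(
                name=name,
                source_population=g["source_node_id"].attrs["node_population"],
                target_population=g["target_node_id"].attrs["node_population"],
                source_node_ids=g["source_node_id"][()],
                target_node_ids=g["target_node_id"][()],
                edge_type_ids=g["edge_type_id"][()],
                attributes=attrs,
            )
            model.add_edge_population(ep)

    model.validate()
    return model


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

def write_spikes(spikes: SpikeSet, path: str | os.PathLike, sort: str = "by_time") -> None:
    """Write a spike file; events are re-sorted to ``sort`` before writing."""
    out = spikes.sorted(sort) if sort != "none" else spikes
    with h5py.File(path, "w") as f:
        root = f.create_group("spikes")
        root.attrs["sorting"] = sort
        for pop in out.population_names():
            ids, times = out.select(pop)
            g = root.create_group(pop)
            g.create_dataset("timestamps", data=times)
            g.create_dataset("node_ids", data=ids)


def read_spikes(path: str | os.PathLike) -> SpikeSet:
    """Read a spike file; the declared sort order is verified on read."""
    if not Path(path).exists():
        raise ParseError(f"spike file not found: {path}")
    pops, ids, times = [], [], []
    with h5py.File(path, "r") as f:
        if "spikes" not in f:
            raise ParseError(f"{path}: missing /spikes group")
        sorting = f["spikes"].attrs.get("sorting", "none")
        for pop, g in f["spikes"].items():
            if "timestamps" not in g or "node_ids" not in g:
                raise ParseError(f"{path}: /spikes/{pop} missing timestamps or node_ids")
            t = g["timestamps"][()]
            i = g["node_ids"][()]
            pops.append(np.full(len(t), pop, dtype=object))
            ids.append(i)
            times.append(t)
    if pops:
        spikes = SpikeSet(np.concatenate(pops), np.concatenate(ids), np.concatenate(times),
                          sort_order=str(sorting))
    else:
        spikes = SpikeSet(sort_order=str(sorting))
    return spikes


class SpikeWriter:
    """Append-safe spike sink used by the simulators for checkpointed output.

    Events are buffered in memory and flushed to resizable HDF5 datasets at
    every checkpoint; ``close()`` rewrites the file in the requested final
    sort order, so a checkpointed run ends with the same payload datasets as
    an uninterrupted one.
    """

    def __init__(self, path: str | os.PathLike, population: str, sort: str = "by_time"):
        self.path = Path(path)
        self.population = population
        self.sort = sort
        self._ids: list[np.ndarray] = []
        self._times: list[np.ndarray] = []
        self._file = h5py.File(self.path, "w")
        root = self._file.create_group("spikes")
        root.attrs["sorting"] = "none"  # partial files are unsorted
        g = root.create_group(population)
        self._d_t = g.create_dataset("timestamps", shape=(0,), maxshape=(None,), dtype="f8",
                                     chunks=(16384,))
        self._d_i = g.create_dataset("node_ids", shape=(0,), maxshape=(None,), dtype="i8",
                                     chunks=(16384,))
        self._written = 0

    def append(self, node_ids: np.ndarray, times: np.ndarray) -> None:
        if len(node_ids):
            self._ids.append(np.asarray(node_ids, dtype=np.int64))
            self._times.append(np.asarray(times, dtype=np.float64))

    def checkpoint(self) -> None:
        """Flush buffered events to disk (crash-safe partial output)."""
        if not self._ids:
            self._file.flush()
            return
        ids = np.concatenate(self._ids)
        times = np.concatenate(self._times)
        self._ids, self._times = [], []
        n0, n1 = self._written, self._written + len(ids)
        self._d_t.resize((n1,))
        self._d_i.resize((n1,))
        self._d_t[n0:n1] = times
        self._d_i[n0:n1] = ids
        self._written = n1
        self._file.flush()

    def close(self) -> SpikeSet:
        """Finalize: sort the complete event list and rewrite the file."""
        self.checkpoint()
        all_t = self._d_t[()]
        all_i = self._d_i[()]
        self._file.close()
        spikes = SpikeSet.from_arrays(self.population, all_i, all_t)
        write_spikes(spikes, self.path, sort=self.sort)
        return spikes.sorted(self.sort)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_report(report: ReportSeries, path: str | os.PathLike) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("report")
        g.create_dataset("data", data=report.data)
        g.create_dataset("channel_ids", data=np.asarray(report.channel_ids))
        g.attrs["dt"] = report.dt
        g.attrs["start"] = report.start
        g.attrs["variable"] = report.variable
        g.attrs["units"] = report.units


def read_report(path: str | os.PathLike) -> ReportSeries:
    with h5py.File(path, "r") as f:
        if "report" not in f:
            raise ParseError(f"{path}: missing /report group")
        g = f["report"]
        return ReportSeries(
            variable=str(g.attrs["variable"]),
            dt=float(g.attrs["dt"]),
            start=float(g.attrs["start"]),
            data=g["data"][()],
            channel_ids=g["channel_ids"][()],
            units=str(g.attrs.get("units", "")),
        )
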