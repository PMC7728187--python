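"""Simulation configuration: JSON loading, manifest substitution, validation.

Configs follow the SONATA convention: a ``run`` block (tstop, dt, seed,
optional checkpoint_interval, all in ms except the seed), a ``manifest`` of
path variables, ``networks`` with nodes/edges file lists, ``inputs``,
``reports`` and ``output`` blocks.  Validation is tolerant-reader /
strict-writer: unknown top-level keys warn and are kept, structural errors
fail fast.
"""

from __future__ import annotations

import json
import logging
import math
import os
import re
from dataclasses import dataclass, field
from pathlib import Path

log = logging.getLogger(__name__)

__all__ = ["SimulationConfig", "ConfigError", "load_config"]

_KNOWN_TOP = {"run", "manifest", "networks", "inputs", "reports", "output", "target_simulator"}
_VAR = re.compile(r"\$\{([^}]+)\}")


class ConfigError(ValueError):
    """An invalid or unresolvable simulation configuration."""


@dataclass
class SimulationConfig:
    """A resolved simulation configuration.

    ``tstop`` and ``dt`` are in ms; ``n_steps`` is ``floor(tstop/dt)`` and
    ``tstop`` must be a multiple of ``dt`` to within 1e-9 relative tolerance.
    """

    tstop: float
    dt: float
    seed: int = 0
    checkpoint_interval: float | None = None
    networks: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    reports: dict = field(default_factory=dict)
    output: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)
    base_dir: Path = field(default_factory=Path)

    def __post_init__(self):
        if self.tstop <= 0:
            raise ConfigError("run.tstop must be positive")
        if self.dt <= 0:
            raise ConfigError("run.dt must be positive")
        steps = self.tstop / self.dt
        if abs(steps - round(steps)) > 1e-9 * max(1.0, steps):
            raise ConfigError(
                f"run.tstop={self.tstop} is not a multiple of run.dt={self.dt}"
            )
        if self.checkpoint_interval is not None and self.checkpoint_interval <= 0:
            raise ConfigError("run.checkpoint_interval must be positive")

    @property
    def n_steps(self) -> int:
        return int(math.floor(self.tstop / self.dt + 0.5))

    @classmethod
    def from_dict(cls, raw: dict, base_dir: str | os.PathLike = ".") -> "SimulationConfig":
        raw = substitute_manifest(raw)
        unknown = set(raw) - _KNOWN_TOP - {"manifest"}
        for key in sorted(unknown):
            log.warning("unknown top-level config key %r kept as extra", key)
        if "run" not in raw:
            raise ConfigError("config missing required 'run' block")
        run = raw["run"]
        if "tstop" not in run or "dt" not in run:
            raise ConfigError("run block requires 'tstop' and 'dt'")
        if "seed" not in run:
            log.info("run.seed missing; defaulting to 0")
        return cls(
            tstop=float(run["tstop"]),
            dt=float(run["dt"]),
            seed=int(run.get("seed", 0)),
            checkpoint_interval=(
                float(run["checkpoint_interval"]) if run.get("checkpoint_interval") is not None
                else None
            ),
            networks=raw.get("networks", {}),
            inputs=raw.get("inputs", {}),
            reports=raw.get("reports", {}),
            output=raw.get("output", {}),
            extras={k: raw[k] for k in unknown},
            base_dir=Path(base_dir),
        )

    def resolve_path(self, p: str | os.PathLike) -> Path:
        p = Path(p)
        return p if p.is_absolute() else self.base_dir / p


def substitute_manifest(raw: dict) -> dict:
    """Expand ``${var}`` tokens everywhere using the ``manifest`` block.

    Substitution is applied recursively (manifest entries may reference each
    other); cyclic references raise :class:`ConfigError`, as do tokens left
    unresolved after expansion.
    """
    manifest = dict(raw.get("manifest", {}))

    resolved: dict[str, str] = {}

    def resolve_var(name: str, stack: tuple[str, ...]) -> str:
        if name in resolved:
            return resolved[name]
        if name in stack:
            raise ConfigError(f"cyclic manifest reference: {' -> '.join(stack + (name,))}")
        if name not in manifest:
            raise ConfigError(f"unresolved manifest variable ${{{name}}}")
        value = _VAR.sub(lambda m: resolve_var(m.group(1), stack + (name,)), str(manifest[name]))
        resolved[name] = value
        return value

    def walk(obj):
        if isinstance(obj, str):
            out = _VAR.sub(lambda m: resolve_var(m.group(1), ()), obj)
            if _VAR.search(out):
                raise ConfigError(f"unresolved token remains in {out!r}")
            return out
        if isinstance(obj, dict):
            return {k: walk(v) for k, v in obj.items()}
        if isinstance(obj, list):
            return [walk(v) for v in obj]
        return obj

    out = {k: walk(v) for k, v in raw.items() if k != "manifest"}
    return out


def load_config(path: str | os.PathLike) -> SimulationConfig:
    """Load and validate a JSON simulation config from disk."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"invalid JSON in {path}: {exc}") from exc
    return SimulationConfig.from_dict(raw, base_dir=path.parent)
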