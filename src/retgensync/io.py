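"""File formats and configuration loading.

Activity traces are CSV with a ``#``-prefixed metadata header; the
exact integer active-node counts are stored alongside the percentage
columns so that exact-equality period detection survives serialization.
Sweep configurations are YAML files mirroring :class:`SweepConfig`
one-to-one; unknown keys are rejected.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .dynamics import ActivityTrace, DynamicsParams
from .experiments import SweepConfig
from .topology import TopologySpec

__all__ = [
    "ConfigError",
    "TraceFormatError",
    "write_trace",
    "read_trace",
    "load_sweep_config",
    "load_simulation_config",
    "RunManifest",
    "write_manifest",
]


class ConfigError(ValueError):
    """A configuration file failed validation."""


class TraceFormatError(ValueError):
    """A trace file is malformed; the message names the offending cell."""


_TRACE_COLUMNS = ("t", "c1", "c2", "c3", "c4", "x1", "x2", "x3", "x4")


def write_trace(
    trace: ActivityTrace,
    path: str | Path,
    metadata: Mapping[str, Any] | None = None,
) -> None:
    """Write a trace as CSV: ``# key=value`` header lines, then columns
    t, c1..c4 (exact active counts), x1..x4 (percentages)."""
    lines = [f"# comp_size={trace.comp_size}", f"# horizon={trace.horizon}"]
    for key, value in (metadata or {}).items():
        lines.append(f"# {key}={value}")
    lines.append(",".join(_TRACE_COLUMNS))
    x = trace.x
    for t in range(len(trace.counts)):
        counts = ",".join(str(int(c)) for c in trace.counts[t])
        pcts = ",".join(repr(float(v)) for v in x[t])
        lines.append(f"{t},{counts},{pcts}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_trace(path: str | Path) -> tuple[ActivityTrace, dict[str, str]]:
    """Read a trace written by :func:`write_trace`.

    Returns the trace and the metadata header.  Raises
    :class:`TraceFormatError` naming line and column on malformed cells.
    """
    metadata: dict[str, str] = {}
    rows: list[list[int]] = []
    header_seen = False
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                metadata[key.strip()] = value.strip()
            continue
        if not header_seen:
            if tuple(line.split(",")) != _TRACE_COLUMNS:
                raise TraceFormatError(
                    f"{path}:{lineno}: expected column header "
                    f"{','.join(_TRACE_COLUMNS)!r}, got {line!r}"
                )
            header_seen = True
            continue
        cells = line.split(",")
        if len(cells) != len(_TRACE_COLUMNS):
            raise TraceFormatError(
                f"{path}:{lineno}: expected {len(_TRACE_COLUMNS)} cells, "
                f"got {len(cells)}"
            )
        parsed = []
        for col, cell in zip(_TRACE_COLUMNS[:5], cells[:5]):
            try:
                parsed.append(int(cell))
            except ValueError as exc:
                raise TraceFormatError(
                    f"{path}:{lineno}: column {col!r}: non-integer cell {cell!r}"
                ) from exc
        for col, cell in zip(_TRACE_COLUMNS[5:], cells[5:]):
            try:
                float(cell)
            except ValueError as exc:
                raise TraceFormatError(
                    f"{path}:{lineno}: column {col!r}: non-numeric cell {cell!r}"
                ) from exc
        rows.append(parsed[1:])
    if "comp_size" not in metadata:
        raise TraceFormatError(f"{path}: missing comp_size metadata line")
    counts = np.array(rows, dtype=np.int64).reshape(len(rows), 4)
    return ActivityTrace(counts=counts, comp_size=int(metadata["comp_size"])), metadata


def _coerce_fields(cls, raw: Mapping[str, Any], context: str):
    """Build a dataclass from a mapping, rejecting unknown keys and
    reporting field-level constraint violations."""
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{context}: expected a mapping, got {type(raw).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(raw) - set(fields)
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for key, value in raw.items():
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{context}: {exc}") from exc


def load_sweep_config(path: str | Path) -> SweepConfig:
    """Load and validate a sweep configuration YAML file."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: YAML parse failure: {exc}") from exc
    return _coerce_fields(SweepConfig, raw or {}, str(path))


def load_simulation_config(
    path: str | Path,
) -> tuple[TopologySpec, DynamicsParams, int]:
    """Load a single-run configuration: a YAML mapping with a
    ``topology`` block (TopologySpec fields), a ``dynamics`` block
    (DynamicsParams fields) and a ``seed``."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: YAML parse failure: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{path}: expected a mapping at top level")
    unknown = set(raw) - {"topology", "dynamics", "seed"}
    if unknown:
        raise ConfigError(f"{path}: unknown top-level keys {sorted(unknown)}")
    spec = _coerce_fields(TopologySpec, raw.get("topology", {}), f"{path}:topology")
    params = _coerce_fields(DynamicsParams, raw.get("dynamics", {}), f"{path}:dynamics")
    if params.k > spec.N:
        raise ConfigError(f"{path}:dynamics: k={params.k} exceeds N={spec.N}")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError(f"{path}: seed must be an integer")
    return spec, params, seed


@dataclass(frozen=True)
class RunManifest:
    """Reproducibility record of a run: full parameter set, master seed,
    artifact version, timestamps, and output files with checksums."""

    config: dict[str, Any]
    seed: int
    version: str
    created_utc: str
    outputs: dict[str, str]  # filename -> sha256

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(
    path: str | Path,
    config: Any,
    seed: int,
    output_files: list[str | Path],
) -> RunManifest:
    """Write a JSON manifest listing every output file with its checksum."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config_dict = dataclasses.asdict(config)
    else:
        config_dict = dict(config)
    manifest = RunManifest(
        config=config_dict,
        seed=seed,
        version=__version__,
        created_utc=_dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
        outputs={str(Path(f).name): _sha256(Path(f)) for f in output_files},
    )
    Path(path).write_text(manifest.to_json() + "\n")
    return manifest
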