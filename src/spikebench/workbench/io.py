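"""Plain-text file formats: spike TSV, voltage TSV, synapse TSV, config
and report JSON.

TSV files carry one ``#``-prefixed header line and 15-significant-digit
values; reading back reproduces the written records exactly. Malformed
lines raise :class:`~spikebench.errors.ParseError` with a line number.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from spikebench.errors import ParseError
from spikebench.network_model import NetworkInstance, NetworkSpec

__all__ = [
    "write_spikes_tsv", "read_spikes_tsv",
    "write_voltage_tsv", "read_voltage_tsv",
    "write_synapses_tsv",
    "write_config_json", "read_config_json",
    "write_report_json", "read_report_json",
    "load_schema", "validate_against_schema",
]

_FMT = "%.15g"


def write_spikes_tsv(path, neuron_ids, times) -> None:
    """Write spikes as ``neuron_id<TAB>time_ms`` under a ``#`` header."""
    path = Path(path)
    with path.open("w") as f:
        f.write("# neuron_id\ttime_ms\n")
        for i, t in zip(neuron_ids, times):
            f.write(f"{int(i)}\t{_FMT % t}\n")


def read_spikes_tsv(path) -> tuple[np.ndarray, np.ndarray]:
    ids, times = [], []
    with Path(path).open() as f:
        for ln, line in enumerate(f, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"expected 2 tab-separated columns, got {len(parts)}", ln)
            try:
                ids.append(int(parts[0]))
                times.append(float(parts[1]))
            except ValueError as e:
                raise ParseError(str(e), ln) from e
    return np.asarray(ids, dtype=np.int64), np.asarray(times, dtype=float)


def write_voltage_tsv(path, times, values) -> None:
    """Write a voltage trace as ``time_ms<TAB>value_mV``."""
    path = Path(path)
    with path.open("w") as f:
        f.write("# time_ms\tvalue_mV\n")
        for t, v in zip(times, values):
            f.write(f"{_FMT % t}\t{_FMT % v}\n")


def read_voltage_tsv(path) -> tuple[np.ndarray, np.ndarray]:
    times, values = [], []
    with Path(path).open() as f:
        for ln, line in enumerate(f, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(
                    f"expected 2 tab-separated columns, got {len(parts)}", ln)
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError as e:
                raise ParseError(str(e), ln) from e
    return np.asarray(times, dtype=float), np.asarray(values, dtype=float)


def write_synapses_tsv(path, instance: NetworkInstance) -> None:
    """Export instantiated synapses as
    ``source<TAB>target<TAB>weight_nA<TAB>delay_ms``."""
    with Path(path).open("w") as f:
        f.write("# source\ttarget\tweight_nA\tdelay_ms\n")
        for e in instance.iter_synapses():
            f.write(f"{e.source}\t{e.target}\t{_FMT % e.weight}\t"
                    f"{_FMT % e.delay}\n")


def write_config_json(path, spec: NetworkSpec, extra: dict | None = None) -> None:
    d = spec.to_dict()
    if extra:
        d.update(extra)
    with Path(path).open("w") as f:
        json.dump(d, f, indent=2)
        f.write("\n")


def read_config_json(path) -> NetworkSpec:
    with Path(path).open() as f:
        return NetworkSpec.from_dict(json.load(f))


def write_report_json(path, report: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as f:
        json.dump(report, f, indent=2, default=_json_default)
        f.write("\n")


def read_report_json(path) -> dict:
    with Path(path).open() as f:
        return json.load(f)


def load_schema(name: str) -> dict:
    """Load one of the JSON schemas shipped with the package
    (``"report"`` or ``"config"``)."""
    path = Path(__file__).parent / "schemas" / f"{name}.schema.json"
    with path.open() as f:
        return json.load(f)


_TYPES = {"object": dict, "array": list, "string": str, "integer": int,
          "number": (int, float)}


def validate_against_schema(doc, schema: dict, where: str = "$") -> None:
    """Validate ``doc`` against the subset of JSON Schema the shipped
    schemas use (type, required, properties, items); raises
    :class:`ParseError` on the first violation."""
    typ = schema.get("type")
    if typ and not isinstance(doc, _TYPES[typ]):
        raise ParseError(f"{where}: expected {typ}, got {type(doc).__name__}")
    if typ == "object":
        for key in schema.get("required", ()):
            if key not in doc:
                raise ParseError(f"{where}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in doc:
                validate_against_schema(doc[key], sub, f"{where}.{key}")
    elif typ == "array" and "items" in schema:
        for i, item in enumerate(doc):
            validate_against_schema(item, schema["items"], f"{where}[{i}]")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)!r}")
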