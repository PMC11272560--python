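"""Readers, writers, and run reports.

Signals are exchanged as plain delimited text (comma or whitespace), one
row per time sample, one column per channel, with an optional single
header line that is auto-detected.  TP tables and JSON reports round-trip
at full float precision, and every report embeds the configuration and
master seed that produced it so a run can be reproduced from the report
alone.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .embedding import SignalMatrix
from .persistence import TPCurveSet

__all__ = [
    "RunConfig",
    "read_signal",
    "write_tp",
    "read_tp",
    "write_report",
    "validate_report",
    "REPORT_SCHEMA_PATH",
]

REPORT_SCHEMA_PATH = Path(__file__).with_name("report_schema.json")


@dataclass
class RunConfig:
    """Everything needed to reproduce a test run."""

    input_path: str | None = None
    scenario: str | None = None
    noise_sd: float = 0.1
    window: int = 50
    stride: int | None = None
    max_homology_dim: int = 2
    eps_max: str | float = "auto"
    kmax: int = 10
    n_permutations: int = 999
    alternative: str = "lower"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _parse_line(line: str, lineno: int):
    parts = line.replace(",", " ").split()
    try:
        return [float(v) for v in parts]
    except ValueError as exc:
        raise ValueError(f"non-numeric value on line {lineno}: {line.strip()!r}") from exc


def read_signal(path: str | Path, sampling_rate: float = 1.0) -> SignalMatrix:
    """Read a delimited numeric matrix (rows = samples, columns = channels).

    A single non-numeric first line is treated as a header and skipped.
    Ragged rows and non-numeric cells raise ``ValueError`` naming the
    offending line.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"empty signal file: {path}")
    start = 0
    try:
        _parse_line(lines[0], 1)
    except ValueError:
        start = 1  # header
        if len(lines) == 1:
            raise ValueError(f"signal file {path} has a header but no data")
    rows = []
    width = None
    for i, ln in enumerate(lines[start:], start=start + 1):
        row = _parse_line(ln, i)
        if width is None:
            width = len(row)
        elif len(row) != width:
            raise ValueError(
                f"ragged row on line {i}: expected {width} columns, got {len(row)}"
            )
        rows.append(row)
    return SignalMatrix(np.array(rows, dtype=float), sampling_rate=sampling_rate)


def write_signal(signal: SignalMatrix, path: str | Path) -> None:
    """Write a signal as comma-separated text at full float precision."""
    np.savetxt(path, signal.values, delimiter=",", fmt="%.17g")


def write_tp(curves: TPCurveSet, path: str | Path) -> None:
    """Write a TP curve set as a CSV table, round-trippable bit-for-bit.

    Columns: window_index, end_time, tp0[, tp1[, tp2]].
    """
    if curves.times.size == 0:
        raise ValueError("refusing to write an empty TP curve set")
    data = {"window_index": np.arange(curves.times.size), "end_time": curves.times}
    for k in sorted(curves.tp):
        data[f"tp{k}"] = curves.tp[k]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_tp(path: str | Path) -> TPCurveSet:
    """Read a TP table written by :func:`write_tp`."""
    df = pd.read_csv(path, float_precision="round_trip")
    tp = {
        int(c[2:]): df[c].to_numpy()
        for c in df.columns
        if c.startswith("tp") and c[2:].isdigit()
    }
    if not tp:
        raise ValueError(f"no tp columns found in {path}")
    return TPCurveSet(times=df["end_time"].to_numpy(), tp=tp)


def write_report(results: dict, config: RunConfig, path: str | Path) -> dict:
    """Write the JSON test report; returns the report dict.

    ``results`` maps homology dimension k to a
    :class:`~tdabreak.breaktest.BreakTestResult`.
    """
    from . import __version__

    if not results:
        raise ValueError("refusing to write an empty report")
    report = {
        "package": "tdabreak",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": config.to_dict(),
        "results": {
            str(k): {
                "observed_hfd": r.observed_hfd,
                "p_value": r.p_value,
                "n_permutations": r.n_permutations,
                "mean_permuted_hfd": r.mean_permuted_hfd,
                "alternative": r.alternative,
            }
            for k, r in results.items()
        },
    }
    validate_report(report)
    Path(path).write_text(json.dumps(report, indent=2) + "\n")
    return report


def validate_report(report: dict) -> None:
    """Structural validation against the shipped report schema.

    Checks required keys and value types; raises ``ValueError`` on the
    first violation.
    """
    schema = json.loads(REPORT_SCHEMA_PATH.read_text())
    _check_object(report, schema, "report")


_TYPES = {
    "object": dict,
    "string": str,
    "number": (int, float),
    "integer": int,
}


def _check_object(obj, schema, where: str) -> None:
    if not isinstance(obj, dict):
        raise ValueError(f"{where}: expected an object")
    for key in schema.get("required", []):
        if key not in obj:
            raise ValueError(f"{where}: missing required key {key!r}")
    for key, sub in schema.get("properties", {}).items():
        if key not in obj:
            continue
        expected = _TYPES.get(sub.get("type"))
        if expected is not None and not isinstance(obj[key], expected):
            raise ValueError(f"{where}.{key}: expected {sub['type']}")
        if sub.get("type") == "object" and (
            "properties" in sub or "required" in sub
        ):
            _check_object(obj[key], sub, f"{where}.{key}")
        if "patternProperties" in sub:
            for pat_schema in sub["patternProperties"].values():
                for k, v in obj[key].items():
                    _check_object(v, pat_schema, f"{where}.{key}.{k}")
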