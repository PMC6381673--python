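"""Readers and writers for traces, parameter sets and fit artifacts.

Traces travel as plain CSV with the header ``time_s,amplitude`` and
optional ``#``-prefixed metadata comment lines; parameter sets and fit
results as flat JSON.  Writers emit full float precision (shortest
round-trip repr), so write/read round-trips are exact and byte output
is deterministic.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Union

import numpy as np

from .exceptions import TraceFormatError
from .model import KineticParameters, PoolTotals
from .trace import ERGTrace

__all__ = [
    "read_trace",
    "write_trace",
    "read_parameters",
    "write_parameters",
    "write_states",
]

_HEADER = ("time_s", "amplitude")


def read_trace(path: Union[str, Path]) -> ERGTrace:
    """Read a trace CSV, validating format and time monotonicity.

    Errors name the offending physical (1-based) line of the file.
    """
    path = Path(path)
    times: list[float] = []
    amps: list[float] = []
    meta_lines: list[str] = []
    header_seen = False
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            if not row:
                continue
            if row[0].lstrip().startswith("#"):
                meta_lines.append(",".join(row).lstrip("# ").strip())
                continue
            if not header_seen:
                if tuple(c.strip() for c in row[:2]) != _HEADER:
                    raise TraceFormatError(
                        f"{path}: line {lineno}: expected header "
                        f"'time_s,amplitude', got {','.join(row)!r}"
                    )
                header_seen = True
                continue
            if len(row) < 2:
                raise TraceFormatError(f"{path}: line {lineno}: expected 2 columns")
            try:
                t, a = float(row[0]), float(row[1])
            except ValueError:
                raise TraceFormatError(
                    f"{path}: line {lineno}: non-numeric cell in {row[:2]!r}"
                ) from None
            if times and t <= times[-1]:
                raise TraceFormatError(
                    f"{path}: line {lineno}: non-monotone time {t!r} after {times[-1]!r}"
                )
            times.append(t)
            amps.append(a)
    if not header_seen:
        raise TraceFormatError(f"{path}: missing 'time_s,amplitude' header")
    if not times:
        raise TraceFormatError(f"{path}: no data rows")
    return ERGTrace(np.array(times), np.array(amps), meta="; ".join(meta_lines))


def write_trace(trace: ERGTrace, path: Union[str, Path]) -> None:
    """Write a trace as CSV (header ``time_s,amplitude``, full precision)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        if trace.meta:
            for line in trace.meta.split("; "):
                fh.write(f"# {line}\n")
        fh.write("time_s,amplitude\n")
        for t, a in zip(trace.times, trace.amplitudes):
            fh.write(f"{float(t)!r},{float(a)!r}\n")


def write_states(times: np.ndarray, states: np.ndarray, path: Union[str, Path]) -> None:
    """Write a state trajectory as CSV with columns time_s,x1..x8."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write("time_s," + ",".join(f"x{i}" for i in range(1, 9)) + "\n")
        for t, row in zip(times, states):
            fh.write(f"{float(t)!r}," + ",".join(repr(float(v)) for v in row) + "\n")


def read_parameters(path: Union[str, Path]) -> tuple[KineticParameters, PoolTotals]:
    """Read a flat JSON parameter file (keys k1u..k17, n_cG, R0..Ca0)."""
    with Path(path).open() as fh:
        d = json.load(fh)
    return KineticParameters.from_dict(d), PoolTotals.from_dict(d)


def write_parameters(params: KineticParameters, pools: PoolTotals,
                     path: Union[str, Path]) -> None:
    """Write rates and pool totals as one flat JSON object."""
    d = {**params.as_dict(), **pools.as_dict()}
    with Path(path).open("w") as fh:
        json.dump(d, fh, indent=2, sort_keys=True)
        fh.write("\n")
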