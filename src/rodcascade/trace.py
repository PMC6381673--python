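"""The ERG trace container and basic trace arithmetic."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ConfigError

__all__ = ["ERGTrace", "average_traces"]


@dataclass
class ERGTrace:
    """A sampled ERG recording: (time, amplitude) pairs.

    Times are in seconds, strictly increasing, starting at or after 0.
    Amplitudes are in whatever signal units the recording carries
    (model units for synthetic traces).  ``meta`` is a free-text label,
    typically the experimental group.
    """

    times: np.ndarray
    amplitudes: np.ndarray
    meta: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.amplitudes.shape:
            raise ConfigError("times and amplitudes must be 1-D arrays of equal length")
        if self.times.size == 0:
            raise ConfigError("trace must contain at least one sample")
        if self.times[0] < 0:
            raise ConfigError("first timestamp must be >= 0")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ConfigError("times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def trough_amplitude(self) -> float:
        """Magnitude of the largest deflection from zero."""
        return float(np.max(np.abs(self.amplitudes)))


def average_traces(traces: Sequence[ERGTrace], times: np.ndarray | None = None) -> ERGTrace:
    """Pointwise mean of several traces on a common grid.

    Traces are resampled by linear interpolation onto ``times`` (default:
    the first trace's grid) before averaging — the standard way a group
    mean is formed from per-animal recordings before fitting.
    """
    if not traces:
        raise ConfigError("need at least one trace to average")
    grid = np.asarray(times, dtype=float) if times is not None else traces[0].times
    stack = np.vstack([np.interp(grid, tr.times, tr.amplitudes) for tr in traces])
    meta = "mean(" + ",".join(tr.meta or "?" for tr in traces) + ")"
    return ERGTrace(grid.copy(), stack.mean(axis=0), meta=meta)
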