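"""Synthetic ERG-like traces with the residual structure of real recordings.

Real rod-driven ERGs differ from the pure photoreceptor model in two
ways that matter for estimation: broadband high-frequency instrument
noise, and — outside b-wave-suppressed preparations — a delayed
positive bipolar-cell component (the b-wave) that pulls the trace up
after the a-wave trough.  This module generates traces from the model
itself and layers both contaminants on top, with the ground truth
recorded alongside, so parameter-recovery experiments can quantify each
pipeline stage without access to animal recordings.

The b-wave stand-in is a phenomenological alpha function
``A * (t'/tau) * exp(1 - t'/tau)`` starting ``onset_delay`` after
stimulus onset, with polarity opposite to the a-wave.  It emulates only
the qualitative shape of the contaminant, not bipolar-cell physiology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import ConfigError
from .integrate import SimulationGrid, simulate
from .model import (
    FIXTURE_NAMES,
    KineticParameters,
    PoolTotals,
    Stimulus,
    fixture_parameters,
)
from .trace import ERGTrace

__all__ = [
    "NoiseSpec",
    "ContaminantSpec",
    "GroundTruth",
    "default_contaminant",
    "generate_trace",
    "make_group_panel",
]

#: b-wave weight per group: heavier for wild type, lighter where bipolar
#: cells are suppressed (NOB1 lines).
_BWAVE_FRACTION = {"wild": 0.30, "NOB": 0.15, "NOB_drug": 0.15}


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian noise, SD = sigma_fraction * trough amplitude."""

    sigma_fraction: float = 0.02
    seed: Optional[int] = None

    def __post_init__(self):
        if self.sigma_fraction < 0:
            raise ConfigError("sigma_fraction must be >= 0")


@dataclass(frozen=True)
class ContaminantSpec:
    """Delayed positive b-wave-like alpha-function component."""

    enabled: bool = True
    amplitude_fraction: float = 0.15
    onset_delay: float = 0.05
    rise_time: float = 0.06

    def __post_init__(self):
        if self.amplitude_fraction < 0:
            raise ConfigError("amplitude_fraction must be >= 0")
        if self.rise_time <= 0:
            raise ConfigError("rise_time must be > 0")


@dataclass
class GroundTruth:
    """Everything needed to reproduce and score a synthetic trace."""

    group: str
    params: KineticParameters
    pools: PoolTotals
    stimulus: Stimulus
    grid: SimulationGrid
    sign: float
    model_signal: np.ndarray
    contaminant_signal: np.ndarray
    noise_sigma: float
    seed: Optional[int]

    def as_dict(self) -> dict:
        return {
            "group": self.group,
            "params": self.params.as_dict(),
            "pools": self.pools.as_dict(),
            "stimulus": {"t_on": self.stimulus.t_on, "t_off": self.stimulus.t_off},
            "grid": {
                "t_start": self.grid.t_start, "t_end": self.grid.t_end,
                "dt_output": self.grid.dt_output, "dt_internal": self.grid.dt_internal,
            },
            "sign": self.sign,
            "noise_sigma": float(self.noise_sigma),
            "seed": self.seed,
        }


def default_contaminant(group: str, enabled: bool = True) -> ContaminantSpec:
    """Group-specific default b-wave weight (heavier for wild type)."""
    return ContaminantSpec(enabled=enabled,
                           amplitude_fraction=_BWAVE_FRACTION.get(group, 0.15))


def generate_trace(
    group: str,
    stimulus: Optional[Stimulus] = None,
    grid: Optional[SimulationGrid] = None,
    noise: Optional[NoiseSpec] = None,
    contaminant: Optional[ContaminantSpec] = None,
    sign: float = -1.0,
) -> tuple[ERGTrace, GroundTruth]:
    """Generate one synthetic ERG trace from a named parameter fixture.

    The model is simulated with the fixture's rates (default: 1 kHz over
    [0, 0.3] s, light on throughout), the polarity applied, then the
    b-wave contaminant (if enabled) and finally Gaussian noise are added.
    Noise and contaminant amplitudes are expressed as fractions of the
    noiseless trough amplitude.

    Returns the trace together with a :class:`GroundTruth` record
    (generating parameters, noiseless model signal, contaminant signal,
    seed) for recovery scoring.
    """
    if group not in FIXTURE_NAMES:
        raise ConfigError(f"unknown group {group!r}; available: {', '.join(FIXTURE_NAMES)}")
    params, pools = fixture_parameters(group)
    stimulus = stimulus if stimulus is not None else Stimulus()
    grid = grid if grid is not None else SimulationGrid()
    noise = noise if noise is not None else NoiseSpec(sigma_fraction=0.0)

    sim = simulate(params, pools, stimulus, grid, sign=sign)
    clean = sim.signal
    trough = float(np.max(np.abs(clean)))
    y = clean.copy()

    cont = np.zeros_like(clean)
    if contaminant is not None and contaminant.enabled:
        tprime = sim.times - (stimulus.t_on + contaminant.onset_delay)
        tau = contaminant.rise_time
        shape = np.where(tprime > 0, (tprime / tau) * np.exp(1.0 - tprime / tau), 0.0)
        # b-wave polarity opposes the a-wave trough
        cont = (-np.sign(sign) if sign != 0 else 1.0) * \
            contaminant.amplitude_fraction * trough * shape
        y = y + cont

    sigma = noise.sigma_fraction * trough
    if sigma > 0:
        rng = np.random.default_rng(noise.seed)
        y = y + rng.normal(0.0, sigma, size=y.shape)

    trace = ERGTrace(sim.times.copy(), y, meta=group)
    truth = GroundTruth(
        group=group, params=params, pools=pools, stimulus=stimulus, grid=grid,
        sign=sign, model_signal=clean, contaminant_signal=cont,
        noise_sigma=sigma, seed=noise.seed,
    )
    return trace, truth


def make_group_panel(
    n_per_group: int = 3,
    groups: Sequence[str] = FIXTURE_NAMES,
    stimulus: Optional[Stimulus] = None,
    grid: Optional[SimulationGrid] = None,
    sigma_fraction: float = 0.02,
    bwave: bool = False,
    base_seed: int = 0,
) -> tuple[list[ERGTrace], list[GroundTruth]]:
    """A panel of n traces per group with independent noise seeds.

    Mirrors the small-cohort design of rod ERG studies (a few animals
    per group, traces later averaged per group before fitting).  Seeds
    are derived deterministically from ``base_seed`` so panels are
    reproducible.
    """
    if n_per_group < 1:
        raise ConfigError("n_per_group must be >= 1")
    traces: list[ERGTrace] = []
    truths: list[GroundTruth] = []
    children = np.random.SeedSequence(base_seed).spawn(len(groups) * n_per_group)
    i = 0
    for group in groups:
        for _ in range(n_per_group):
            seed = int(children[i].generate_state(1)[0] % (2**31))
            i += 1
            trace, truth = generate_trace(
                group,
                stimulus=stimulus,
                grid=grid,
                noise=NoiseSpec(sigma_fraction=sigma_fraction, seed=seed),
                contaminant=default_contaminant(group, enabled=bwave),
            )
            traces.append(trace)
            truths.append(truth)
    return traces, truths
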