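"""Levenberg-Marquardt estimation of cascade rates from an ERG trace.

The photoreceptor model only describes the a-wave, so estimation uses
the initial trace segment — from stimulus onset to a moment slightly
past the trough — either by automatic trough detection or a fixed
horizon (0.28 s by default, the classic a-wave fit window).  Parameters
are optimized in log-space, which enforces positivity of the rate
constants without constrained solvers.  The fit-quality metric is the
L2-norm ratio ``||data - model|| / ||data|| * 100`` (percent): scale
invariant and differentiable.

This module holds the functional surface (window selection, residuals,
finite-difference sensitivities, the error metric); the LM iteration
itself lives in :class:`rodcascade.estimator.PhototransductionFitter`,
for which :func:`lm_fit` is a thin wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .exceptions import ConfigError, MetricUndefinedError, WindowUndefinedError
from .integrate import predict_signal
from .model import KineticParameters, PoolTotals, RATE_NAMES, Stimulus
from .trace import ERGTrace

__all__ = [
    "FitConfig",
    "FitResult",
    "FREE_POOL_NAMES",
    "select_fit_window",
    "residuals",
    "numerical_jacobian",
    "relative_error",
    "get_free_values",
    "set_free_values",
    "lm_fit",
]

#: Pool totals that may be co-optimized.  R0 is the normalization
#: reference and is always held fixed.
FREE_POOL_NAMES = ("G0", "E0", "cG0", "Ca0")


@dataclass
class FitConfig:
    """Configuration of one Levenberg-Marquardt fit.

    ``free`` names the parameters to estimate — any of the 17 rates and
    the pool totals G0, E0, cG0, Ca0.  R0 is never estimable.  The
    damping schedule defaults are the classic Marquardt choices.
    """

    free: Sequence[str] = ("k1u",)
    params: Optional[KineticParameters] = None
    pools: Optional[PoolTotals] = None
    window: str = "trough"          # "trough" or "fixed"
    t_max: float = 0.28
    window_pad: float = 0.15
    sign: float = -1.0
    dt_internal: float = 5e-5
    max_iter: int = 200
    tol: float = 1e-10
    damping_init: float = 1e-3
    damping_factor: float = 10.0
    damping_max: float = 1e12
    jacobian_step: float = 1e-6

    def __post_init__(self):
        validate_free_names(self.free)
        if self.damping_factor <= 1.0:
            raise ConfigError("damping_factor must exceed 1")


@dataclass
class FitResult:
    """Outcome of a Levenberg-Marquardt fit."""

    params: KineticParameters
    pools: PoolTotals
    free: tuple[str, ...]
    estimates: np.ndarray
    residual: np.ndarray
    relative_error_pct: float
    n_iter: int
    converged: bool
    damping_final: float
    cost_history: list[float] = field(default_factory=list)
    window: tuple[int, int] = (0, 0)
    message: str = ""

    def as_dict(self) -> dict:
        """JSON-serializable summary (residual vector excluded)."""
        return {
            "free": list(self.free),
            "estimates": {n: float(v) for n, v in zip(self.free, self.estimates)},
            "params": self.params.as_dict(),
            "pools": self.pools.as_dict(),
            "relative_error_pct": float(self.relative_error_pct),
            "n_iter": int(self.n_iter),
            "converged": bool(self.converged),
            "damping_final": float(self.damping_final),
            "cost_history": [float(c) for c in self.cost_history],
            "window": [int(self.window[0]), int(self.window[1])],
            "message": self.message,
        }


def validate_free_names(names: Sequence[str]) -> tuple[str, ...]:
    names = tuple(names)
    if not names:
        raise ConfigError("at least one free parameter is required")
    allowed = set(RATE_NAMES) | set(FREE_POOL_NAMES)
    for n in names:
        if n == "R0":
            raise ConfigError("R0 is the fixed normalization reference and cannot be fitted")
        if n not in allowed:
            raise ConfigError(f"unknown free parameter {n!r}")
    if len(set(names)) != len(names):
        raise ConfigError("duplicate names in free parameter list")
    return names


def get_free_values(params: KineticParameters, pools: PoolTotals,
                    names: Sequence[str]) -> np.ndarray:
    """Current values of the named free parameters, in order."""
    out = []
    for n in names:
        out.append(getattr(params, n) if n in RATE_NAMES else getattr(pools, n))
    return np.array(out, dtype=float)


def set_free_values(params: KineticParameters, pools: PoolTotals,
                    names: Sequence[str], values: np.ndarray
                    ) -> tuple[KineticParameters, PoolTotals]:
    """Return copies of (params, pools) with the named entries replaced."""
    p_changes = {n: float(v) for n, v in zip(names, values) if n in RATE_NAMES}
    q_changes = {n: float(v) for n, v in zip(names, values) if n in FREE_POOL_NAMES}
    if p_changes:
        params = params.replace(**p_changes)
    if q_changes:
        pools = pools.replace(**q_changes)
    return params, pools


def select_fit_window(trace: ERGTrace, rule: str = "trough",
                      t_max: float = 0.28, pad: float = 0.15) -> tuple[int, int]:
    """Choose the initial-segment fit window as a half-open index range.

    rule="trough": locate the global extremum of the polarity-normalized
    trace (max |amplitude|) and keep samples up to t_trough*(1+pad).
    The extremum must not sit on the last sample, otherwise the trough
    is not bracketed and the window is undefined.

    rule="fixed": keep all samples with t <= t_max (inclusive).
    """
    if rule == "fixed":
        stop = int(np.searchsorted(trace.times, t_max + 1e-12, side="right"))
        if stop == 0:
            raise WindowUndefinedError(f"no samples at or before t_max = {t_max} s")
        return 0, stop
    if rule != "trough":
        raise ConfigError(f"unknown window rule {rule!r}")

    i_ext = int(np.argmax(np.abs(trace.amplitudes)))
    if i_ext == len(trace) - 1:
        raise WindowUndefinedError(
            "trace extremum lies on the final sample; trough not bracketed"
        )
    t_end = trace.times[i_ext] * (1.0 + pad)
    stop = int(np.searchsorted(trace.times, t_end + 1e-12, side="right"))
    return 0, max(stop, i_ext + 1)


def residuals(trace: ERGTrace, params: KineticParameters, pools: PoolTotals,
              stimulus: Optional[Stimulus] = None,
              window: Optional[tuple[int, int]] = None,
              sign: float = -1.0, dt_internal: float = 5e-5) -> np.ndarray:
    """data - model, per sample, at the trace's own timestamps in the window."""
    start, stop = window if window is not None else (0, len(trace))
    t = trace.times[start:stop]
    model = predict_signal(t, params, pools, stimulus, sign=sign, dt_internal=dt_internal)
    return trace.amplitudes[start:stop] - model


def numerical_jacobian(trace: ERGTrace, params: KineticParameters, pools: PoolTotals,
                       free: Sequence[str],
                       window: Optional[tuple[int, int]] = None,
                       step: float = 1e-6,
                       stimulus: Optional[Stimulus] = None,
                       sign: float = -1.0, dt_internal: float = 5e-5,
                       base: Optional[np.ndarray] = None) -> np.ndarray:
    """Forward-difference sensitivities of the model prediction.

    One column per free parameter: d f(t_i) / d p_j, estimated with a
    relative step ``step`` (absolute floor for near-zero values).  Shape
    is (samples in window, number of free parameters).  A perturbed
    simulation that fails raises with the offending column named.
    """
    free = validate_free_names(free)
    start, stop = window if window is not None else (0, len(trace))
    t = trace.times[start:stop]
    if base is None:
        base = predict_signal(t, params, pools, stimulus, sign=sign,
                              dt_internal=dt_internal)
    J = np.empty((t.size, len(free)))
    values = get_free_values(params, pools, free)
    for j, (name, v) in enumerate(zip(free, values)):
        h = step * max(abs(v), 1e-8)
        p_j, q_j = set_free_values(params, pools, [name], [v + h])
        try:
            pert = predict_signal(t, p_j, q_j, stimulus, sign=sign,
                                  dt_internal=dt_internal)
        except Exception as exc:
            raise RuntimeError(
                f"jacobian column for {name!r} failed: perturbed simulation error"
            ) from exc
        J[:, j] = (pert - base) / h
    return J


def relative_error(data: np.ndarray, model: np.ndarray) -> float:
    """Relative fitting error in percent: ||data - model||_2 / ||data||_2 * 100."""
    data = np.asarray(data, dtype=float)
    model = np.asarray(model, dtype=float)
    if data.shape != model.shape:
        raise ConfigError("data and model must have equal shapes")
    denom = float(np.linalg.norm(data))
    if denom == 0.0:
        raise MetricUndefinedError("relative error undefined for zero data norm")
    return float(np.linalg.norm(data - model)) / denom * 100.0


def lm_fit(trace: ERGTrace, config: Optional[FitConfig] = None,
           stimulus: Optional[Stimulus] = None) -> FitResult:
    """Fit the model to a trace by Levenberg-Marquardt.

    Thin functional wrapper over
    :class:`rodcascade.estimator.PhototransductionFitter`; see that
    class for the algorithm.
    """
    from .estimator import PhototransductionFitter

    config = config if config is not None else FitConfig()
    est = PhototransductionFitter(
        free=tuple(config.free),
        params=config.params,
        pools=config.pools,
        stimulus=stimulus,
        sign=config.sign,
        window=config.window,
        t_max=config.t_max,
        window_pad=config.window_pad,
        dt_internal=config.dt_internal,
        max_iter=config.max_iter,
        tol=config.tol,
        damping_init=config.damping_init,
        damping_factor=config.damping_factor,
        damping_max=config.damping_max,
        jacobian_step=config.jacobian_step,
    )
    est.fit(trace.times, trace.amplitudes)
    return est.result_
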