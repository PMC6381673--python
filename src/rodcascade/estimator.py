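"""scikit-learn style estimator wrapping the cascade model fit.

``PhototransductionFitter`` is a regressor in the curve-fitting sense:
``X`` is the sample times of an ERG trace (seconds, shape (n,) or
(n, 1)), ``y`` the recorded amplitudes.  ``fit`` runs Levenberg-
Marquardt on the selected initial segment; ``predict`` simulates the
fitted model at arbitrary times.  Because it follows the scikit-learn
parameter contract it composes with ``clone``, ``GridSearchCV`` and
friends, though in practice the interesting hyper-parameter is the set
of free rate constants.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import ConfigError
from .fitting import (
    FitResult,
    get_free_values,
    relative_error,
    select_fit_window,
    set_free_values,
    validate_free_names,
    numerical_jacobian,
)
from .integrate import predict_signal
from .model import (
    KineticParameters,
    PoolTotals,
    Stimulus,
    fixture_parameters,
)
from .trace import ERGTrace

__all__ = ["PhototransductionFitter"]

# log-parameter clip keeps exp() finite during wild trial steps
_LOG_LIM = 46.0


def _resolve_params(params) -> tuple[KineticParameters, Optional[PoolTotals]]:
    if params is None:
        return fixture_parameters("NOB")[0], None
    if isinstance(params, str):
        return fixture_parameters(params)
    if isinstance(params, KineticParameters):
        return params, None
    if isinstance(params, dict):
        return KineticParameters.from_dict(params), None
    raise ConfigError(f"cannot interpret initial parameters: {params!r}")


def _resolve_pools(pools) -> PoolTotals:
    if pools is None:
        return PoolTotals()
    if isinstance(pools, PoolTotals):
        return pools
    if isinstance(pools, dict):
        return PoolTotals.from_dict(pools)
    raise ConfigError(f"cannot interpret pool totals: {pools!r}")


class PhototransductionFitter(BaseEstimator, RegressorMixin):
    """Estimate cascade rate constants from an ERG trace.

    Parameters
    ----------
    free : sequence of str
        Parameters to estimate: any of k1u..k17 and the pool totals
        G0, E0, cG0, Ca0.  R0 is the fixed normalization reference and
        is rejected.
    params : KineticParameters, dict, fixture name, or None
        Initial guess for the rate constants (default: "NOB" fixture).
    pools : PoolTotals, dict or None
        Initial guess for the pool totals (default ratios).
    stimulus : Stimulus or None
        Light gate; default light on over [0, 0.3) s.
    sign : float
        Trace polarity the model is matched in; -1 (default) for
        negative-going a-wave troughs.
    window : {"trough", "fixed"}
        Initial-segment selection rule.
    t_max, window_pad : float
        Fixed-rule horizon / trough-rule padding fraction.
    dt_internal : float
        Integrator step (s).
    max_iter, tol : int, float
        LM iteration cap and relative cost-decrease convergence
        threshold.
    damping_init, damping_factor, damping_max : float
        Marquardt damping schedule: lambda shrinks by the factor on
        accepted steps, grows on rejections, and the fit stalls out
        (converged=False unless already at the optimum) if lambda
        exceeds the ceiling.
    jacobian_step : float
        Relative forward-difference step for sensitivities.

    Attributes
    ----------
    params_ : KineticParameters — fitted rate constants.
    pools_ : PoolTotals — fitted pool totals.
    result_ : FitResult — residuals, error metric, convergence record.
    window_ : (start, stop) — fitted sample index range.
    n_iter_ : int — accepted LM iterations.
    converged_ : bool

    Notes
    -----
    Free parameters are optimized as their logarithms, which enforces
    positivity without constraints; the normal equations use Marquardt
    scaling, solving ``(J'J + lambda*diag(J'J)) delta = J'r`` with
    ``r = data - model``.  A step is accepted only if the cost
    ``||r||^2`` decreases, so the accepted-cost history is monotone.
    """

    def __init__(
        self,
        free: Sequence[str] = ("k1u",),
        params: Union[KineticParameters, dict, str, None] = None,
        pools: Union[PoolTotals, dict, None] = None,
        stimulus: Optional[Stimulus] = None,
        sign: float = -1.0,
        window: str = "trough",
        t_max: float = 0.28,
        window_pad: float = 0.15,
        dt_internal: float = 5e-5,
        max_iter: int = 200,
        tol: float = 1e-10,
        damping_init: float = 1e-3,
        damping_factor: float = 10.0,
        damping_max: float = 1e12,
        jacobian_step: float = 1e-6,
    ):
        self.free = free
        self.params = params
        self.pools = pools
        self.stimulus = stimulus
        self.sign = sign
        self.window = window
        self.t_max = t_max
        self.window_pad = window_pad
        self.dt_internal = dt_internal
        self.max_iter = max_iter
        self.tol = tol
        self.damping_init = damping_init
        self.damping_factor = damping_factor
        self.damping_max = damping_max
        self.jacobian_step = jacobian_step

    # -- sklearn plumbing -------------------------------------------------

    def _validate_X_y(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ConfigError("X must be a 1-D array of sample times (or column vector)")
        if y is None:
            return X
        y = np.asarray(y, dtype=float)
        if y.shape != X.shape:
            raise ConfigError("y must match X in length")
        return X, y

    # -- estimation --------------------------------------------------------

    def fit(self, X, y):
        """Run the Levenberg-Marquardt fit on the trace (times X, amplitudes y)."""
        times, amps = self._validate_X_y(X, y)
        trace = ERGTrace(times, amps)

        free = validate_free_names(self.free)
        params0, fixture_pools = _resolve_params(self.params)
        pools0 = _resolve_pools(self.pools if self.pools is not None else fixture_pools)
        stim = self.stimulus if self.stimulus is not None else Stimulus()
        if self.damping_factor <= 1.0:
            raise ConfigError("damping_factor must exceed 1")

        window = select_fit_window(trace, self.window, self.t_max, self.window_pad)
        start, stop = window
        tw = trace.times[start:stop]
        yw = trace.amplitudes[start:stop]
        y_norm = float(np.linalg.norm(yw))

        def model_of(p, q):
            return predict_signal(tw, p, q, stim, sign=self.sign,
                                  dt_internal=self.dt_internal)

        params, pools = params0, pools0
        theta = np.log(get_free_values(params, pools, free))
        m = model_of(params, pools)
        r = yw - m
        cost = float(r @ r)
        cost_history = [cost]
        lam = float(self.damping_init)
        converged = False
        message = ""
        n_iter = 0

        def at_optimum(c):
            # perfect (noiseless self-consistent) fits bottom out here
            return y_norm > 0 and np.sqrt(c) / y_norm < 1e-12

        if at_optimum(cost):
            converged = True
            message = "initial guess already at optimum"

        while not converged and n_iter < self.max_iter:
            J = numerical_jacobian(trace, params, pools, free, window,
                                   step=self.jacobian_step, stimulus=stim,
                                   sign=self.sign, dt_internal=self.dt_internal,
                                   base=m)
            # chain rule to log-space: d f / d log p = p * d f / d p
            Jl = J * np.exp(theta)[None, :]
            A = Jl.T @ Jl
            g = Jl.T @ r
            diag = np.diag(A).copy()
            diag[diag <= 0] = max(diag.max(), 1.0) * 1e-14 + 1e-300

            accepted = False
            while lam <= self.damping_max:
                try:
                    delta = np.linalg.solve(A + lam * np.diag(diag), g)
                except np.linalg.LinAlgError:
                    lam *= self.damping_factor
                    continue
                theta_trial = np.clip(theta + delta, -_LOG_LIM, _LOG_LIM)
                p_trial, q_trial = set_free_values(params, pools, free,
                                                   np.exp(theta_trial))
                try:
                    m_trial = model_of(p_trial, q_trial)
                except Exception:
                    lam *= self.damping_factor
                    continue
                r_trial = yw - m_trial
                cost_trial = float(r_trial @ r_trial)
                if np.isfinite(cost_trial) and cost_trial < cost:
                    accepted = True
                    break
                lam *= self.damping_factor

            if not accepted:
                message = "damping ceiling reached without a cost-decreasing step"
                break

            theta, params, pools = theta_trial, p_trial, q_trial
            m, r = m_trial, r_trial
            prev_cost, cost = cost, cost_trial
            cost_history.append(cost)
            lam = max(lam / self.damping_factor, 1e-300)
            n_iter += 1

            if at_optimum(cost):
                converged = True
                message = "residual at numerical floor"
            elif prev_cost - cost <= self.tol * prev_cost:
                converged = True
                message = "relative cost decrease below tolerance"

        if not converged and not message:
            message = "maximum iterations reached"

        rel_err = relative_error(yw, m) if y_norm > 0 else 0.0

        self.params_ = params
        self.pools_ = pools
        self.stimulus_ = stim
        self.window_ = window
        self.free_ = free
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.result_ = FitResult(
            params=params,
            pools=pools,
            free=free,
            estimates=np.exp(theta),
            residual=r.copy(),
            relative_error_pct=rel_err,
            n_iter=n_iter,
            converged=converged,
            damping_final=lam,
            cost_history=cost_history,
            window=window,
            message=message,
        )
        return self

    def predict(self, X):
        """Simulate the fitted model at the given sample times."""
        times = self._validate_X_y(X)
        if not hasattr(self, "params_"):
            raise ConfigError("estimator is not fitted yet; call fit first")
        return predict_signal(times, self.params_, self.pools_, self.stimulus_,
                              sign=self.sign, dt_internal=self.dt_internal)
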