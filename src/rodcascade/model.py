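"""Core kinetic model of the rod phototransduction cascade.

The model tracks eight dynamic species of the rod outer segment —
activated rhodopsin (R*), activated transducin alpha subunit (G*), the
R*:G complex (C1), activated PDE subunits (E*), the E*:cGMP complex
(C2), free cGMP, inactivated Galpha-GDP (Gr), and cytoplasmic Ca2+ —
as normalized, dimensionless concentrations ``x1 .. x8``.  Seventeen
effective rate constants drive mass-action activation (photoexcitation,
transducin and PDE activation, cGMP hydrolysis) and the calcium-mediated
inactivation feedbacks (R* shutoff, cGMP resynthesis, Ca2+ restoration).

The recorded photoreceptor signal is a Hill-type readout of cGMP
depletion relative to the dark-adapted level,

    f(t) = k17 * (cG0**n - x6(t)**n),    n = 2 by default,

optionally sign-flipped so that the model trace is a negative-going
a-wave trough like a conventional ERG recording.

Concentrations are ratios normalized against a fixed rhodopsin pool
(R0 = 50), so the rate constants are *effective* rates: comparable
across experimental groups fitted with the same normalization, but not
directly against literature pseudo-first-order rates.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace, fields
from typing import Iterable, Mapping

import numpy as np

from .exceptions import ConfigError, DomainError

__all__ = [
    "KineticParameters",
    "PoolTotals",
    "Stimulus",
    "RATE_NAMES",
    "POOL_NAMES",
    "FIXTURE_NAMES",
    "fixture_parameters",
    "dark_state",
    "reaction_rhs",
    "erg_output",
]

#: Names of the 17 effective rate constants, in cascade order.
RATE_NAMES = (
    "k1u", "k2", "k3", "k4", "k5", "k6", "k7", "k8", "k9",
    "k10", "k11", "k12", "k13", "k14", "k15", "k16", "k17",
)

#: Names of the dark-adapted pool totals / initial concentrations.
POOL_NAMES = ("R0", "G0", "E0", "cG0", "Ca0")


@dataclass(frozen=True)
class KineticParameters:
    """The 17 effective rate constants plus the channel Hill coefficient.

    ``k1u`` is the composite photoactivation rate (rate constant times
    light intensity); the two factors are never separated because only
    their product is identifiable from a recording.  ``n_cG`` is the
    cooperativity of channel gating by cGMP and is a structural constant
    (default 2), not a fitted parameter.
    """

    k1u: float
    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    k7: float
    k8: float
    k9: float
    k10: float
    k11: float
    k12: float
    k13: float
    k14: float
    k15: float
    k16: float
    k17: float
    n_cG: float = 2.0

    def __post_init__(self):
        for name in RATE_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0.0:
                raise ConfigError(f"rate constant {name} must be strictly positive, got {v!r}")
        if not np.isfinite(self.n_cG) or self.n_cG <= 0.0:
            raise ConfigError(f"n_cG must be strictly positive, got {self.n_cG!r}")

    def rates(self) -> tuple[float, ...]:
        """The 17 rates as a tuple in :data:`RATE_NAMES` order."""
        return tuple(float(getattr(self, n)) for n in RATE_NAMES)

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "KineticParameters":
        known = {f.name for f in fields(cls)}
        return cls(**{k: float(v) for k, v in d.items() if k in known})

    def replace(self, **changes) -> "KineticParameters":
        return replace(self, **changes)


@dataclass(frozen=True)
class PoolTotals:
    """Dark-adapted totals / initial concentrations (normalized ratios).

    Defaults are the normalized ratios R0=50, G0=5, E0=0.5, cG0=4,
    Ca0=0.22 with R0 the fixed normalization reference.
    """

    R0: float = 50.0
    G0: float = 5.0
    E0: float = 0.5
    cG0: float = 4.0
    Ca0: float = 0.22

    def __post_init__(self):
        for name in POOL_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0.0:
                raise ConfigError(f"pool total {name} must be strictly positive, got {v!r}")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.R0, self.G0, self.E0, self.cG0, self.Ca0)

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "PoolTotals":
        return cls(**{k: float(v) for k, v in d.items() if k in POOL_NAMES})

    def replace(self, **changes) -> "PoolTotals":
        return replace(self, **changes)


@dataclass(frozen=True)
class Stimulus:
    """A step of light: the photoactivation term is active on [t_on, t_off)."""

    t_on: float = 0.0
    t_off: float = 0.3

    def __post_init__(self):
        if not (self.t_on < self.t_off):
            raise ConfigError(f"stimulus needs t_on < t_off, got [{self.t_on}, {self.t_off})")

    def active(self, t: float) -> bool:
        return self.t_on <= t < self.t_off


# Fitted effective rates per experimental group: NOB1 mice (b-wave
# genetically suppressed), NOB1 with N-methyl-N-nitrosourea treatment
# (photoreceptor-damaged), and wild type.
_FIXTURES: dict[str, dict[str, float]] = {
    "NOB": dict(
        k1u=0.6717, k2=17.9455, k3=18.2341, k4=5847.3409, k5=52.3225,
        k6=0.2329, k7=45.6849, k8=36.8285, k9=6.1385, k10=1.2880,
        k11=52.8416, k12=31.2042, k13=79.5587, k14=14.9012, k15=11.0894,
        k16=6.5656, k17=1649.2012,
    ),
    "NOB_drug": dict(
        k1u=0.5488, k2=27.5449, k3=14.4897, k4=3997.7881, k5=40.9749,
        k6=2.3551, k7=34.2112, k8=24.9522, k9=5.4685, k10=1.2817,
        k11=35.9586, k12=27.3478, k13=56.7860, k14=2.1693, k15=9.0645,
        k16=3.1117, k17=614.8300,
    ),
    "wild": dict(
        k1u=0.7487, k2=17.5549, k3=17.4280, k4=5723.8125, k5=51.0795,
        k6=0.2336, k7=45.7306, k8=36.2993, k9=6.0209, k10=1.2676,
        k11=53.0859, k12=28.8673, k13=77.7604, k14=14.7936, k15=10.6546,
        k16=5.5993, k17=2227.1000,
    ),
}

FIXTURE_NAMES = tuple(_FIXTURES)


def fixture_parameters(name: str) -> tuple[KineticParameters, PoolTotals]:
    """Return the named group's fitted rate constants and the default pools.

    Parameters
    ----------
    name : one of ``"NOB"``, ``"NOB_drug"``, ``"wild"``.
    """
    try:
        rates = _FIXTURES[name]
    except KeyError:
        raise ConfigError(
            f"unknown parameter fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    return KineticParameters(**rates), PoolTotals()


def dark_state(pools: PoolTotals) -> np.ndarray:
    """The dark-adapted initial state [0, 0, 0, 0, 0, cG0, 0, Ca0]."""
    return np.array([0.0, 0.0, 0.0, 0.0, 0.0, pools.cG0, 0.0, pools.Ca0])


def _make_rhs(params: KineticParameters, pools: PoolTotals):
    """Bind parameters into a fast scalar right-hand-side closure.

    The returned function takes the eight state components plus the
    *active* photoactivation rate (k1u while the light is on, 0.0
    otherwise) and returns the eight time-derivatives as a tuple.  The
    free pools (R0-x1-x3 etc.) are formed on the fly so conservation is
    structural.  This is the hot path of the fixed-step integrator, so
    it works on plain floats.
    """
    (k1u, k2, k3, k4, k5, k6, k7, k8, k9,
     k10, k11, k12, k13, k14, k15, k16, _k17) = params.rates()
    n = float(params.n_cG)
    R0, G0, E0, cG0, Ca0 = pools.as_tuple()
    cG0n = cG0 ** n

    if n == 2.0:
        def rhs(x1, x2, x3, x4, x5, x6, x7, x8, kact,
                k2=k2, k3=k3, k4=k4, k5=k5, k6=k6, k7=k7, k8=k8, k9=k9,
                k10=k10, k11=k11, k12=k12, k13=k13, k14=k14, k15=k15, k16=k16,
                R0=R0, G0=G0, E0=E0, cG0=cG0, Ca0=Ca0, cG0n=cG0n):
            free_G = G0 - x3 - x2 - x4 - x5 - x7
            free_E = E0 - x4 - x5
            dCa = Ca0 - x8
            dcG = cG0 - x6
            hill = cG0n - x6 * x6
            bind1 = k2 * x1 * free_G
            bind2 = k6 * x4 * x6
            act_E = k5 * x2 * free_E
            return (
                kact * (R0 - x1 - x3) - bind1 + k3 * x3 + k4 * x3 - k13 * dCa * x1 - k16 * x1,
                k4 * x3 - act_E,
                bind1 - k3 * x3 - k4 * x3,
                act_E - bind2 + k7 * x5 + k8 * x5 - k9 * x4,
                bind2 - k7 * x5 - k8 * x5,
                -bind2 + k7 * x5 + k14 * dCa * dcG + k15 * dcG,
                k9 * x4 - k10 * x7,
                -k11 * hill + k12 * dCa,
            )
    else:
        def rhs(x1, x2, x3, x4, x5, x6, x7, x8, kact,
                k2=k2, k3=k3, k4=k4, k5=k5, k6=k6, k7=k7, k8=k8, k9=k9,
                k10=k10, k11=k11, k12=k12, k13=k13, k14=k14, k15=k15, k16=k16,
                R0=R0, G0=G0, E0=E0, cG0=cG0, Ca0=Ca0, cG0n=cG0n, n=n):
            free_G = G0 - x3 - x2 - x4 - x5 - x7
            free_E = E0 - x4 - x5
            dCa = Ca0 - x8
            dcG = cG0 - x6
            hill = cG0n - x6 ** n
            bind1 = k2 * x1 * free_G
            bind2 = k6 * x4 * x6
            act_E = k5 * x2 * free_E
            return (
                kact * (R0 - x1 - x3) - bind1 + k3 * x3 + k4 * x3 - k13 * dCa * x1 - k16 * x1,
                k4 * x3 - act_E,
                bind1 - k3 * x3 - k4 * x3,
                act_E - bind2 + k7 * x5 + k8 * x5 - k9 * x4,
                bind2 - k7 * x5 - k8 * x5,
                -bind2 + k7 * x5 + k14 * dCa * dcG + k15 * dcG,
                k9 * x4 - k10 * x7,
                -k11 * hill + k12 * dCa,
            )

    return rhs


def reaction_rhs(
    state: Iterable[float],
    params: KineticParameters,
    pools: PoolTotals,
    light_on: bool = True,
) -> np.ndarray:
    """Evaluate the time-derivatives of the eight cascade species.

    Parameters
    ----------
    state : array-like of 8 floats
        Current concentrations (x1..x8).
    params, pools
        Rate constants and dark-adapted pool totals.
    light_on : bool
        Whether the photoactivation term k1u*(R0 - x1 - x3) is active;
        when False it is replaced by zero.

    Returns
    -------
    ndarray of shape (8,) — d(x1..x8)/dt.

    Raises
    ------
    DomainError
        If any state component is non-finite.
    """
    x = np.asarray(state, dtype=float)
    if x.shape != (8,):
        raise DomainError(f"state must have 8 components, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise DomainError("state contains non-finite components")
    rhs = _make_rhs(params, pools)
    kact = params.k1u if light_on else 0.0
    return np.array(rhs(*x, kact))


def erg_output(
    x6,
    params: KineticParameters,
    pools: PoolTotals,
    sign: float = 1.0,
):
    """Map free-cGMP concentration to the recorded signal amplitude.

    Implements the Hill-type readout ``sign * k17 * (cG0**n - x6**n)``.
    As written the deflection is non-negative for cGMP depletion; pass
    ``sign=-1`` to produce the negative-going trough convention of
    recorded a-waves (the default of the simulation layer).

    Accepts a scalar or an array of x6 values.
    """
    x6 = np.asarray(x6, dtype=float)
    if np.any(x6 < 0):
        raise DomainError("x6 (cGMP concentration) must be non-negative")
    n = params.n_cG
    out = sign * params.k17 * (pools.cG0 ** n - x6 ** n)
    return float(out) if out.ndim == 0 else out
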