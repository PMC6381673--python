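"""Exception types shared across the package."""


class ConfigError(ValueError):
    """Invalid configuration: bad pool totals, unknown fixture, malformed spec."""


class DomainError(ValueError):
    """Mathematical-domain violation, e.g. non-finite state components."""


class IntegrationError(RuntimeError):
    """The ODE integration produced a non-finite state.

    Carries the time of failure in ``t_fail``.
    """

    def __init__(self, message: str, t_fail: float):
        super().__init__(message)
        self.t_fail = t_fail


class WindowUndefinedError(ValueError):
    """The fit window cannot be determined (e.g. trough not bracketed)."""


class TraceFormatError(ValueError):
    """A trace file violates the expected CSV format."""


class MetricUndefinedError(ValueError):
    """A metric is undefined for the given inputs (e.g. zero data norm)."""
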