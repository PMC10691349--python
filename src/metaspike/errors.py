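"""Exception types shared across the simulator suite."""


class MetaspikeError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MetaspikeError):
    """Invalid, unknown, or ill-typed configuration key."""


class DomainError(MetaspikeError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class IntegrationError(MetaspikeError):
    """A numerical integration step produced an invalid state.

    Usually indicates the time step is too large for the chosen
    parameters; the message says which variable left its bounds.
    """


class SteadyStateError(MetaspikeError):
    """Fixed-point search failed to converge to the stated tolerance."""
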