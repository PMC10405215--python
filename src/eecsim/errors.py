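"""Exception hierarchy.

Exit-code mapping used by the CLI: configuration errors -> 2,
convergence errors -> 3, numerical errors -> 4.
"""


class EECSimError(Exception):
    """Base class for package errors."""


class ConfigurationError(EECSimError):
    """Invalid configuration: unknown keys, out-of-range parameters."""


class ParameterError(EECSimError, ValueError):
    """Physically inadmissible parameter (e.g. negative attraction strength)."""


class ConvergenceError(EECSimError):
    """A profile or estimate has not met its convergence gate."""


class NumericalError(EECSimError):
    """Quadrature/root-finding/integration failure with diagnostics."""
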