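"""Exception hierarchy shared across the package.

Exit codes used by the command-line layer: config errors map to 2,
data errors to 3, convergence errors to 4.
"""


class RampkinError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(RampkinError):
    """Invalid configuration, parameters or units."""

    exit_code = 2


class ScheduleError(ConfigError):
    """A flow schedule is unphysical (flow reaches zero, reactor not swept)."""


class SchemaError(ConfigError):
    """A table or scheme is missing required fields/species."""


class DataError(RampkinError):
    """Input data violate the assumptions of an estimator (e.g. a
    non-monotone step-response curve)."""

    exit_code = 3


class IntegrationError(RampkinError):
    """The kinetic ODE integrator failed; carries solver diagnostics."""

    exit_code = 4

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ConvergenceError(RampkinError):
    """A nonlinear fit failed to converge."""

    exit_code = 4


class IdentifiabilityError(ConvergenceError):
    """The requested parameters are not identifiable from the data
    (singular Jacobian, e.g. activation energies from isothermal data)."""
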