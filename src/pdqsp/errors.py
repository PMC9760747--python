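"""Package exception hierarchy."""


class PdqspError(Exception):
    """Base class for all package errors."""


class ConfigError(PdqspError):
    """Invalid configuration or parameter value."""


class CalibrationError(PdqspError):
    """A calibration target is unreachable or structurally infeasible."""


class BindingSolveError(PdqspError):
    """The binding quasi-equilibrium could not be solved to tolerance."""


class IntegrationError(PdqspError):
    """ODE integration failed."""


class RegimenParseError(PdqspError):
    """A dosing-regimen specification string could not be parsed."""


class FitError(PdqspError):
    """Population or individual estimation failed."""
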