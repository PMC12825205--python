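"""Exception hierarchy for the package."""


class PrljagError(Exception):
    """Base class for package errors."""


class ConfigurationError(PrljagError):
    """A fixture or configuration table is missing or inconsistent."""


class ValidationError(PrljagError):
    """A supplied value violates a model contract (e.g. negative rate)."""


class SimulationError(PrljagError):
    """The ODE integrator failed; carries the offending parameter set."""

    def __init__(self, message, params=None):
        super().__init__(message)
        self.params = params


class NormalizationError(PrljagError):
    """A fold-change could not be formed (zero baseline)."""


class DataError(PrljagError):
    """An observation/cohort table is malformed or incomplete."""
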