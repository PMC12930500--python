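"""Exception hierarchy shared by all modules."""


class BasalcogError(Exception):
    """Base class for all package-specific errors."""


class DomainError(BasalcogError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class SimulationError(BasalcogError, RuntimeError):
    """The integrator produced an invalid state (blow-up, large negatives)."""


class UndefinedFoldChangeError(BasalcogError, ValueError):
    """A fold change is requested against a zero reference peak."""


class AssumptionError(BasalcogError, ValueError):
    """A closed-form result was requested outside its validity region."""


class ConfigError(BasalcogError, ValueError):
    """A configuration file or sweep specification is invalid."""
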