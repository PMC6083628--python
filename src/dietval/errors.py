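"""Exception hierarchy.

The CLI maps these onto distinct exit codes: configuration errors (2),
input/data errors (3), non-convergence (4).
"""


class DietvalError(Exception):
    """Base class for all package errors."""


class ConfigError(DietvalError):
    """Invalid configuration (bad parameter values, inadmissible covariance)."""


class InputError(DietvalError):
    """Invalid input data (non-positive values, missing columns, bad mode)."""


class ContractError(DietvalError):
    """An operation was called outside its documented precondition."""


class IdentifiabilityError(InputError):
    """The data cannot identify the requested model (e.g. <2 instruments)."""


class UndefinedResultError(DietvalError):
    """A derived quantity is undefined for these parameters (zero denominator)."""


class ConvergenceError(DietvalError):
    """An iterative fit failed to converge and no fallback was permitted."""
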