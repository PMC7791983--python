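"""Exception hierarchy shared across the package."""


class PromkitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PromkitError, ValueError):
    """A value violates an instrument or record invariant."""


class SchemaError(PromkitError, ValueError):
    """A tabular input is missing required columns or has a bad header."""


class EmptyCohortError(PromkitError, ValueError):
    """A cohort has no usable records."""


class ConfigurationError(PromkitError, ValueError):
    """A simulation or pipeline configuration is infeasible."""


class DegenerateStatisticError(PromkitError, ValueError):
    """A statistic is undefined for the given inputs (zero SD, r = 1, ...)."""


class InsufficientDataError(PromkitError, ValueError):
    """A stratum or class required by a statistic is empty or too small."""
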