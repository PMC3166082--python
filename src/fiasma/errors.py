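"""Exception hierarchy shared across the package."""


class FiasmaError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FiasmaError):
    """A file could not be parsed under the declared format."""


class ValidationError(FiasmaError):
    """Input data violate a documented contract (duplicate ids, bad ranges...)."""


class ConfigurationError(FiasmaError):
    """Inconsistent configuration, e.g. a speciation variant without its pKa values."""


class PipelineError(FiasmaError):
    """A pipeline stage cannot proceed (empty matrix after filtering, ...)."""


class NumericError(FiasmaError):
    """Numerical failure (integrator breakdown, invariant violation)."""
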