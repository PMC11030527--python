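"""Exception and warning types shared across the package."""


class HaplaseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HaplaseError, ValueError):
    """A simulation or pipeline configuration value is invalid."""


class ConsistencyError(HaplaseError, ValueError):
    """Inputs that must agree (e.g. loci vs. ground truth) do not."""


class ParseError(HaplaseError, ValueError):
    """A file does not conform to its declared format."""


class ValidationError(HaplaseError, ValueError):
    """A statistical input is outside its legal domain (e.g. p not in [0, 1])."""


class AnnotationWarning(UserWarning):
    """A transcript model is unusable for part of the annotation (e.g. CDS length
    not divisible by three); the offending terms are suppressed, not fatal."""
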