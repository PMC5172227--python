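"""Exception and warning types used across the pipeline."""


class MitoprofilerError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MitoprofilerError):
    """A configuration object violates its invariants."""


class GenerationError(MitoprofilerError):
    """The synthetic generator could not satisfy a geometric constraint."""


class InputError(MitoprofilerError):
    """An input table or image does not match the expected schema."""


class ParameterError(MitoprofilerError):
    """An operation parameter is outside its valid range."""


class FittingError(MitoprofilerError):
    """A statistical fit could not be performed (e.g. single-class input)."""


class AnalysisWarning(UserWarning):
    """Non-fatal analysis condition (empty mask, skipped fold, low n, ...)."""
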