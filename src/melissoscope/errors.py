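"""Exception hierarchy shared across the pipeline stages."""


class MelissoscopeError(Exception):
    """Base class for all package errors."""


class StackError(MelissoscopeError):
    """A focal stack violates its structural contract (plane count, shapes)."""


class FormatError(MelissoscopeError):
    """A file could not be decoded into the expected structure."""


class SchemaError(MelissoscopeError):
    """A feature table has missing/unknown columns."""


class SizingError(MelissoscopeError):
    """A phantom grain would be rendered too small to measure reliably."""


class ConfigurationError(MelissoscopeError):
    """An unknown modality or invalid parameterization."""


class UndefinedInputError(MelissoscopeError):
    """A measurement was requested on an empty/degenerate region."""


class ParameterError(MelissoscopeError):
    """An operation parameter is outside its valid range."""


class ContractViolation(MelissoscopeError):
    """A precondition stated in the operation contract was broken."""


class DegenerateDataError(MelissoscopeError):
    """Statistics requested on data with no usable variance."""
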