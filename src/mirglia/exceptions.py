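"""Exception hierarchy shared across the analysis stages."""


class MirgliaError(Exception):
    """Base class for all package errors."""


class FormatError(MirgliaError):
    """A delimited input file does not match the expected schema."""


class EmptyInputError(MirgliaError):
    """An input table contains no data rows."""


class ParameterError(MirgliaError, ValueError):
    """A function argument is outside its documented domain."""


class ValidationError(MirgliaError):
    """A data record violates a field-level invariant."""


class ConfigurationError(MirgliaError):
    """A configuration value is inconsistent with the data it is applied to."""


class IntegrityError(MirgliaError):
    """Cross-table references are inconsistent (e.g., unknown ids)."""
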