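"""Exception hierarchy shared across the package."""


class MetfaError(Exception):
    """Base class for all package errors."""


class SchemaError(MetfaError):
    """Input file does not provide the required columns."""


class ValidationError(MetfaError):
    """Input data violates a structural precondition (duplicates, bad weights...)."""


class NoDataError(MetfaError):
    """An operation was left with no data to work on."""


class SpecError(MetfaError):
    """A variance-model specification is invalid for the data at hand."""


class ConnectivityError(MetfaError):
    """Dataset is not sufficiently connected for the requested analysis."""

    def __init__(self, message, components=None):
        super().__init__(message)
        self.components = components
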