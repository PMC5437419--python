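"""Exception hierarchy shared across the package."""


class Hor5sError(Exception):
    """Base class for all package errors."""


class EmptyInput(Hor5sError):
    """An operation received an empty table, read set or spec."""


class InvalidArgument(Hor5sError, ValueError):
    """A parameter is outside its documented domain."""


class NoGenicRegion(Hor5sError):
    """No placement of the genic consensus reaches the identity floor."""


class ParseError(Hor5sError):
    """A record in an input file could not be parsed."""

    def __init__(self, message: str, record_index: int | None = None):
        super().__init__(message)
        self.record_index = record_index


class InvalidPlacement(Hor5sError):
    """A read placement lies outside the reference it claims to map to."""


class InsufficientData(Hor5sError):
    """Too few observations for the requested statistic."""


class ConfigError(Hor5sError):
    """A pipeline configuration field failed validation."""

    def __init__(self, field: str, message: str):
        super().__init__(f"{field}: {message}")
        self.field = field
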