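"""Exception hierarchy shared across the package."""


class EqrbotError(Exception):
    """Base class for all package-specific errors."""


class DomainError(EqrbotError, ValueError):
    """An identifier or element is outside the domain it must belong to."""


class CapacityError(EqrbotError):
    """A configurable size cap was exceeded (exhaustive search, saturation)."""


class KBParseError(EqrbotError):
    """Malformed knowledge-base text; carries line/column of the failure."""

    def __init__(self, message: str, line: int, column: int):
        super().__init__(f"{message} (line {line}, column {column})")
        self.line = line
        self.column = column


class SafetyError(EqrbotError):
    """A rule head uses a variable that does not occur in its body."""


class InstantiationError(EqrbotError):
    """A scheme binding is missing or malformed; names the offending variable."""


class ConfigurationError(EqrbotError):
    """Registry misuse: duplicate scheme, missing template, and similar."""


class AcceptabilityError(EqrbotError):
    """An explanation was requested for a rejected scheme instance."""


class EmptyRepositoryError(EqrbotError):
    """The explanation repository holds no entry of the required kind."""
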