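"""Exception types shared across the package."""


class GlenocardError(Exception):
    """Base class for all package-specific errors."""


class DomainError(GlenocardError, ValueError):
    """A numeric argument lies outside the operation's domain."""


class DegenerateInputError(GlenocardError, ValueError):
    """Input is structurally valid but geometrically degenerate (e.g. collinear rim points)."""


class InvalidGeometryError(GlenocardError, ValueError):
    """A polygon or curve violates its geometric contract (e.g. self-intersection)."""


class DataError(GlenocardError, ValueError):
    """Malformed input data file (CSV/JSON/config)."""


class UndefinedICCError(GlenocardError, ValueError):
    """ICC is undefined because the ratings table carries no variance."""
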