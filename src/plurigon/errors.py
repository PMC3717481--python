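"""Exception hierarchy."""


class PlurigonError(Exception):
    """Base class for all package errors."""


class ParseError(PlurigonError):
    """A text input could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DimensionalityError(PlurigonError):
    """Vector too short, mismatched lengths, or an invalid reduction target."""


class GeometryError(PlurigonError):
    """Degenerate or inconsistent geometry (bad hull, open mesh, inverted faces)."""
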