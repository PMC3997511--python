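"""Exception hierarchy shared by all iontraj modules."""


class IontrajError(Exception):
    """Base class for all package errors."""


class FormatError(IontrajError):
    """A structure/trajectory file could not be parsed."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class EmptyInputError(IontrajError):
    """An input contained no usable records."""


class AlignmentError(IontrajError):
    """Models of a multi-model file are inconsistent with each other."""


class SelectionError(IontrajError):
    """A selection expression could not be parsed or applied."""

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


class CardinalityError(SelectionError):
    """A selection resolved to the wrong number of atoms."""

    def __init__(self, message: str):
        super().__init__(message, position=None)


class ValidationError(IontrajError):
    """A configuration object failed its invariants."""


class DegenerateGeometryError(IontrajError):
    """Input geometry is degenerate for the requested operation."""


class InsufficientDataError(IontrajError):
    """Not enough frames/samples for a statistically defined quantity."""


class ParameterError(IontrajError):
    """A parameter value is missing or outside its documented range."""


class TopologyError(IontrajError):
    """A required atom or residue is absent from the topology."""


class FitError(IontrajError):
    """Nonlinear fit failed to converge; carries solver diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
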