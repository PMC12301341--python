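"""Exception hierarchy shared across the package.

Input/parse problems raise :class:`InputError` subclasses (CLI exit code 2);
biological/constraint failures raise :class:`AnalysisError` subclasses
(CLI exit code 3).
"""


class PhycodelimError(Exception):
    """Base class for all package errors."""


class InputError(PhycodelimError):
    """Malformed or inconsistent input data."""


class FastaParseError(InputError):
    """FASTA file could not be parsed; ``line`` is 1-based when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class DuplicateIdError(InputError):
    """Two records share an id within one collection."""


class AnalysisError(PhycodelimError):
    """A biologically meaningful stage failed on valid input."""


class UndefinedDistanceError(AnalysisError):
    """No comparable columns between two aligned sequences."""


class DelimitationFailure(AnalysisError):
    """An anchor motif could not be located or annealed."""


class DegenerateIts2Error(AnalysisError):
    """Anchors are adjacent: the delimited ITS2 interval is empty."""


class ConstraintViolationError(AnalysisError):
    """A folding constraint cannot be satisfied on this sequence."""


class AnnotationError(AnalysisError):
    """A barcode policy references a helix absent from the structure."""


class GenerationError(InputError):
    """A synthetic-family spec requests more changes than eligible sites."""
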