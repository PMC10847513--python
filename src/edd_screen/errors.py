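"""Exception hierarchy shared across the package."""


class EddScreenError(Exception):
    """Base class for all package errors."""


class FastaFormatError(EddScreenError):
    """Malformed or empty FASTA input."""


class DuplicateIdError(EddScreenError):
    """Two records share the same identifier."""


class AlphabetError(EddScreenError):
    """A sequence contains a character outside its allowed alphabet."""

    def __init__(self, symbol: str, position: int, context: str = ""):
        self.symbol = symbol
        self.position = position  # 1-based
        msg = f"illegal character {symbol!r} at position {position}"
        if context:
            msg += f" in {context}"
        super().__init__(msg)


class AlignmentShapeError(EddScreenError):
    """Rows of an alignment have unequal length or too few rows."""


class NewickParseError(EddScreenError):
    """Invalid Newick string."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset  # 0-based character offset when known
        if offset is not None:
            message = f"{message} (at character offset {offset})"
        super().__init__(message)


class PatternSyntaxError(EddScreenError):
    """Invalid motif pattern text."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at character offset {offset})"
        super().__init__(message)


class ConfigurationError(EddScreenError):
    """Invalid library / scheme / threshold configuration."""


class UndefinedColumnError(EddScreenError):
    """An alignment column holds no non-gap residues."""


class SpanError(EddScreenError):
    """Empty or out-of-range column span."""


class FrameError(EddScreenError):
    """Internal stop codon or CDS length not divisible by three."""


class IncomparablePairError(EddScreenError):
    """Two aligned rows share no non-gap column."""


class TreeSizeError(EddScreenError):
    """Too few taxa for the requested tree operation."""


class CalibrationError(EddScreenError):
    """Non-positive calibration slope or otherwise unusable series."""


class KineticFitError(EddScreenError):
    """Kinetic data unusable with the requested fitting method."""


class UndefinedRatioError(EddScreenError):
    """Division by a zero quantity in a stoichiometry check."""
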