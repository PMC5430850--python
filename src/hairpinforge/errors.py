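"""Exception hierarchy shared by all pipeline stages."""


class HairpinForgeError(Exception):
    """Base class for all package-specific errors."""


class ParseError(HairpinForgeError):
    """A file could not be parsed (carries a line number where known)."""


class ConsistencyError(HairpinForgeError):
    """Two inputs that must agree (e.g. sequence and pair table) do not."""


class ChemistryError(HairpinForgeError):
    """A residue or atom is chemically unknown or of the wrong kind."""


class WrongChemistryError(ChemistryError):
    """An operation received a DNA model where RNA was required, or vice versa."""


class IllegalStructureError(HairpinForgeError):
    """A pair table violates nesting, involution or Watson-Crick pairing."""


class CorrespondenceError(HairpinForgeError):
    """Two coordinate/atom sets cannot be put in one-to-one correspondence."""


class DegenerateInputError(HairpinForgeError):
    """Input too small or empty for the requested geometric operation."""


class TemplateValidationError(HairpinForgeError):
    """A nucleotide template violates its geometric invariants."""


class MinimizerError(HairpinForgeError):
    """The restrained minimizer failed to make progress (carries the trace)."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace if trace is not None else []


class ClassificationError(HairpinForgeError):
    """A candidate record carries an unknown structural motif class."""


class GeometryError(HairpinForgeError):
    """A geometric precondition (box size, coordinate range) is violated."""


class FormatOverflowError(HairpinForgeError):
    """A value cannot be represented in the fixed-column output format."""
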