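"""Exception hierarchy shared across the package."""


class InappFitchError(Exception):
    """Base class for all package errors."""


class MatrixParseError(InappFitchError):
    """Malformed character-matrix text (undeclared symbol, bad block)."""


class DimensionError(InappFitchError):
    """Row length / taxon count disagrees with the declared dimensions."""


class TreeParseError(InappFitchError):
    """Malformed Newick text or duplicate leaf labels."""


class StructureError(InappFitchError):
    """Tree shape unsuitable for the requested operation (e.g. polytomy)."""


class DataError(InappFitchError):
    """Tree and matrix disagree (missing taxon, unexpanded missing cell)."""


class SizeLimitError(InappFitchError):
    """Exhaustive enumeration refused: instance too large."""
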