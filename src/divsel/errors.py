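"""Exception hierarchy.

Every error raised by the library derives from :class:`DivselError` so callers
can catch at whatever granularity they need.
"""


class DivselError(Exception):
    """Base class for all divsel errors."""


class ValidationError(DivselError):
    """A container invariant was violated."""


class AlignmentShapeError(ValidationError):
    """Rows of an alignment differ in length."""


class FrameError(ValidationError):
    """Codon data whose length or interval bounds are not multiples of 3."""


class IntervalError(DivselError):
    """Column intervals overlap or fall outside the alignment."""


class SchemaError(DivselError):
    """A tabular input is missing required columns."""


class TreeParseError(DivselError):
    """Newick input could not be parsed."""


class ParameterError(DivselError):
    """A numeric argument is outside its valid domain."""


class MappingError(DivselError):
    """A tip, taxon, or gene is missing from a required mapping."""


class MonophylyError(DivselError):
    """A taxonomic group is not monophyletic in the tree."""


class PruningError(DivselError):
    """Too few shared taxa to prune a constraint tree."""


class AnchorError(DivselError):
    """A synteny anchor gene is absent from the locus table."""


class SizeError(DivselError):
    """Too few taxa, records, or observations for the requested analysis."""


class ConvergenceError(DivselError):
    """Optimizer failed to converge; carries the best fit found so far."""

    def __init__(self, message, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit


class AuFitError(DivselError):
    """Too few usable scales to fit the multiscale-bootstrap curve."""
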