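"""Exception hierarchy for the hdxens pipeline."""


class HdxError(Exception):
    """Base class for all hdxens errors."""


class ParseError(HdxError):
    """A file could not be parsed (message names the offending line)."""


class FormatError(HdxError):
    """A table is missing required columns or metadata."""


class ValidationError(HdxError):
    """Input values violate a documented precondition."""


class StructureError(HdxError):
    """Structural inconsistency: atom counts, residue sets, missing atoms."""


class FeatureError(HdxError):
    """A per-residue feature could not be computed."""


class DimensionError(HdxError):
    """Mismatched array shapes between frames, weights or features."""


class ConvergenceError(HdxError):
    """Optimizer failed to converge; carries the partial trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace
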