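"""Exception types shared across the package."""


class NjoinError(ValueError):
    """Base class for all njoin errors."""


class PhylipParseError(NjoinError):
    """Malformed PHYLIP distance-matrix input; message names the offending line."""


class NewickParseError(NjoinError):
    """Malformed Newick input."""


class ValidationError(NjoinError):
    """Input violates a semantic contract (negative distance, asymmetry, ...)."""
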