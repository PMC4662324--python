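"""Exception hierarchy shared across the package."""


class PhyloDietError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PhyloDietError):
    """Malformed or out-of-contract input data."""


class DegenerateEntryError(ValidationError):
    """A diet entry with no positive category value."""


class UndefinedIndexError(ValidationError):
    """Dietary index undefined (all intake in the 'Other' category)."""


class NewickParseError(ValidationError):
    """Malformed Newick text (position reported by the parser)."""


class BranchLengthError(ValidationError):
    """Operation requires branch lengths the tree does not carry."""


class NotBinaryError(ValidationError):
    """Operation requires a fully bifurcating tree."""


class ConvergenceError(PhyloDietError):
    """Numerical optimization failed to converge after all restarts."""
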