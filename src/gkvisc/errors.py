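"""Exception hierarchy for gkvisc.

All library failures derive from :class:`GkviscError` so callers (and the
CLI) can catch one base class. Subclasses are deliberately fine-grained:
a non-uniform time grid is a different user mistake than a bad column map,
and the messages say which file/value offended.
"""


class GkviscError(Exception):
    """Base class for all gkvisc errors."""


class ValidationError(GkviscError):
    """A domain object violates one of its invariants."""


class ParseError(GkviscError):
    """A text input could not be parsed (non-numeric cell, bad header...)."""


class NonUniformTimeGridError(ParseError):
    """Rows of a time series are not equally spaced in time."""


class ColumnMapError(ParseError):
    """A requested column index does not exist in every data row."""


class FitError(GkviscError):
    """A least-squares fit failed or its result violates model constraints."""
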