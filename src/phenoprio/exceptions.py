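"""Exception hierarchy shared across the package."""


class PhenoprioError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PhenoprioError):
    """A file does not conform to its declared dialect."""


class AlignmentError(PhenoprioError):
    """Two objects that must share an identifier set do not."""


class DegenerateInputError(PhenoprioError):
    """Input is structurally valid but degenerate for the requested operation."""


class NumericError(PhenoprioError):
    """A numeric computation produced non-finite values."""
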