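"""Exception hierarchy shared across the package."""


class EcsbmrError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(EcsbmrError):
    """A required column is missing or the input file layout is wrong."""


class ValidationError(EcsbmrError):
    """The data violate a structural invariant (e.g. a dataset lacks a matched control)."""


class ParseError(EcsbmrError):
    """A cell could not be parsed as the required type; carries the offending row number."""


class FitError(EcsbmrError):
    """Model fitting failed or was asked to operate on a non-converged result."""
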