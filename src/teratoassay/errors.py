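"""Exception hierarchy for the tumorigenicity-assay toolkit."""


class TeratoassayError(Exception):
    """Base class for all package errors."""


class SchemaError(TeratoassayError):
    """Malformed or invariant-violating tabular input (names the offending row)."""


class SpacingError(TeratoassayError):
    """Dose ladder is not equally spaced on the log10 scale."""


class InsufficientDesignError(TeratoassayError):
    """The assay design cannot support the requested estimator (e.g. one dose group)."""


class BoundaryError(TeratoassayError):
    """A parameter is not identifiable because the data sit on the likelihood boundary."""


class SaturatedWellError(TeratoassayError):
    """All droplets in a ddPCR well are positive; the concentration is unbounded."""


class ReferenceFailure(TeratoassayError):
    """The reference-gene amplification failed, so the well cannot be interpreted."""
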