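"""Exception hierarchy used across the package."""


class MRNetError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MRNetError, ValueError):
    """An argument is outside its documented domain."""


class SpecificationError(MRNetError, ValueError):
    """A simulation specification violates its invariants (e.g. a cycle)."""


class WeakInstrumentError(MRNetError, ValueError):
    """An instrument is too weakly associated with its exposure to be used."""


class DataError(MRNetError, ValueError):
    """Input data are degenerate (constant, non-finite, misaligned)."""


class VariantLookupError(MRNetError, KeyError):
    """Requested variants are absent from a genotype matrix."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"variants not found: {', '.join(map(str, self.missing))}")


class CollinearityError(MRNetError, ValueError):
    """A design matrix is rank deficient; names the offending columns."""

    def __init__(self, columns, context=""):
        self.columns = list(columns)
        msg = f"collinear columns: {', '.join(map(str, self.columns))}"
        if context:
            msg = f"{context}: {msg}"
        super().__init__(msg)


class QueryError(MRNetError, ValueError):
    """An adjustment query is malformed (overlapping roles, unknown nodes)."""


class AmbiguityError(MRNetError, ValueError):
    """A graphical query cannot be answered because of unresolved edges."""


class ComparisonError(MRNetError, ValueError):
    """Two networks cannot be compared (mismatched node sets)."""
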