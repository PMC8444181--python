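"""Exception hierarchy shared across the package."""


class SiginfoError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(SiginfoError):
    """An event table is missing a required column or a column has the wrong type."""


class EmptyInputError(SiginfoError):
    """An input file or table contains no events."""


class ValidationError(SiginfoError):
    """A configuration violates one of its documented invariants."""


class DegenerateDataError(SiginfoError):
    """Data are degenerate for the requested operation (constant channel, zero
    variance, all-zero normalisation target, under-sized group, ...)."""
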