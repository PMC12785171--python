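"""Exception hierarchy shared across modules."""


class TelocapError(Exception):
    """Base class for all telocap errors."""


class FormatError(TelocapError):
    """A file does not parse in its declared format."""


class ParameterError(TelocapError):
    """A parameter violates its documented constraints."""


class DataError(TelocapError):
    """Inputs are internally inconsistent (e.g. alignment to unknown contig)."""


class IntegrityError(TelocapError):
    """An internal invariant that must never fail did fail."""
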