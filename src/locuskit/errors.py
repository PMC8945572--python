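"""Exception hierarchy shared across locuskit modules."""


class LocusKitError(Exception):
    """Base class for all locuskit errors."""


class InputError(LocusKitError, ValueError):
    """Invalid argument supplied by the caller (empty symbol, bad name, ...)."""


class GeneNameParseError(LocusKitError, ValueError):
    """A symbol could not be parsed under the requested grammar."""


class CnvParseError(LocusKitError, ValueError):
    """A CNV definition string is malformed; carries the offending position."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class ValidationError(LocusKitError, ValueError):
    """A structural invariant is violated (duplicate orders, length mismatch, ...)."""


class MissingGeneError(LocusKitError, LookupError):
    """A referenced gene is not present in the table."""


class MissingHaplotypeError(LocusKitError, LookupError):
    """A referenced haplotype label is not present in the table."""


class FlatFileParseError(LocusKitError, ValueError):
    """A locus-unit flat-file fragment is malformed."""


class CoordinateError(LocusKitError, ValueError):
    """A position falls outside the locus frame."""
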