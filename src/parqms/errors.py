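"""Exception hierarchy for parqms.

All library errors derive from :class:`ParqmsError` so callers can catch a
single base class at CLI or pipeline boundaries.
"""


class ParqmsError(Exception):
    """Base class for all parqms errors."""


class SchemaError(ParqmsError):
    """A table or file does not have the expected long-format column set."""


class DomainError(ParqmsError, ValueError):
    """An argument is outside its mathematical/physical domain."""


class InsufficientDataError(ParqmsError, ValueError):
    """Not enough data points to perform a fit."""


class InvalidTableError(ParqmsError):
    """A table failed semantic validation.

    Carries the offending :class:`~parqms.data_model.ValidationReport` as
    the ``report`` attribute.
    """

    def __init__(self, report, message: str = "table failed validation"):
        self.report = report
        details = "; ".join(v.message for v in report.violations[:5])
        super().__init__(f"{message}: {details}")


class MzmlParseError(ParqmsError):
    """The mzML document could not be parsed."""


class IngestError(ParqmsError):
    """Spectra were parsed but could not be assembled into a valid table."""


class LevelMappingError(IngestError):
    """A spectrum could not be attributed to an MS level."""


class StorageError(ParqmsError, OSError):
    """Low-level I/O failure while writing or reading a sample."""


class MetadataMissingError(ParqmsError):
    """Neither embedded key-value metadata nor a JSON sidecar was found."""


class MetadataMismatchError(ParqmsError):
    """Embedded key-value metadata and the JSON sidecar disagree."""


class CapabilityError(ParqmsError):
    """The sample structurally lacks the queried dimension (e.g. no IMS)."""


class NotFoundError(ParqmsError, LookupError):
    """The requested scan/record does not exist in the sample."""


class ConfigurationError(ParqmsError, ValueError):
    """A simulation or CLI configuration violates its invariants."""
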