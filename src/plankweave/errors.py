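"""Exception hierarchy.

Exit-code mapping used by the CLI: :class:`InputError` subclasses exit with
code 2, :class:`ValidationFailure` with code 3.
"""


class PlankweaveError(Exception):
    """Base class for all package errors."""


class InputError(PlankweaveError):
    """Malformed or inconsistent input (CLI exit code 2)."""


class IntegrityError(InputError):
    """Conflicting taxonomic parentage or duplicate keys."""


class RankError(InputError):
    """A rank query below a taxon's own level."""


class LookupError_(InputError):
    """Unknown taxon name."""


class MappingError(InputError):
    """Unmapped species codes during survey ingest; carries the offenders."""

    def __init__(self, offenders):
        self.offenders = sorted(set(offenders))
        super().__init__(f"unmapped species codes: {', '.join(self.offenders)}")


class RowError(InputError):
    """A malformed data row; message names the file and line."""


class KeyCollisionError(InputError):
    """Two distinct samples mapped to one SampleID."""


class PlanMismatchError(InputError):
    """A catch record whose category is absent from the harmonization plan."""


class DomainError(InputError):
    """A physically impossible argument (negative conductivity, zero volume)."""


class ConfigError(InputError):
    """Invalid configuration (zero net-mouth area, bad schedule)."""


class AlignmentError(InputError):
    """Sample sets of two tables that should match do not."""


class ValidationFailure(PlankweaveError):
    """A validation check failed (CLI exit code 3)."""
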