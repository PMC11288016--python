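"""Exception hierarchy.

All input-level failures derive from :class:`CommPrimeError` so the CLI can
map them to exit status 2; anything else is an internal error (exit 1).
"""


class CommPrimeError(Exception):
    """Base class for all user-input and configuration errors."""


class CdsFilenameError(CommPrimeError):
    """CDS filename violates the naming contract (missing 'cds' or '.fna')."""


class CdsParseError(CommPrimeError):
    """Malformed FASTA entry, empty file, or illegal sequence characters."""


class DuplicateGeneError(CommPrimeError):
    """Two FASTA entries in one file share the same header token."""


class GenomeCollisionError(CommPrimeError):
    """The same genome identifier appears in both target and non-target dirs."""


class ConfigurationError(CommPrimeError):
    """Invalid run configuration (empty input dir, bad group, bad params)."""


class HitReferenceError(CommPrimeError):
    """A hit table row references a gene the catalog cannot resolve."""


class HitParseError(CommPrimeError):
    """Malformed row in an external alignment table."""


class InfeasiblePoolError(CommPrimeError):
    """Equal-copy pooling requested with a zero-concentration member."""


class UndefinedCompositionError(CommPrimeError):
    """Relative abundance requested for an all-zero count vector."""
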