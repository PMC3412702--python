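"""Named exceptions raised across the package.

Every rejected input maps to one of these rather than a bare ValueError so
callers (and the CLI) can distinguish user errors from bugs.
"""


class PrimerSpecError(Exception):
    """Base class for all package errors."""


class FastaFormatError(PrimerSpecError):
    """Malformed or empty FASTA input, or illegal sequence characters."""


class BedFormatError(PrimerSpecError):
    """Malformed BED line or invalid interval coordinates."""


class SequenceError(PrimerSpecError):
    """A sequence violates a precondition (e.g. contains N where forbidden)."""


class EmptyDatabaseError(PrimerSpecError):
    """A search database with no usable sequences."""


class InvalidScoringError(PrimerSpecError):
    """A scoring scheme without negative expected score or positive scores."""


class AllMaskedQueryError(PrimerSpecError):
    """A query consisting entirely of N after masking."""


class TemplateTooLongError(PrimerSpecError):
    """PCR template longer than the supported maximum."""


class EmptyWindowError(PrimerSpecError):
    """A realignment subject window that is empty after clipping."""


class ConfigError(PrimerSpecError):
    """Inconsistent run configuration."""
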