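"""Exception hierarchy shared across the pipeline.

Every user-facing error derives from :class:`HerbitaError` so the CLI can
map data/validation problems to a distinct exit code.
"""


class HerbitaError(Exception):
    """Base class for all package errors."""


class SchemaError(HerbitaError):
    """An input table or file is missing a required column or header."""


class RowParseError(HerbitaError):
    """A row of an input table could not be parsed; carries the row index."""

    def __init__(self, message: str, row_index: int | None = None):
        super().__init__(message)
        self.row_index = row_index


class InsufficientDataError(HerbitaError):
    """Fewer usable values than an operation requires."""


class SequenceFormatError(HerbitaError):
    """Malformed FASTA input, bad alphabet, or duplicate accessions."""


class AnnotationError(HerbitaError):
    """ITS annotation missing, invalid, or not transferable to a target."""

    def __init__(self, message: str, region: str | None = None):
        super().__init__(message)
        self.region = region


class DistanceError(HerbitaError):
    """A pairwise distance is undefined (no comparable sites, or the
    Jukes-Cantor transform is out of domain)."""


class ConfigError(HerbitaError):
    """Invalid simulation or pipeline configuration."""
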