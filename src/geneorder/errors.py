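"""Exception types raised across the pipeline."""


class GeneOrderError(Exception):
    """Base class for all pipeline errors."""


class ParseError(GeneOrderError):
    """An input file could not be parsed into the data model."""


class InvalidRecordError(GeneOrderError):
    """A record violates a data-model invariant (bad coordinates, strand, ...)."""


class MissingDataError(GeneOrderError):
    """A required field or input is absent (e.g. protein length before dedup)."""
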