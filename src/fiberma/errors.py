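"""Exception hierarchy for the fiberma pipeline."""


class FibermaError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(FibermaError):
    """Invalid or inconsistent configuration."""


class InputError(FibermaError):
    """Malformed or out-of-range input data."""


class FastqParseError(InputError):
    """Malformed FASTQ record; carries the 0-based record index."""

    def __init__(self, message: str, record_index: int | None = None):
        super().__init__(message)
        self.record_index = record_index


class AlphabetError(InputError):
    """Sequence contains characters outside the nucleotide alphabet."""


class EmptyInputError(InputError):
    """An operation that requires data received none."""


class SizingError(ConfigurationError):
    """Requested simulation does not fit in the configured genome."""


class CoordinateError(InputError):
    """Coordinates fall outside the sequence they refer to."""


class NormalizationError(FibermaError):
    """Library-size normalization is impossible (zero total)."""


class ClusteringError(FibermaError):
    """Clustering preconditions violated (e.g. fewer rows than clusters)."""


class PairingError(InputError):
    """qPCR table lacks reference-gene measurements needed for pairing."""


class UndefinedCorrelationError(FibermaError):
    """Correlation undefined (zero-variance profile)."""


class DependencyError(FibermaError):
    """A pipeline stage is missing the outputs of an upstream stage."""


class ReferenceFormatError(InputError):
    """Reference FASTA violates format expectations (e.g. duplicate IDs)."""
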