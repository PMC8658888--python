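"""Exception hierarchy shared across the package."""


class CrnnQsarError(Exception):
    """Base class for package errors."""


class ConfigurationError(CrnnQsarError):
    """Invalid configuration: missing columns, bad group sets, scheme mismatch."""


class EmptyDatasetError(CrnnQsarError):
    """No usable rows remain after validation."""


class InvalidSmilesError(CrnnQsarError):
    """A SMILES string could not be parsed."""


class FormatError(CrnnQsarError):
    """Malformed on-disk data (ragged matrix, non-numeric labels, ...)."""


class DataError(CrnnQsarError):
    """Degenerate data: single-class labels, zero label variance, ..."""


class MetricUndefinedError(DataError):
    """Requested metric is undefined for the given labels."""


class ArchitectureError(CrnnQsarError):
    """Layer arithmetic fails for the given configuration (input too short)."""


class MissingEmbeddingError(CrnnQsarError):
    """A molecule is absent from an external embedding matrix."""
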