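"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`PlantDtiError`
so callers can catch one type at the CLI boundary.
"""


class PlantDtiError(Exception):
    """Base class for all errors raised by plantdti."""


class ParseError(PlantDtiError):
    """A file could not be parsed (message names the offending line)."""


class SchemaError(PlantDtiError):
    """A tabular input is missing required columns."""


class AlphabetError(PlantDtiError):
    """A sequence contains characters outside its allowed alphabet."""


class CappedExpansionError(PlantDtiError):
    """IUPAC expansion would exceed the configured cap.

    Attributes
    ----------
    cardinality : int
        The full expansion size that triggered the error.
    """

    def __init__(self, message: str, cardinality: int):
        super().__init__(message)
        self.cardinality = cardinality


class NoDataError(PlantDtiError):
    """An operation received an empty input it cannot act on."""


class InvariantError(PlantDtiError):
    """A domain-type invariant was violated (e.g. mixed lengths, start >= end)."""


class GenerationError(PlantDtiError):
    """Negative-set generation is impossible (e.g. fewer than two distinct TFBSs)."""


class StratificationError(PlantDtiError):
    """A train/test stratum is too small to split."""


class TrainingError(PlantDtiError):
    """A classifier cannot be fitted (e.g. a single-class training set)."""


class KeyMismatchError(PlantDtiError):
    """A record's length or DBD type does not match the model/profile keys."""


class ConfigurationError(PlantDtiError):
    """An invalid configuration (overlapping spikes, missing models, bad ratio)."""
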