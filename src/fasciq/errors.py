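"""Exception hierarchy for the pipeline."""


class FasciqError(Exception):
    """Base class for all package errors."""


class FormatError(FasciqError):
    """File could not be parsed in any supported format."""


class MetadataError(FasciqError):
    """Required acquisition metadata (e.g. sampling rate) is missing."""


class DataError(FasciqError):
    """Signal content is invalid (NaN/inf samples, empty signal, ...)."""


class ConfigurationError(FasciqError):
    """Configuration values are inconsistent with the data or each other."""


class UnanalysableRecordingError(FasciqError):
    """Quality control rejected every channel; nothing left to analyse."""
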