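"""Exception hierarchy shared across the pipeline stages."""


class ActidiaryError(Exception):
    """Base class for all package errors."""


class ConfigError(ActidiaryError):
    """Invalid configuration (CLI exit code 2)."""


class DataError(ActidiaryError):
    """Malformed or inconsistent input data (CLI exit code 3)."""


class EmptyCohortError(ActidiaryError):
    """All participants were excluded by the QC rules (CLI exit code 4)."""


class NyquistError(DataError):
    """Sampling rate too low for the requested low-pass cutoff."""
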