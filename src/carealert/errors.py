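"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3.
"""


class CareAlertError(Exception):
    """Base class for all package errors."""


class ConfigError(CareAlertError):
    """Invalid configuration (bad parameter value, inconsistent options)."""


class DataError(CareAlertError):
    """Malformed or internally inconsistent input data."""


class ResourceError(CareAlertError):
    """A computation was refused because it would be too expensive
    (e.g. exact enumeration beyond the supported sample size)."""
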