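"""Exception hierarchy for the dopafilm pipeline.

Each stage raises a distinct class so the CLI can map failures to exit
messages without string matching.
"""


class DopafilmError(Exception):
    """Base class for all package errors."""


class ConfigError(DopafilmError):
    """Invalid simulation or analysis configuration."""


class DataError(DopafilmError):
    """Input data violates a precondition (non-finite, empty, wrong shape)."""


class SiteBoundsError(ConfigError):
    """A release site or event falls outside the simulated grid."""


class FitError(DopafilmError):
    """A model fit failed or is degenerate."""
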