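"""Exception hierarchy.

Config/input problems and statistical hard errors are distinguished so the
CLI can map them to different exit codes.
"""


class MrkitError(Exception):
    """Base class for all package errors."""


class ConfigError(MrkitError):
    """Invalid configuration, missing file, or malformed input table."""


class NoInstrumentsError(MrkitError):
    """No instruments survive selection, even at the relaxed threshold."""


class HarmonizationError(MrkitError):
    """Exposure and outcome datasets cannot be aligned."""


class InsufficientSnpsError(MrkitError):
    """An estimator or diagnostic was given fewer SNPs than it requires."""
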