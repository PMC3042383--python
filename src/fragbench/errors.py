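"""Exception hierarchy.

All fragbench errors derive from :class:`FragbenchError` so callers can
catch the package's failures with a single except clause.
"""


class FragbenchError(Exception):
    """Base class for all fragbench errors."""


class ConfigurationError(FragbenchError):
    """A simulation or pipeline configuration is invalid or degenerate."""


class FormatError(FragbenchError):
    """An on-disk file violates its format contract (bounds, conventions)."""


class PoolShortfallError(FragbenchError):
    """A candidate pool is too small for without-replacement sampling."""


class TrainingError(FragbenchError):
    """A model cannot be trained from the provided data."""
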