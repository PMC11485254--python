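"""Exception hierarchy shared across the package.

Exit-code mapping in the CLI: DataError -> 1, ConfigError -> 2.
"""


class GdmtTrialError(Exception):
    """Base class for all package errors."""


class ConfigError(GdmtTrialError):
    """Invalid configuration: unknown drug, bad probability, missing path."""


class DataError(GdmtTrialError):
    """Schema or invariant violation in an input dataset."""


class UnscreenedError(GdmtTrialError):
    """Iron-deficiency status requested but the labs needed to decide are absent.

    Deliberately distinct from ``False``: an unscreened patient is not
    known to be iron-replete.
    """


class EstimationError(GdmtTrialError):
    """A statistical estimate is degenerate (no events, zero margin, monotone likelihood)."""
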