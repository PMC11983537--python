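"""Exception hierarchy for the MR pipeline.

Every error raised by this package derives from :class:`MRError`, so callers
(and the CLI) can distinguish pipeline failures from programming errors.
"""

from __future__ import annotations


class MRError(Exception):
    """Base class for all errors raised by mrmediation."""


class ConfigError(MRError):
    """A configuration value (threshold, column mapping, run config) is invalid."""


class InputError(MRError):
    """An input table is empty, unreadable, or contains no usable records."""


class UsageError(MRError):
    """An operation was called with arguments that violate its contract."""


class DegenerateInputError(MRError):
    """A numerically degenerate input (eaf of 0/1, n <= k+1, zero exposure beta)."""


class EmptyInstrumentError(MRError):
    """No instruments survive selection.  Carries the per-filter removal counts."""

    def __init__(self, message: str, filter_log: dict | None = None):
        super().__init__(message)
        self.filter_log = dict(filter_log or {})


class InsufficientInstrumentsError(MRError):
    """Fewer instruments than the estimator's minimum."""


class CollinearityError(MRError):
    """Exposure-effect columns are rank deficient."""


class BootstrapInstabilityError(MRError):
    """Too many bootstrap draws rejected by the denominator guard."""
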