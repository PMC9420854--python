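"""Exception hierarchy.

Every stage of the pipeline raises a distinct subclass of
:class:`ThyrocvError` so the command-line driver can map failures to
stage-labelled messages and exit codes (2 for validation problems, 3 for
computation problems).
"""


class ThyrocvError(Exception):
    """Base class for all package errors."""

    exit_code = 3


class SchemaError(ThyrocvError):
    """Malformed input table or record (missing column, invariant violation)."""

    exit_code = 2


class UsageError(ThyrocvError):
    """A function was called with arguments that make no sense (e.g. empty input)."""

    exit_code = 2


class ConfigError(ThyrocvError):
    """Invalid pipeline configuration."""

    exit_code = 2


class HarmonizationError(ThyrocvError):
    """A hazard-ratio rescaling produced a non-positive value, i.e. the
    linear approximation behind the conversion equations is inapplicable
    to the record at hand."""


class PoolingError(ThyrocvError):
    """Meta-analysis cannot proceed (fewer than two studies, duplicated
    study in one analysis set, degenerate weights)."""


class FunnelRuleError(ThyrocvError):
    """Funnel diagnostics refused: fewer than five studies in the set."""


class EstimationError(ThyrocvError):
    """Rate-ratio estimation impossible (e.g. zero events in a tertile)."""


class DomainError(ThyrocvError):
    """Physically meaningless argument (e.g. negative refractory period)."""
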