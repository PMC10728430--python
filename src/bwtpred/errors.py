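"""Exception hierarchy for the bwtpred pipeline."""


class BwtPredError(Exception):
    """Base class for all bwtpred errors."""


class FormatError(BwtPredError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(BwtPredError):
    """Parsed content violates a domain invariant (bounds, enums, uniqueness)."""


class FixtureIntegrityError(BwtPredError):
    """A packaged fixture fails its integrity check (row count, columns)."""


class EmptyRegionError(BwtPredError):
    """No probes fall inside the requested genomic region for a sample."""


class InsufficientControlsError(BwtPredError):
    """Fewer than two control samples; an SD cannot be estimated."""


class MissingInputError(BwtPredError):
    """A required input value is absent (e.g. missing beta value)."""


class DegenerateTableError(BwtPredError):
    """A contingency table has too few populated rows/columns to test."""


class UndefinedCorrelationError(BwtPredError):
    """Correlation is undefined because an input vector is constant."""


class ConfigError(BwtPredError):
    """An invalid configuration value (e.g. mode mixture not summing to 1)."""
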