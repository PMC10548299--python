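"""Exception hierarchy for opometrics.

Every failure mode has a dedicated class so callers (and the CLI exit-code
mapping) can distinguish configuration problems, malformed input tables, and
computation-time errors.
"""


class OpoMetricsError(Exception):
    """Base class for all opometrics errors."""


class ConfigurationError(OpoMetricsError):
    """Invalid scenario or run configuration (bad probabilities, sizes, years)."""


class SchemaError(OpoMetricsError):
    """An input table is missing required columns or has the wrong layout."""


class ValidationError(OpoMetricsError):
    """Rows violate table invariants (duplicate keys, negative counts, ...)."""


class ResolutionError(OpoMetricsError):
    """A record's county could not be resolved to an OPO or ADI quintile."""

    def __init__(self, message: str, county_id=None):
        super().__init__(message)
        self.county_id = county_id


class ComputationError(OpoMetricsError):
    """A metric is undefined for the given inputs (e.g. zero national potential)."""


class ThresholdError(OpoMetricsError):
    """Thresholds cannot be computed (fewer than two defined rates)."""


class AssignmentError(OpoMetricsError):
    """Tier assignment is impossible (missing prior-year thresholds)."""


class ComparisonError(OpoMetricsError):
    """Reclassification comparison over mismatched OPO sets or years."""
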