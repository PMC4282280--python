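"""Exception hierarchy for the vulnerability pipeline."""


class HerdvulnError(Exception):
    """Base class for all package errors."""


class SchemaError(HerdvulnError):
    """A mandatory metadata column is missing or malformed."""


class ConfigError(HerdvulnError):
    """The category or run configuration is inconsistent with the data."""


class ParseError(HerdvulnError):
    """A cell could not be parsed as the expected type."""


class ZeroRangeError(HerdvulnError):
    """Min-max scaling was asked for a vector with no spread."""


class UndefinedRatioError(HerdvulnError):
    """Self-sufficiency ratio denominator is non-positive."""


class ReductionError(HerdvulnError):
    """No within-category correlation could be computed."""


class CoefficientMissingError(HerdvulnError):
    """A species has no livestock-unit coefficient."""
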