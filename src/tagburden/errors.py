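"""Exception hierarchy for tag-burden calculations."""


class TagBurdenError(Exception):
    """Base class for all package errors."""


class InvalidInputError(TagBurdenError, ValueError):
    """A physical quantity violates its domain (e.g. non-positive viscosity)."""


class ConfigurationError(TagBurdenError, ValueError):
    """A required configuration field is missing or malformed."""


class RangeError(TagBurdenError, ValueError):
    """A lookup falls outside the coefficient table's speed or size coverage."""


class BudgetError(TagBurdenError, ValueError):
    """An activity budget's time fractions are inconsistent."""


class UndefinedRatioError(TagBurdenError, ZeroDivisionError):
    """A relative metric is requested against a zero baseline."""


class FitError(TagBurdenError, RuntimeError):
    """A surrogate fit cannot be performed (degenerate or underdetermined data)."""
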