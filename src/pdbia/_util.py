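"""Small shared helpers: display rounding and error types."""

import math


class PortfolioError(Exception):
    """Base class for portfolio validation and configuration problems.

    Deliberately not a ValueError: cross-field checks inside model
    validators must surface with their own type instead of being
    swallowed into a generic validation error.
    """


class SchemaError(PortfolioError):
    """A required row/stage/column is missing or malformed."""


class ConfigurationError(PortfolioError):
    """An option value is unknown or inconsistent with the model setup."""


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero.

    This is the display rule used throughout: 47913.75 -> 47914,
    453.6 -> 454, 172350.45 -> 172350.  Python's built-in banker's
    rounding would disagree on exact .5 ties.
    """
    if not math.isfinite(x):
        raise ValueError(f"cannot display-round non-finite value {x!r}")
    return int(math.copysign(math.floor(abs(x) + 0.5), x)) if x else 0
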