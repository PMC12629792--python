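"""Shared helpers: errors, rounding, logging."""

from __future__ import annotations

import logging
import math

logger = logging.getLogger("pdackit")


class PdackitError(Exception):
    """Base class for package errors."""


class SchemaError(PdackitError):
    """An input table violates its column/key contract."""


class BaselineError(PdackitError):
    """A per-patient series lacks a usable baseline measurement."""


class InsufficientDataError(PdackitError):
    """Too few observations for the requested computation."""


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round with halves going away from zero (reporting convention).

    Python's builtin ``round`` uses banker's rounding; clinical tables
    conventionally round 0.05 up, so percentages are reported with this
    helper.
    """
    if math.isnan(x):
        return x
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)
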