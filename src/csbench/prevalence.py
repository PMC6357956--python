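"""Prevalence estimates and display rounding.

The central quantity throughout the package is the *specific caesarean
prevalence*:

    specific prevalence = caesareans for one indication / all deliveries

with the denominator being every delivery in the catchment population (home
births included), never only facility deliveries or only caesareans.
Internal arithmetic is carried at full floating-point precision; rounding is
applied only at display time, half-up at the requested number of decimals,
because published tables round each cell independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .errors import ValidationError


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round ``x`` to ``decimals`` places with ties going away from zero."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent_display(proportion: float, decimals: int = 0) -> str:
    """Format a proportion as a percentage string, half-up rounded.

    >>> percent_display(178 / 24157)
    '1%'
    >>> percent_display(2900 / 30259, decimals=1)
    '9.6%'
    """
    value = round_half_up(proportion * 100.0, decimals)
    return f"{value:.{decimals}f}%"


@dataclass(frozen=True)
class PrevalenceEstimate:
    """A proportion together with the counts it came from."""

    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ValidationError("prevalence denominator must be positive")
        if not 0 <= self.numerator <= self.denominator:
            raise ValidationError(
                f"numerator {self.numerator} outside [0, {self.denominator}]"
            )

    @property
    def proportion(self) -> float:
        return self.numerator / self.denominator

    def display(self, decimals: int = 0) -> str:
        return percent_display(self.proportion, decimals)

    def __str__(self) -> str:  # pragma: no cover - convenience only
        return f"{self.numerator}/{self.denominator} ({self.display(1)})"
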