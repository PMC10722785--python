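"""Currency-amount ranges and the rounding convention used throughout.

All published benchmark values are whole currency units; every conversion
step rounds half away from zero, which is what reproduces the source
tables' cells (banker's rounding does not).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero."""
    if x >= 0:
        return int(math.floor(x + 0.5))
    return -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class MoneyRange:
    """A (lower, upper) currency-amount pair; point values have lower == upper."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(f"range lower {self.lower} exceeds upper {self.upper}")

    @classmethod
    def point(cls, value: float) -> "MoneyRange":
        return cls(value, value)

    @property
    def is_point(self) -> bool:
        return self.lower == self.upper

    def map(self, fn: Callable[[float], float]) -> "MoneyRange":
        """Apply ``fn`` elementwise; endpoints are reordered if ``fn`` reverses them."""
        a, b = fn(self.lower), fn(self.upper)
        return MoneyRange(min(a, b), max(a, b))

    def rounded(self) -> "MoneyRange":
        return MoneyRange(round_half_away(self.lower), round_half_away(self.upper))

    def endpoints(self) -> tuple[float, ...]:
        """Distinct endpoints: one for a point value, two for a genuine range."""
        if self.is_point:
            return (self.lower,)
        return (self.lower, self.upper)

    def __str__(self) -> str:  # en dash, as the source tables print ranges
        if self.is_point:
            return f"{self.lower:,.0f}"
        return f"{self.lower:,.0f}–{self.upper:,.0f}"


def parse_range(text: str) -> MoneyRange:
    """Parse ``"x"`` or ``"x-y"`` / ``"x–y"`` (hyphen or en dash) into a range.

    Thousands separators are tolerated.
    """
    cleaned = text.strip().replace(",", "").replace("–", "-")
    # a leading minus would be invalid anyway (values are strictly positive)
    parts = [p for p in cleaned.split("-") if p]
    try:
        if len(parts) == 1:
            return MoneyRange.point(float(parts[0]))
        if len(parts) == 2:
            return MoneyRange(float(parts[0]), float(parts[1]))
    except ValueError as exc:
        raise ValueError(f"malformed currency amount {text!r}") from exc
    raise ValueError(f"malformed currency range {text!r}")
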