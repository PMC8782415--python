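"""Decimal-exact rounding policies.

The printed tables this package replicates were produced with stage-specific
decimal rounding (truncation in some stages, round-half-up in others).
Binary floating point cannot replicate decimal truncation reliably
(``0.572*2.288`` then ``sqrt`` may land a hair below ``1.144``), so every
policy application routes through :mod:`decimal` via the shortest-repr
string of the value.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

__all__ = ["RoundingPolicy", "NO_ROUNDING", "as_decimal"]

_MODES = ("half-up", "truncate", "none")


def as_decimal(x) -> Decimal:
    """Exact decimal image of ``x`` (shortest-repr for floats)."""
    if isinstance(x, Decimal):
        return x
    if isinstance(x, int):
        return Decimal(x)
    return Decimal(repr(float(x)))


@dataclass(frozen=True)
class RoundingPolicy:
    """Uniform rounding applied within one pipeline stage.

    decimals: digits kept after the decimal point.
    mode: ``half-up`` (commercial rounding), ``truncate`` (toward zero),
        or ``none`` (identity; ``decimals`` ignored).
    """

    decimals: int = 3
    mode: str = "half-up"

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown rounding mode {self.mode!r}; expected one of {_MODES}")
        if self.decimals < 0:
            raise ValueError("decimals must be non-negative")

    @property
    def quantum(self) -> Decimal:
        return Decimal(1).scaleb(-self.decimals)

    def apply_decimal(self, x) -> Decimal:
        d = as_decimal(x)
        if self.mode == "none":
            return d
        rounding = ROUND_HALF_UP if self.mode == "half-up" else ROUND_DOWN
        return d.quantize(self.quantum, rounding=rounding)

    def apply(self, x) -> float:
        return float(self.apply_decimal(x))

    def apply_map(self, values: Mapping[str, float]) -> dict[str, float]:
        return {k: self.apply(v) for k, v in values.items()}

    def apply_seq(self, values: Iterable[float]) -> list[float]:
        return [self.apply(v) for v in values]

    def describe(self) -> str:
        if self.mode == "none":
            return "none"
        return f"{self.mode}:{self.decimals}dp"


NO_ROUNDING = RoundingPolicy(decimals=0, mode="none")
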