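"""Hyperparameter search spaces encoded as real vectors on the unit box.

Population optimizers in :mod:`histotune.optimizers` work on ``[0, 1]^d``;
:class:`SearchSpace` maps unit-box vectors to physical hyperparameter
records (continuous, integer or categorical, on linear or log scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

__all__ = ["HyperparamSpec", "SearchSpace"]

_KINDS = ("continuous", "integer", "categorical")
_SCALES = ("linear", "log")


@dataclass(frozen=True)
class HyperparamSpec:
    """One dimension of a search space.

    Parameters
    ----------
    name:
        Unique identifier of the hyperparameter.
    kind:
        ``"continuous"``, ``"integer"`` or ``"categorical"``.
    low, high:
        Inclusive physical range for continuous/integer kinds.
    choices:
        Ordered options for the categorical kind.
    scale:
        ``"linear"`` or ``"log"``; log requires a strictly positive range.
    """

    name: str
    kind: str
    low: float | None = None
    high: float | None = None
    choices: Sequence[Any] | None = None
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown kind {self.kind!r}; expected one of {_KINDS}")
        if self.scale not in _SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {_SCALES}")
        if self.kind == "categorical":
            if not self.choices:
                raise ValueError(f"{self.name}: categorical spec needs non-empty choices")
        else:
            if self.low is None or self.high is None:
                raise ValueError(f"{self.name}: {self.kind} spec needs low/high bounds")
            if not self.low < self.high:
                raise ValueError(f"{self.name}: low must be < high")
            if self.scale == "log" and self.low <= 0:
                raise ValueError(f"{self.name}: log scale requires a strictly positive range")

    def decode(self, u: float) -> Any:
        """Map a unit-interval coordinate to the physical value."""
        u = min(max(float(u), 0.0), 1.0)
        if self.kind == "categorical":
            # equal-width bins over [0, 1]; u == 1 falls in the last bin
            idx = min(int(u * len(self.choices)), len(self.choices) - 1)
            return self.choices[idx]
        if self.scale == "log":
            value = 10.0 ** (math.log10(self.low) + u * (math.log10(self.high) - math.log10(self.low)))
        else:
            value = self.low + u * (self.high - self.low)
        if self.kind == "integer":
            # round half away from zero
            return int(math.floor(value + 0.5)) if value >= 0 else -int(math.floor(-value + 0.5))
        return value

    def encode(self, value: Any) -> float:
        """Map a physical value back to a unit-interval coordinate."""
        if self.kind == "categorical":
            idx = list(self.choices).index(value)
            # bin centre
            return (idx + 0.5) / len(self.choices)
        v = float(value)
        if self.scale == "log":
            u = (math.log10(v) - math.log10(self.low)) / (math.log10(self.high) - math.log10(self.low))
        else:
            u = (v - self.low) / (self.high - self.low)
        return min(max(u, 0.0), 1.0)


@dataclass
class SearchSpace:
    """Ordered collection of :class:`HyperparamSpec`; dimension ``d = len(specs)``."""

    specs: list[HyperparamSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ValueError("hyperparameter names must be unique")

    @property
    def dimension(self) -> int:
        return len(self.specs)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def decode(self, vector: Sequence[float]) -> dict[str, Any]:
        """Decode a unit-box vector into a ``{name: value}`` record.

        Out-of-box coordinates are clipped to ``[0, 1]`` before decoding.
        """
        if len(vector) != self.dimension:
            raise ValueError(f"vector length {len(vector)} != dimension {self.dimension}")
        return {s.name: s.decode(u) for s, u in zip(self.specs, vector)}

    def encode(self, record: dict[str, Any]) -> list[float]:
        """Encode a hyperparameter record into a unit-box vector."""
        return [s.encode(record[s.name]) for s in self.specs]
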