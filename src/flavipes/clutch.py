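"""Clutch configurations and the clutch-size → fertility mapping.

Gregarious egg parasitoids such as *Anaphes flavipes* lay 1–7 offspring
into a single host egg, in any sex ratio.  Because the host egg is a
fixed food supply (the wasp is an idiobiont), per-offspring body size —
and hence the lifetime fertility of each emerging female — declines with
clutch size.  This module holds the two primitives everything else is
built on: enumeration of the possible (clutch size, female count)
configurations, and the empirical fertility mapping

    fertility(c) = round(base − sqrt(c)),   base = 20 by default,

which gives the expected lifetime offspring count of a female that
developed in a clutch of size ``c``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

__all__ = [
    "ClutchConfig",
    "FertilityModel",
    "fertility_of_clutch",
    "enumerate_clutch_configs",
]

logger = logging.getLogger("flavipes")

DEFAULT_MAX_CLUTCH = 7

#: decay forms understood by :class:`FertilityModel`
_DECAY_FORMS = {
    "sqrt": math.sqrt,
    "linear": lambda c: float(c),
    "none": lambda c: 0.0,
}

_ROUNDING_RULES = ("nearest", "floor", "ceil", "none")


def _round_half_away(x: float) -> float:
    """Round to nearest integer, ties away from zero.

    ``round()`` uses banker's rounding; the convention here is fixed so
    that a configurable model (where a .5 can arise) stays deterministic.
    """
    return math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5)


@dataclass(frozen=True, order=True)
class ClutchConfig:
    """One host egg's brood: total offspring and how many are female."""

    size: int
    females: int

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError(f"clutch size must be >= 1, got {self.size}")
        if not 0 <= self.females <= self.size:
            raise ValueError(
                f"females must be in [0, size={self.size}], got {self.females}"
            )

    @property
    def males(self) -> int:
        return self.size - self.females


@dataclass(frozen=True)
class FertilityModel:
    """Mapping from natal clutch size to a female's lifetime fertility.

    Parameters
    ----------
    base
        Fertility of a hypothetical female developing with no
        competition; default 20 offspring.
    decay
        Functional form of the decline: ``"sqrt"`` (default),
        ``"linear"`` or ``"none"``.
    rounding
        ``"nearest"`` (default; ties away from zero), ``"floor"``,
        ``"ceil"`` or ``"none"`` (return the raw float).
    max_clutch
        Largest clutch size the model is defined on; default 7, the
        biological maximum observed for *A. flavipes*.
    """

    base: float = 20.0
    decay: str = "sqrt"
    rounding: str = "nearest"
    max_clutch: int = DEFAULT_MAX_CLUTCH

    def __post_init__(self) -> None:
        if self.decay not in _DECAY_FORMS:
            raise ValueError(
                f"unknown decay form {self.decay!r}; choose from {sorted(_DECAY_FORMS)}"
            )
        if self.rounding not in _ROUNDING_RULES:
            raise ValueError(
                f"unknown rounding rule {self.rounding!r}; choose from {_ROUNDING_RULES}"
            )
        if self.max_clutch < 1:
            raise ValueError("max_clutch must be >= 1")
        if self.max_clutch > DEFAULT_MAX_CLUTCH:
            logger.warning(
                "max_clutch=%d extrapolates beyond the observed support 1..%d",
                self.max_clutch,
                DEFAULT_MAX_CLUTCH,
            )

    def fertility(self, size: int) -> float:
        """Lifetime fertility of one female from a clutch of ``size``."""
        if not 1 <= size <= self.max_clutch:
            raise ValueError(
                f"clutch size {size} outside valid support 1..{self.max_clutch}"
            )
        raw = self.base - _DECAY_FORMS[self.decay](size)
        if self.rounding == "nearest":
            return float(_round_half_away(raw))
        if self.rounding == "floor":
            return float(math.floor(raw))
        if self.rounding == "ceil":
            return float(math.ceil(raw))
        return raw

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "base": self.base,
            "decay": self.decay,
            "rounding": self.rounding,
            "max_clutch": self.max_clutch,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FertilityModel":
        known = {"base", "decay", "rounding", "max_clutch"}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown FertilityModel keys: {sorted(extra)}")
        return cls(**{k: d[k] for k in known & set(d)})


def fertility_of_clutch(size: int, model: FertilityModel | None = None) -> int:
    """Per-female lifetime fertility for a clutch of ``size`` offspring.

    With the default model this is ``round(20 - sqrt(size))``: 19 for a
    singleton clutch down to 17 for the maximum clutch of 7.
    """
    model = model if model is not None else FertilityModel()
    return int(model.fertility(size))


def enumerate_clutch_configs(max_clutch: int = DEFAULT_MAX_CLUTCH) -> list[ClutchConfig]:
    """All (size, females) configurations with 1 <= size <= ``max_clutch``.

    A clutch of size ``c`` admits ``c + 1`` female counts (0..c), so the
    total is ``max_clutch * (max_clutch + 3) / 2`` — 35 for the
    biological maximum of 7.
    """
    if max_clutch < 1:
        raise ValueError(f"max_clutch must be >= 1, got {max_clutch}")
    return [
        ClutchConfig(size=c, females=f)
        for c in range(1, max_clutch + 1)
        for f in range(c + 1)
    ]
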