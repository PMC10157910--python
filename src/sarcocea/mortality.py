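"""Age-dependent background mortality and hazard-scale risk adjustment.

Background mortality enters the model as an annual life table (age ->
probability of death within the year).  When no national table is supplied
the package synthesises one from a Gompertz hazard anchored at the age-60
annual death probability: the hazard doubles roughly every ``ln 2 / slope``
years, the canonical pattern of adult human mortality.

Excess mortality (the sarcopenia hazard ratio, the first-year fracture
relative risk) is applied on the hazard scale,
``q' = 1 - (1 - q)^m``, which keeps probabilities in [0, 1] at any age and
multiplier, unlike direct probability multiplication.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "LifeTableError",
    "gompertz_life_table",
    "read_life_table",
    "write_life_table",
    "adjusted_death_prob",
]


class LifeTableError(ValueError):
    """Raised for malformed life tables."""


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities ``qx`` for contiguous ages starting at
    ``start_age``; the final age is a forced terminal death (qx = 1)."""

    start_age: int
    qx: np.ndarray

    def __post_init__(self) -> None:
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "qx", qx)
        if qx.ndim != 1 or qx.size == 0:
            raise LifeTableError("qx must be a non-empty 1-D sequence")
        if np.any((qx < 0) | (qx > 1)):
            raise LifeTableError("every qx must lie in [0, 1]")
        if qx[-1] != 1.0:
            raise LifeTableError("qx at max_age must be 1 (terminal death)")

    @property
    def max_age(self) -> int:
        return self.start_age + len(self.qx) - 1

    def q(self, age: int) -> float:
        """Annual death probability at integer ``age``."""
        idx = age - self.start_age
        if not 0 <= idx < len(self.qx):
            raise LifeTableError(
                f"age {age} outside life table [{self.start_age}, {self.max_age}]"
            )
        return float(self.qx[idx])

    def q_slice(self, start_age: int) -> np.ndarray:
        """qx from ``start_age`` through max_age (used by the cohort engine)."""
        idx = start_age - self.start_age
        if not 0 <= idx < len(self.qx):
            raise LifeTableError(
                f"age {start_age} outside life table "
                f"[{self.start_age}, {self.max_age}]"
            )
        return self.qx[idx:]


def gompertz_life_table(
    q_anchor: float = 0.0095,
    anchor_age: int = 60,
    slope: float = 0.085,
    max_age: int = 110,
) -> LifeTable:
    """Synthesise an annual life table from a Gompertz hazard.

    The hazard at the anchor age reproduces the anchor probability exactly:
    ``h(a) = -ln(1 - q_anchor) * exp(slope * (a - anchor_age))`` and
    ``qx(a) = 1 - exp(-h(a))``.  ``slope = 0`` gives a flat hazard (constant
    qx), useful for closed-form checks.  The table runs from ``anchor_age``
    to ``max_age`` with death forced at ``max_age``.
    """
    if not 0.0 < q_anchor < 1.0:
        raise LifeTableError(f"q_anchor must be in (0, 1), got {q_anchor}")
    if slope < 0:
        raise LifeTableError(f"slope must be non-negative, got {slope}")
    if max_age <= anchor_age:
        raise LifeTableError("max_age must exceed anchor_age")
    ages = np.arange(anchor_age, max_age + 1)
    h0 = -math.log1p(-q_anchor)
    hazard = h0 * np.exp(slope * (ages - anchor_age))
    qx = -np.expm1(-hazard)
    qx = np.minimum(qx, 1.0)
    qx[-1] = 1.0
    return LifeTable(start_age=anchor_age, qx=qx)


def read_life_table(path) -> LifeTable:
    """Read a two-column CSV ``age,qx`` (header optional, 1-year ages)."""
    first = pd.read_csv(path, nrows=1, header=None)
    header = 0
    try:
        float(first.iloc[0, 0])
        header = None
    except (TypeError, ValueError):
        pass
    df = pd.read_csv(path, header=header)
    if df.shape[1] != 2:
        raise LifeTableError(f"expected 2 columns (age, qx), got {df.shape[1]}")
    try:
        ages = df.iloc[:, 0].astype(float).to_numpy()
        qx = df.iloc[:, 1].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise LifeTableError(f"non-numeric life-table entries: {exc}") from exc
    if np.any(ages != np.round(ages)):
        raise LifeTableError("ages must be integers")
    order = np.argsort(ages)
    ages, qx = ages[order].astype(int), qx[order]
    if np.any(np.diff(ages) != 1):
        raise LifeTableError("ages must be contiguous (1-year abridgment)")
    return LifeTable(start_age=int(ages[0]), qx=qx)


def write_life_table(table: LifeTable, path) -> None:
    ages = np.arange(table.start_age, table.max_age + 1)
    pd.DataFrame({"age": ages, "qx": table.qx}).to_csv(path, index=False)


def adjusted_death_prob(q: float, hazard_multiplier: float) -> float:
    """Apply a hazard ratio / relative risk to an annual death probability
    on the hazard scale: ``1 - (1 - q)^m``."""
    if not 0.0 <= q < 1.0:
        raise ValueError(f"q must be in [0, 1), got {q}")
    if hazard_multiplier <= 0:
        raise ValueError(f"multiplier must be positive, got {hazard_multiplier}")
    return -math.expm1(hazard_multiplier * math.log1p(-q))
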