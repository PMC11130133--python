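"""Behavioral indices for the hemiparkinsonian mouse design.

* Cylinder test: percent use of the (lesion-affected) left forelimb,
  100 * (left + bilateral/2) / (left + bilateral + right).
* Pole test: descent time in seconds, collected into a long-format table.
* Apomorphine rotation test: a unilateral lesion is considered successful
  when the animal turns more than 120 times in 30 minutes; the model success
  rate is the percentage of animals passing.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CylinderTrial",
    "RotationTrial",
    "cylinder_score",
    "rotation_pass",
    "success_rate",
    "pole_table",
]


@dataclass(frozen=True)
class CylinderTrial:
    left_touches: int
    right_touches: int
    bilateral_touches: int
    duration_s: float = 180.0

    def __post_init__(self) -> None:
        if min(self.left_touches, self.right_touches, self.bilateral_touches) < 0:
            raise ValueError("touch counts must be >= 0")


@dataclass(frozen=True)
class RotationTrial:
    net_rotations: int
    threshold: int = 120

    def __post_init__(self) -> None:
        if self.net_rotations < 0 or self.threshold < 0:
            raise ValueError("counts must be >= 0")


def cylinder_score(trial: CylinderTrial) -> float:
    """Percent left-forelimb use; bilateral touches count half in the
    numerator and fully in the denominator.  Undefined with no touches."""
    total = trial.left_touches + trial.bilateral_touches + trial.right_touches
    if total == 0:
        raise ValueError("cylinder score undefined with zero touches")
    return 100.0 * (trial.left_touches + trial.bilateral_touches / 2.0) / total


def rotation_pass(trial: RotationTrial) -> bool:
    """Lesion-success criterion: strictly more than ``threshold`` rotations
    (default 120) in the 30-min test."""
    return trial.net_rotations > trial.threshold


def success_rate(passes: Sequence[bool]) -> float:
    """Percent of animals passing the rotation criterion, rounded
    half-away-from-zero to two decimals."""
    passes = list(passes)
    if not passes:
        raise ValueError("success rate undefined for an empty cohort")
    pct = 100.0 * sum(bool(p) for p in passes) / len(passes)
    return float(Decimal(repr(pct)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def pole_table(records: Iterable[Mapping]) -> pd.DataFrame:
    """Long-format pole-test table for the group statistics stage.

    Each record needs ``subject``, ``group``, ``time_s`` and may carry
    ``week`` and ``light_state``; descent times must be positive.  No
    transformation is applied.
    """
    rows = []
    for rec in records:
        t = float(rec["time_s"])
        if t <= 0:
            raise ValueError(f"non-positive descent time {t} for {rec.get('subject')}")
        rows.append(
            {
                "subject": rec["subject"],
                "group": rec["group"],
                "week": rec.get("week"),
                "light_state": rec.get("light_state"),
                "measure": "pole_time_s",
                "value": t,
            }
        )
    if not rows:
        raise ValueError("no records provided")
    return pd.DataFrame(rows)
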