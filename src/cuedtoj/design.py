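"""Experimental designs: SOA grids and per-SOA repetition counts.

The bundled presets reproduce the two cued-TOJ experiments the package
emulates: ``exp1`` has a no-cue condition and three cue onset asynchronies
(40, 80, 140 ms) with repetition counts biased toward the (shifting) point of
subjective simultaneity, 160 trials per condition; ``exp2`` fixes the COA at
80 ms and varies the spatial cue displacement (CLD 0, 15, 60 px) plus a
no-cue condition, reusing the corresponding repetition rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from .model import TrialCondition

__all__ = ["ConditionDesign", "ExperimentDesign", "make_design"]

_SOAS = (-120, -90, -60, -30, 0, 30, 60, 90, 120, 150, 180)

_REPS_NOCUE = (4, 12, 20, 28, 32, 28, 20, 12, 4, 0, 0)
_REPS_COA40 = (0, 4, 12, 20, 28, 32, 32, 20, 8, 4, 0)
_REPS_COA80 = (0, 4, 8, 12, 20, 28, 32, 28, 20, 8, 0)
_REPS_COA140 = (0, 0, 4, 4, 12, 16, 24, 32, 32, 24, 12)


def _rep_map(reps) -> Dict[float, int]:
    return {float(s): int(r) for s, r in zip(_SOAS, reps) if r > 0}


@dataclass(frozen=True)
class ConditionDesign:
    """One condition: label, timing/geometry, and SOA -> repetitions map."""

    label: str
    coa: Optional[float]
    cld: Optional[float]
    repetitions: Dict[float, int]

    def __post_init__(self) -> None:
        if not self.repetitions:
            raise ValueError(f"condition {self.label!r} has no repetitions")
        for soa, n in self.repetitions.items():
            if not np.isfinite(soa):
                raise ValueError(f"non-finite SOA in condition {self.label!r}")
            if not (isinstance(n, (int, np.integer)) and n >= 0):
                raise ValueError(
                    f"repetition counts must be nonnegative integers, got {n!r} "
                    f"at SOA {soa} in condition {self.label!r}"
                )
        if self.coa is not None and self.coa < 0:
            raise ValueError("coa must be >= 0")

    @property
    def n_trials(self) -> int:
        return sum(self.repetitions.values())

    def trial_conditions(self) -> List[TrialCondition]:
        return [
            TrialCondition(soa=s, coa=self.coa, cld=self.cld)
            for s in sorted(self.repetitions)
        ]


@dataclass(frozen=True)
class ExperimentDesign:
    """A full experiment: conditions plus the number of subjects."""

    name: str
    conditions: List[ConditionDesign]
    n_subjects: int = 30

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        labels = [c.label for c in self.conditions]
        if len(set(labels)) != len(labels):
            raise ValueError("condition labels must be unique")
        if sum(c.coa is None for c in self.conditions) > 1:
            raise ValueError("at most one no-cue condition is allowed")

    def condition(self, label: str) -> ConditionDesign:
        for c in self.conditions:
            if c.label == label:
                return c
        raise KeyError(label)


def make_design(
    preset: str = "exp1",
    n_subjects: Optional[int] = None,
    conditions: Optional[List[ConditionDesign]] = None,
) -> ExperimentDesign:
    """Build a preset (``"exp1"``/``"exp2"``) or custom design.

    For a custom design pass ``preset="custom"`` with a ``conditions`` list;
    validation of repetition tables happens in :class:`ConditionDesign`.
    """
    if preset == "exp1":
        conds = [
            ConditionDesign("no-cue", None, None, _rep_map(_REPS_NOCUE)),
            ConditionDesign("COA=40", 40.0, None, _rep_map(_REPS_COA40)),
            ConditionDesign("COA=80", 80.0, None, _rep_map(_REPS_COA80)),
            ConditionDesign("COA=140", 140.0, None, _rep_map(_REPS_COA140)),
        ]
        return ExperimentDesign("exp1", conds, n_subjects or 30)
    if preset == "exp2":
        conds = [
            ConditionDesign("no-cue", None, None, _rep_map(_REPS_NOCUE)),
            ConditionDesign("CLD=0", 80.0, 0.0, _rep_map(_REPS_COA80)),
            ConditionDesign("CLD=15", 80.0, 15.0, _rep_map(_REPS_COA80)),
            ConditionDesign("CLD=60", 80.0, 60.0, _rep_map(_REPS_COA80)),
        ]
        return ExperimentDesign("exp2", conds, n_subjects or 26)
    if preset == "custom":
        if not conditions:
            raise ValueError("custom design requires a conditions list")
        return ExperimentDesign("custom", list(conditions), n_subjects or 1)
    raise ValueError(f"unknown preset {preset!r}")
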