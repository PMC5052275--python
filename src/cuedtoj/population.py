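"""Synthetic subject populations with the hierarchical structure the
inference assumes.

Subject log-rates are drawn from Gaussian distributions on the log scale
(log-normal rates), which guarantees positivity; the location is
parameterized by the group *median* rate in Hz.  Two phenotypes are mixed:
a "beneficial" majority whose cued conditions show probe-rate benefits at
short cue-target intervals, a reference-rate boost plus a clearly nonzero
cue-as-probe rate at the long interval, and a "disadvantageous" minority for
whom the cue only slows the probe (v_p < v_r) and essentially never wins the
cue-as-probe race.

The default presets center the beneficial phenotype near the group-level
rates reported for the designs bundled in :mod:`cuedtoj.design` (neutral
~29 Hz; probe ~69 Hz at COA 80 ms; probe ~58 Hz, reference ~113 Hz and
cue-as-probe ~10 Hz at COA 140 ms).  The disadvantageous phenotype's rates
are illustrative preset choices (no published values exist for it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .design import ExperimentDesign
from .model import RateSet

__all__ = ["RateDistribution", "ConditionRates", "PopulationSpec", "sample_population"]


@dataclass(frozen=True)
class RateDistribution:
    """Log-normal rate distribution given by its median (Hz) and log-scale sd.

    ``median = 0`` denotes a degenerate point mass at zero (used for a
    cue-as-probe race that never wins, e.g. a fully displaced cue).
    """

    median: float
    sd_log: float = 0.25

    def __post_init__(self) -> None:
        if not (np.isfinite(self.median) and self.median >= 0):
            raise ValueError(f"median must be finite and >= 0, got {self.median}")
        if not (np.isfinite(self.sd_log) and self.sd_log >= 0):
            raise ValueError(f"sd_log must be finite and >= 0, got {self.sd_log}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.median == 0.0:
            return np.zeros(size)
        if self.sd_log == 0.0:
            return np.full(size, self.median)
        return np.exp(rng.normal(np.log(self.median), self.sd_log, size))


@dataclass(frozen=True)
class ConditionRates:
    """Generating distributions for one cued condition."""

    v_p: RateDistribution
    v_r: RateDistribution
    v_cp: RateDistribution


@dataclass(frozen=True)
class PopulationSpec:
    """Generating population: per-phenotype condition rates + mixture weights."""

    v_neutral: RateDistribution
    beneficial: Dict[str, ConditionRates]
    disadvantageous: Optional[Dict[str, ConditionRates]] = None
    weight_disadvantageous: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight_disadvantageous <= 1.0:
            raise ValueError("weight_disadvantageous must be in [0, 1]")
        if self.weight_disadvantageous > 0 and self.disadvantageous is None:
            raise ValueError(
                "weight_disadvantageous > 0 requires a disadvantageous phenotype"
            )


def _exp1_beneficial() -> Dict[str, ConditionRates]:
    return {
        # COA=40: small, unreliable group-level benefit; overall rate ~74 Hz.
        "COA=40": ConditionRates(
            RateDistribution(36.0), RateDistribution(34.0), RateDistribution(4.0, 0.5)
        ),
        # COA=80: clear probe benefit (~69 Hz); overall rate ~96 Hz.
        "COA=80": ConditionRates(
            RateDistribution(69.0), RateDistribution(22.0), RateDistribution(5.0, 0.5)
        ),
        # COA=140: IOR pattern -- reference boosted past the probe, large
        # rightward shift carried by cue-as-probe categorizations.
        "COA=140": ConditionRates(
            RateDistribution(58.0), RateDistribution(113.0), RateDistribution(10.0, 0.5)
        ),
    }


def _disadvantageous(labels) -> Dict[str, ConditionRates]:
    # Cue only slows the probe; essentially no cue-as-probe categorizations.
    return {
        label: ConditionRates(
            RateDistribution(20.0), RateDistribution(36.0), RateDistribution(0.5, 0.5)
        )
        for label in labels
    }


def _exp2_beneficial() -> Dict[str, ConditionRates]:
    return {
        "CLD=0": ConditionRates(
            RateDistribution(83.0), RateDistribution(45.0), RateDistribution(5.0, 0.5)
        ),
        "CLD=15": ConditionRates(
            RateDistribution(53.0), RateDistribution(46.0), RateDistribution(2.0, 0.5)
        ),
        # Fully displaced cue: no cue-as-probe confusions at all.
        "CLD=60": ConditionRates(
            RateDistribution(27.0), RateDistribution(32.0), RateDistribution(0.0)
        ),
    }


def default_population(preset: str = "exp1") -> PopulationSpec:
    """Preset population matched to :func:`cuedtoj.design.make_design`."""
    if preset == "exp1":
        beneficial = _exp1_beneficial()
        return PopulationSpec(
            v_neutral=RateDistribution(29.0),
            beneficial=beneficial,
            disadvantageous=_disadvantageous(beneficial),
            weight_disadvantageous=0.2,
        )
    if preset == "exp2":
        beneficial = _exp2_beneficial()
        return PopulationSpec(
            v_neutral=RateDistribution(31.0),
            beneficial=beneficial,
            disadvantageous=_disadvantageous(beneficial),
            weight_disadvantageous=0.2,
        )
    raise ValueError(f"unknown preset {preset!r}")


@dataclass(frozen=True)
class SubjectRates:
    """Sampled rates for one subject: phenotype, neutral rate, per-condition rates."""

    subject: int
    phenotype: str
    v_neutral: float
    conditions: Dict[str, RateSet]


def sample_population(
    spec: PopulationSpec,
    design: ExperimentDesign,
    seed: int = 0,
) -> List[SubjectRates]:
    """Draw per-subject rate sets for every condition of ``design``.

    Phenotype labels are assigned by a Bernoulli draw with the spec's mixture
    weight; all rates are drawn from the log-normal group distributions, so
    positivity holds by construction.  A fixed seed yields an identical
    population.
    """
    rng = np.random.default_rng(seed)
    n = design.n_subjects
    cued_labels = [c.label for c in design.conditions if c.coa is not None]
    for label in cued_labels:
        if label not in spec.beneficial:
            raise ValueError(f"population spec lacks condition {label!r}")

    disadv = rng.random(n) < spec.weight_disadvantageous
    v_neutral = spec.v_neutral.sample(rng, n)

    per_condition: Dict[str, Dict[str, np.ndarray]] = {}
    for label in cued_labels:
        ben = spec.beneficial[label]
        dis = (spec.disadvantageous or {}).get(label, ben)
        draws = {}
        for name in ("v_p", "v_r", "v_cp"):
            b = getattr(ben, name).sample(rng, n)
            d = getattr(dis, name).sample(rng, n)
            draws[name] = np.where(disadv, d, b)
        per_condition[label] = draws

    subjects = []
    for i in range(n):
        conds = {
            label: RateSet(
                v_p=float(per_condition[label]["v_p"][i]),
                v_r=float(per_condition[label]["v_r"][i]),
                v_cp=float(per_condition[label]["v_cp"][i]),
                v_neutral=float(v_neutral[i]),
            )
            for label in cued_labels
        }
        subjects.append(
            SubjectRates(
                subject=i,
                phenotype="disadvantageous" if disadv[i] else "beneficial",
                v_neutral=float(v_neutral[i]),
                conditions=conds,
            )
        )
    return subjects
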