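"""Trial-level Monte-Carlo implementation of the encoding race.

Serves as the brute-force oracle for the closed form in :mod:`cuedtoj.model`
and as a response engine for illustration plots.  With ``refinements_on=False``
the plain algorithm is used (no cue censoring, reference always at ``v_r``),
which reproduces the textbook simulation exactly; with refinements on (the
default) the cue race is censored at probe onset and a reference shown before
the cue races at the neutral rate until cue onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, ModelConfig
from .model import RateSet, TrialCondition

__all__ = ["SimulationConfig", "simulate_trials", "simulate_curve"]


@dataclass(frozen=True)
class SimulationConfig:
    """Monte-Carlo settings: draws per SOA, the SOA grid (ms), and the seed."""

    n_per_soa: int = 10_000
    soa_grid: Sequence[float] = field(default_factory=lambda: tuple(np.linspace(-150, 250, 61)))
    seed: int = 0
    refinements_on: bool = True

    def __post_init__(self) -> None:
        if self.n_per_soa < 1:
            raise ValueError(f"n_per_soa must be >= 1, got {self.n_per_soa}")
        grid = np.asarray(list(self.soa_grid), dtype=float)
        if grid.size == 0 or not np.all(np.isfinite(grid)):
            raise ValueError("soa_grid must be nonempty and finite")


def _exponential(rng: np.random.Generator, rate_hz: float, size: int) -> np.ndarray:
    """Exponential waiting times in ms; rate 0 yields +inf (never completes)."""
    draws = rng.standard_exponential(size)
    if rate_hz <= 0.0:
        return np.full(size, np.inf)
    return draws / (rate_hz / 1000.0)


def simulate_trials(
    rates: RateSet,
    cond: TrialCondition,
    rng: np.random.Generator,
    n: int = 1,
    refinements_on: bool = True,
    config: ModelConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Simulate ``n`` independent trials of one condition.

    Returns a DataFrame with boolean column ``probe_first`` and column
    ``cause`` in {"probe", "cue", "none"}; ``cause == "cue"`` marks trials in
    which the cue-as-probe event was encoded before both its censoring time
    and the reference (the event counted by ``decompose_contributions``).
    """
    if not isinstance(rates, RateSet):
        raise TypeError("rates must be a RateSet")
    t0 = rates.t0 if rates.t0 else config.t0_ms
    soa = cond.soa

    if not cond.is_cued:
        t_ref = t0 + _exponential(rng, rates.v_neutral, n)
        t_probe = soa + t0 + _exponential(rng, rates.v_neutral, n)
        cue_wins = np.zeros(n, dtype=bool)
        probe_wins = t_probe < t_ref
    else:
        coa = cond.coa
        cue_onset = soa - coa
        if refinements_on and config.regime_rule == "piecewise" and cue_onset > t0:
            # Reference races at v_neutral until cue onset; memoryless restart
            # at v_r afterwards.
            first_leg = _exponential(rng, rates.v_neutral, n)
            second_leg = _exponential(rng, rates.v_r, n)
            pre_cue = cue_onset - t0
            t_ref = t0 + np.where(
                first_leg < pre_cue, first_leg, pre_cue + second_leg
            )
        elif refinements_on and config.regime_rule == "fixed" and cue_onset > 0.0:
            t_ref = t0 + _exponential(rng, rates.v_neutral, n)
        else:
            t_ref = t0 + _exponential(rng, rates.v_r, n)

        t_probe = soa + t0 + _exponential(rng, rates.v_p, n)
        t_cue = cue_onset + t0 + _exponential(rng, rates.v_cp, n)
        if refinements_on:
            cue_valid = t_cue < soa  # masked by the probe at probe onset
        else:
            cue_valid = np.ones(n, dtype=bool)
        cue_wins = cue_valid & (t_cue < t_ref)
        probe_wins = t_probe < t_ref

    probe_first = cue_wins | probe_wins
    cause = np.where(cue_wins, "cue", np.where(probe_wins, "probe", "none"))
    return pd.DataFrame({"probe_first": probe_first, "cause": cause})


def simulate_trial(
    rates: RateSet,
    cond: TrialCondition,
    rng: np.random.Generator,
    refinements_on: bool = True,
    config: ModelConfig = DEFAULT_CONFIG,
):
    """Single-trial convenience wrapper; returns ``(judgment, cause)``."""
    row = simulate_trials(rates, cond, rng, 1, refinements_on, config).iloc[0]
    judgment = "probe_first" if row.probe_first else "reference_first"
    return judgment, str(row.cause)


def simulate_curve(
    rates: RateSet,
    coa: float | None,
    sim: SimulationConfig,
    cld: float | None = None,
    config: ModelConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Empirical psychometric curve over the SOA grid.

    Returns columns ``soa_ms``, ``n``, ``k_probe_first``, ``k_via_cue``.
    Each SOA uses an independent substream spawned from the master seed, so
    results do not depend on evaluation order.
    """
    grid = np.asarray(list(sim.soa_grid), dtype=float)
    streams = np.random.SeedSequence(sim.seed).spawn(grid.size)
    rows = []
    for soa, stream in zip(grid, streams):
        rng = np.random.default_rng(stream)
        cond = TrialCondition(soa=float(soa), coa=coa, cld=cld)
        trials = simulate_trials(rates, cond, rng, sim.n_per_soa, sim.refinements_on, config)
        rows.append(
            {
                "soa_ms": float(soa),
                "n": sim.n_per_soa,
                "k_probe_first": int(trials.probe_first.sum()),
                "k_via_cue": int((trials.cause == "cue").sum()),
            }
        )
    return pd.DataFrame(rows)
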