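"""Closed-form race model of cued temporal-order judgments.

Three independent exponential races, one per stimulus, determine the judgment:
the reference (shown at virtual time 0), the probe (shown at time ``soa``), and
the cue (shown at ``soa - coa``), which races for being miscategorized as the
probe.  A "probe first" judgment occurs when the probe or the cue-as-probe
event completes before the reference is encoded.  Two refinements apply: the
cue race is censored at probe onset (the probe masks the cue), and a reference
shown before the cue races at the neutral-condition rate over the portion of
its race preceding cue onset.

All public interfaces take rates in Hz and times in milliseconds; internally
times stay in ms and rates are converted to events/ms (see :func:`_per_ms`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .config import DEFAULT_CONFIG, ModelConfig

__all__ = [
    "RateSet",
    "TrialCondition",
    "probe_first_probability",
    "cue_capture_probability",
    "decompose_contributions",
    "overall_rate",
]


def _per_ms(rate_hz):
    """Convert a rate in Hz (events/s) to events/ms. Single conversion point."""
    return np.asarray(rate_hz, dtype=float) / 1000.0


@dataclass(frozen=True)
class RateSet:
    """TVA encoding rates for one subject in one condition.

    Parameters
    ----------
    v_p:
        Probe encoding rate in Hz.
    v_r:
        Reference encoding rate in Hz.
    v_cp:
        Rate (Hz) of the "cue is the probe" categorization race.  Zero
        recovers a plain two-racer temporal-order model.
    v_neutral:
        Per-target rate (Hz) in the no-cue condition; also the rate of a
        reference shown before the cue, over its pre-cue race portion.
    t0:
        Encoding threshold in ms (common onset delay for every racer).
    """

    v_p: float
    v_r: float
    v_cp: float = 0.0
    v_neutral: float = 0.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("v_p", "v_r", "v_cp", "v_neutral"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value >= 0.0):
                raise ValueError(f"{name} must be finite and >= 0, got {value}")
        if not (math.isfinite(self.t0) and self.t0 >= 0.0):
            raise ValueError(f"t0 must be finite and >= 0, got {self.t0}")


@dataclass(frozen=True)
class TrialCondition:
    """Timing (and cue-geometry metadata) of one presentation regime.

    Timeline convention: the reference appears at time 0, the probe at ``soa``
    (negative = probe first), the cue at ``soa - coa``.  ``cld`` (cue location
    displacement in px) is condition metadata only and never enters the model.
    """

    soa: float
    coa: Optional[float] = None
    cld: Optional[float] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.soa):
            raise ValueError(f"soa must be finite, got {self.soa}")
        if self.coa is not None and not (math.isfinite(self.coa) and self.coa >= 0.0):
            raise ValueError(f"coa must be finite and >= 0, got {self.coa}")
        if self.cld is not None and not (math.isfinite(self.cld) and self.cld >= 0.0):
            raise ValueError(f"cld must be finite and >= 0, got {self.cld}")

    @property
    def is_cued(self) -> bool:
        return self.coa is not None


# ---------------------------------------------------------------------------
# Vectorized analytic kernels (times in ms, rates in events/ms).
#
# The reference has a piecewise-constant hazard: 0 before its race start t0,
# ``u`` on [t0, m), ``w`` on [m, inf), with m >= t0 the switch time (cue
# onset, clipped to t0).  For any competing racer starting at x0 with rate r,
# the probability that it completes inside [x0, hi) *and* before the
# reference is
#
#   integral_{x0}^{hi} r exp(-r (x - x0)) * S_ref(x) dx ,
#
# which splits into at most three segment integrals of products of
# exponentials.  Everything below is broadcastable numpy.
# ---------------------------------------------------------------------------


def _segment_integral(r, x0, x1, x2, rho, cumhaz_x1):
    """∫_{x1}^{x2} r e^{-r(x-x0)} e^{-cumhaz_x1 - rho (x-x1)} dx, x2 >= x1.

    Valid for r >= 0, rho >= 0; returns 0 where r == 0 or the segment is empty.
    """
    r = np.asarray(r, dtype=float)
    dt = np.maximum(np.asarray(x2, dtype=float) - np.asarray(x1, dtype=float), 0.0)
    total = r + rho
    safe_total = np.where(total > 0.0, total, 1.0)
    # -expm1(-total*dt) is accurate for tiny exponents and handles dt = inf.
    mass = -np.expm1(-safe_total * dt)
    prefactor = r * np.exp(-r * (np.asarray(x1) - np.asarray(x0)) - cumhaz_x1)
    return np.where(total > 0.0, prefactor * mass / safe_total, 0.0)


def _win_before_reference(r, x0, hi, t0, m, u, w):
    """P(racer completes in [x0, hi) and before the reference).

    The racer starts its exponential clock (rate ``r``) at ``x0``; only
    completions strictly before ``hi`` count.  The reference hazard is 0
    before ``t0``, ``u`` on [t0, m) and ``w`` from ``m`` on (m >= t0).
    """
    x0, hi = np.asarray(x0, dtype=float), np.asarray(hi, dtype=float)
    t0, m = np.asarray(t0, dtype=float), np.asarray(m, dtype=float)
    u, w = np.asarray(u, dtype=float), np.asarray(w, dtype=float)

    # Segment A: reference not yet racing (survival 1).
    a1 = x0
    a2 = np.maximum(x0, np.minimum(hi, t0))
    part_a = _segment_integral(r, x0, a1, a2, 0.0, 0.0)

    # Segment B: reference at the neutral rate u.
    b1 = np.maximum(x0, t0)
    b2 = np.maximum(b1, np.minimum(hi, m))
    part_b = _segment_integral(r, x0, b1, b2, u, u * np.maximum(b1 - t0, 0.0))

    # Segment C: reference at rate w.
    c1 = np.maximum(x0, m)
    c2 = np.maximum(c1, hi)
    cumhaz_c1 = u * np.maximum(m - t0, 0.0) + w * np.maximum(c1 - m, 0.0)
    part_c = _segment_integral(r, x0, c1, c2, w, cumhaz_c1)

    return part_a + part_b + part_c


def _cued_components(v_p, v_r, v_cp, v_neutral, soa, coa, t0, regime_rule):
    """(p_via_cue, p_via_probe) for cued trials; all arguments broadcastable.

    Rates in Hz, times in ms.
    """
    p = _per_ms(v_p)
    w = _per_ms(v_r)
    q = _per_ms(v_cp)
    u = _per_ms(v_neutral)
    soa = np.asarray(soa, dtype=float)
    coa = np.asarray(coa, dtype=float)
    t0 = np.asarray(t0, dtype=float)

    cue_onset = soa - coa
    if regime_rule == "piecewise":
        m = np.maximum(cue_onset, t0)
    elif regime_rule == "fixed":
        # Single reference rate per regime: neutral when the reference leads
        # the cue, v_r otherwise.  Encoded as an empty neutral segment with a
        # regime-selected constant rate.
        m = np.broadcast_to(t0, np.broadcast_shapes(soa.shape, coa.shape, t0.shape)).copy()
        w = np.where(cue_onset > 0.0, u, w)
    else:  # pragma: no cover - guarded by ModelConfig
        raise ValueError(f"unknown regime rule {regime_rule!r}")

    probe_start = soa + t0
    cue_start = soa - coa + t0
    mask_time = soa  # probe onset terminates the cue race

    p_probe_beats_ref = _win_before_reference(p, probe_start, np.inf, t0, m, u, w)
    p_via_cue = _win_before_reference(q, cue_start, mask_time, t0, m, u, w)
    capture = -np.expm1(-q * np.maximum(mask_time - cue_start, 0.0))
    p_via_probe = (1.0 - capture) * p_probe_beats_ref
    return p_via_cue, p_via_probe


def _neutral_probability(v_neutral, soa):
    """P(probe first) in the no-cue condition: both targets race at v_neutral.

    The common threshold t0 shifts both racers equally and cancels.
    """
    u = _per_ms(v_neutral)
    soa = np.asarray(soa, dtype=float)
    up = u * np.abs(soa)
    half_tail = 0.5 * np.exp(-up)
    with np.errstate(invalid="ignore"):
        out = np.where(soa >= 0.0, half_tail, 1.0 - half_tail)
    # u == 0: neither target is ever encoded; ties resolve as "not probe first".
    return np.where(u > 0.0, out, 0.0)


def _validate(rates: RateSet, cond: TrialCondition) -> None:
    if not isinstance(rates, RateSet):
        raise TypeError("rates must be a RateSet")
    if not isinstance(cond, TrialCondition):
        raise TypeError("cond must be a TrialCondition")


def decompose_contributions(
    rates: RateSet,
    cond: TrialCondition,
    config: ModelConfig = DEFAULT_CONFIG,
) -> Tuple[float, float]:
    """Split P(probe first) into the cue-borne and probe-borne contribution.

    Returns ``(p_via_cue, p_via_probe)``: the probability that the
    cue-as-probe categorization completes before both its masking time and the
    reference, and the probability that the probe itself beats the reference
    when the cue event has not.  Their sum is :func:`probe_first_probability`
    exactly.
    """
    _validate(rates, cond)
    t0 = rates.t0 if rates.t0 else config.t0_ms
    if not cond.is_cued:
        return 0.0, float(_neutral_probability(rates.v_neutral, cond.soa))
    via_cue, via_probe = _cued_components(
        rates.v_p, rates.v_r, rates.v_cp, rates.v_neutral,
        cond.soa, cond.coa, t0, config.regime_rule,
    )
    return float(via_cue), float(via_probe)


def probe_first_probability(
    rates: RateSet,
    cond: TrialCondition,
    config: ModelConfig = DEFAULT_CONFIG,
) -> float:
    """Probability of a "probe first" judgment for one condition.

    P(min(probe completion, censored cue-as-probe completion) < reference
    completion) under independent exponential races started at each stimulus's
    onset plus ``t0``.  In a no-cue condition both targets race at
    ``v_neutral`` and ``v_cp`` is ignored.
    """
    via_cue, via_probe = decompose_contributions(rates, cond, config)
    return via_cue + via_probe


def cue_capture_probability(v_cp: float, coa: float, t0: float = 0.0) -> float:
    """Probability that the cue wins its cue-as-probe race before being masked.

    The race runs over the uncensored window from cue onset + ``t0`` to probe
    onset, of length ``max(coa - t0, 0)``; with ``t0 = 0`` this is
    ``1 - exp(-v_cp * coa)``.  Arguments: ``v_cp`` in Hz, ``coa``/``t0`` in ms.
    """
    for name, value in (("v_cp", v_cp), ("coa", coa), ("t0", t0)):
        if not (math.isfinite(value) and value >= 0.0):
            raise ValueError(f"{name} must be finite and >= 0, got {value}")
    window = max(coa - t0, 0.0)
    return float(-np.expm1(-_per_ms(v_cp) * window))


def overall_rate(rates: RateSet, cued: bool = True) -> float:
    """Overall processing rate C: the sum of all v rates in a condition (Hz).

    For a cued condition this is ``v_p + v_r + v_cp``; for the no-cue
    condition both targets race at the neutral rate, giving ``2 * v_neutral``.
    """
    if not isinstance(rates, RateSet):
        raise TypeError("rates must be a RateSet")
    if cued:
        return rates.v_p + rates.v_r + rates.v_cp
    return 2.0 * rates.v_neutral


# Vectorized entry point used by inference and the synthetic-data generator.
def probe_first_probability_arrays(
    v_p, v_r, v_cp, v_neutral, soa, coa, t0=0.0, regime_rule: str = "piecewise"
):
    """Broadcasting version of :func:`probe_first_probability`.

    ``coa`` may contain NaN to mark no-cue cells (the corresponding targets
    then both race at ``v_neutral``).
    """
    soa = np.asarray(soa, dtype=float)
    coa = np.asarray(coa, dtype=float)
    nocue = ~np.isfinite(coa)
    via_cue, via_probe = _cued_components(
        v_p, v_r, v_cp, v_neutral, soa, np.where(nocue, 0.0, coa), t0, regime_rule
    )
    cued_p = via_cue + via_probe
    neutral_p = _neutral_probability(v_neutral, soa)
    return np.where(nocue, neutral_p, cued_p)
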