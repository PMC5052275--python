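"""Classic psychometric summaries: PSS and DL, from model rates or count fits.

The point of subjective simultaneity (PSS) is the SOA at which the "probe
first" probability crosses 0.5; the difference limen (DL) is half the
distance between two flanking quantile points (25%/75% by default).  Both can
be read off the race model's closed-form curve or estimated the traditional
way, by maximum-likelihood fit of a logistic psychometric function to
binomial counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq, minimize
from sklearn.base import BaseEstimator

from .config import DEFAULT_CONFIG, ModelConfig
from .model import RateSet, TrialCondition, probe_first_probability

__all__ = [
    "PsychometricSummary",
    "pss_dl_from_rates",
    "ClassicPsychometricFit",
    "fit_classic_curve",
    "pss_from_curve",
]

_SOA_SPAN = 3000.0  # ms; search bracket for quantile crossings


@dataclass(frozen=True)
class PsychometricSummary:
    """PSS and DL in ms, with the curve source and a success flag."""

    pss: float
    dl: float
    source: str  # "model_rates" or "logistic_fit"
    quantiles: Tuple[float, float] = (0.25, 0.75)
    success: bool = True
    message: str = ""


def _crossing(fun, level: float) -> Optional[float]:
    """SOA at which the decreasing curve ``fun`` crosses ``level``."""
    lo, hi = -_SOA_SPAN, _SOA_SPAN
    f_lo, f_hi = fun(lo) - level, fun(hi) - level
    if f_lo < 0.0 or f_hi > 0.0:
        return None
    return brentq(lambda s: fun(s) - level, lo, hi, xtol=1e-6)


def pss_dl_from_rates(
    rates: RateSet,
    coa: Optional[float],
    config: ModelConfig = DEFAULT_CONFIG,
    quantiles: Tuple[float, float] = (0.25, 0.75),
) -> PsychometricSummary:
    """PSS and DL of the closed-form race-model curve (root finding).

    ``coa=None`` evaluates the no-cue curve.  If the curve never crosses 0.5
    in the searched SOA range the summary is flagged unsuccessful with
    ``pss = nan``.
    """
    q_lo, q_hi = quantiles
    if not 0.0 < q_lo < 0.5 < q_hi < 1.0:
        raise ValueError(f"quantiles must straddle 0.5 strictly, got {quantiles}")

    def curve(s: float) -> float:
        return probe_first_probability(rates, TrialCondition(s, coa), config)

    pss = _crossing(curve, 0.5)
    if pss is None:
        return PsychometricSummary(
            pss=float("nan"), dl=float("nan"), source="model_rates",
            quantiles=quantiles, success=False,
            message="curve does not cross 0.5 in the searched SOA range",
        )
    # Decreasing curve: the q_hi probability point sits at a smaller SOA.
    s_hi = _crossing(curve, q_hi)
    s_lo = _crossing(curve, q_lo)
    if s_hi is None or s_lo is None:
        dl = float("nan")
        ok, msg = False, "quantile points outside the searched SOA range"
    else:
        dl = (s_lo - s_hi) / 2.0
        ok, msg = True, ""
    return PsychometricSummary(
        pss=float(pss), dl=float(dl), source="model_rates",
        quantiles=quantiles, success=ok, message=msg,
    )


def pss_from_curve(soa: Sequence[float], p: Sequence[float]) -> float:
    """Empirical PSS: linear interpolation of the 0.5 crossing of a
    (noisy, roughly decreasing) relative-frequency curve."""
    soa = np.asarray(soa, dtype=float)
    p = np.asarray(p, dtype=float)
    order = np.argsort(soa)
    soa, p = soa[order], p[order]
    above = p >= 0.5
    if above.all() or not above.any():
        return float("nan")
    i = int(np.max(np.nonzero(above)[0]))  # last SOA still at/above 0.5
    if i + 1 >= soa.size:
        return float(soa[i])
    s0, s1, p0, p1 = soa[i], soa[i + 1], p[i], p[i + 1]
    if p0 == p1:
        return float((s0 + s1) / 2)
    return float(s0 + (p0 - 0.5) * (s1 - s0) / (p0 - p1))


class ClassicPsychometricFit(BaseEstimator):
    """Maximum-likelihood logistic psychometric function for binomial counts.

    Model: P("probe first" | soa) = 1 / (1 + exp((soa - alpha) / beta)),
    decreasing in SOA, with ``alpha`` the PSS and ``beta > 0`` the spread.
    DL is ``beta * log((1 - q) / q)`` for the lower quantile ``q``.

    Fitted attributes: ``alpha_``, ``beta_``, ``pss_``, ``dl_``,
    ``success_``, ``message_``.
    """

    def __init__(self, quantiles: Tuple[float, float] = (0.25, 0.75)) -> None:
        self.quantiles = quantiles

    def fit(self, soa, k, n) -> "ClassicPsychometricFit":
        soa = np.asarray(soa, dtype=float)
        k = np.asarray(k, dtype=float)
        n = np.asarray(n, dtype=float)
        keep = n > 0
        soa, k, n = soa[keep], k[keep], n[keep]
        if np.unique(soa).size < 3:
            raise ValueError("need >= 3 distinct SOA levels with trials")
        if np.all(k == 0) or np.all(k == n):
            self._flag_failure("degenerate data: all responses identical")
            return self

        def nll(params):
            alpha, log_beta = params
            beta = math.exp(np.clip(log_beta, -10, 10))
            z = (soa - alpha) / beta
            # log(p) and log(1-p) for p = 1/(1+e^z), numerically stable
            log_p = -np.logaddexp(0.0, z)
            log_q = -np.logaddexp(0.0, -z)
            return -float(np.sum(k * log_p + (n - k) * log_q))

        freq = k / n
        alpha0 = pss_from_curve(soa, freq)
        if not np.isfinite(alpha0):
            alpha0 = float(np.median(soa))
        beta0 = max((soa.max() - soa.min()) / 8.0, 1.0)
        best = None
        for scale in (1.0, 3.0):
            res = minimize(
                nll, x0=[alpha0, math.log(beta0 * scale)], method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 2000},
            )
            if best is None or res.fun < best.fun:
                best = res
        self.alpha_ = float(best.x[0])
        self.beta_ = float(math.exp(best.x[1]))
        self.pss_ = self.alpha_
        q = self.quantiles[0]
        self.dl_ = self.beta_ * math.log((1.0 - q) / q)
        self.success_ = bool(best.success)
        self.message_ = str(best.message)
        self.nll_ = float(best.fun)
        return self

    def predict(self, soa) -> np.ndarray:
        z = (np.asarray(soa, dtype=float) - self.alpha_) / self.beta_
        return 1.0 / (1.0 + np.exp(z))

    def summary(self) -> PsychometricSummary:
        return PsychometricSummary(
            pss=self.pss_, dl=self.dl_, source="logistic_fit",
            quantiles=self.quantiles, success=self.success_,
            message=self.message_,
        )

    def _flag_failure(self, message: str) -> None:
        self.alpha_ = self.pss_ = self.dl_ = self.beta_ = float("nan")
        self.nll_ = float("nan")
        self.success_ = False
        self.message_ = message


def fit_classic_curve(
    soa, k, n, quantiles: Tuple[float, float] = (0.25, 0.75)
) -> PsychometricSummary:
    """Thin wrapper: logistic ML fit of counts, returning the summary."""
    return ClassicPsychometricFit(quantiles=quantiles).fit(soa, k, n).summary()
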