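"""Numba-compiled scalar kernels for the race-model likelihood.

These mirror the vectorized closed form in :mod:`cuedtoj.model` exactly (same
segment integrals, same unit conventions) but run as tight scalar loops, which
is what the MCMC sampler needs: tens of thousands of small likelihood
evaluations.  Equivalence with the numpy implementation is asserted in the
test suite.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["p1st_scalar", "neutral_scalar", "unit_loglik", "cell_probs_draws"]


@njit(cache=True)
def _segment(r, x0, x1, x2, rho, cumhaz_x1):
    if r <= 0.0:
        return 0.0
    dt = x2 - x1
    if dt <= 0.0:
        return 0.0
    total = r + rho
    return r * math.exp(-r * (x1 - x0) - cumhaz_x1) * (-math.expm1(-total * dt)) / total


@njit(cache=True)
def _win_before_reference(r, x0, hi, t0, m, u, w):
    a2 = max(x0, min(hi, t0))
    part = _segment(r, x0, x0, a2, 0.0, 0.0)
    b1 = max(x0, t0)
    b2 = max(b1, min(hi, m))
    part += _segment(r, x0, b1, b2, u, u * max(b1 - t0, 0.0))
    c1 = max(x0, m)
    c2 = max(c1, hi)
    cumhaz = u * max(m - t0, 0.0) + w * max(c1 - m, 0.0)
    part += _segment(r, x0, c1, c2, w, cumhaz)
    return part


@njit(cache=True)
def p1st_scalar(vp, vr, vcp, vn, soa, coa, t0, piecewise):
    p = vp / 1000.0
    w = vr / 1000.0
    q = vcp / 1000.0
    u = vn / 1000.0
    cue_onset = soa - coa
    if piecewise:
        m = max(cue_onset, t0)
    else:
        m = t0
        if cue_onset > 0.0:
            w = u
    probe_start = soa + t0
    cue_start = cue_onset + t0
    mask_time = soa
    pbr = _win_before_reference(p, probe_start, np.inf, t0, m, u, w)
    pvc = _win_before_reference(q, cue_start, mask_time, t0, m, u, w)
    capture = -math.expm1(-q * max(mask_time - cue_start, 0.0))
    return pvc + (1.0 - capture) * pbr


@njit(cache=True)
def neutral_scalar(vn, soa):
    u = vn / 1000.0
    if u <= 0.0:
        return 0.0
    half_tail = 0.5 * math.exp(-u * abs(soa))
    if soa >= 0.0:
        return half_tail
    return 1.0 - half_tail


@njit(cache=True)
def _rate(log_rate):
    """Hz rate from a log-rate, clamped to a physically absurd but finite
    range so far-out MCMC proposals cannot overflow."""
    if log_rate < -30.0:
        log_rate = -30.0
    elif log_rate > 15.0:
        log_rate = 15.0
    return math.exp(log_rate)


@njit(cache=True)
def unit_loglik(lvp, lvr, lvcp, lvn, subj, soa, n, k, coa, t0, piecewise, nocue, out):
    """Per-subject binomial log-likelihood sums; (S,) log-rate arrays."""
    out[:] = 0.0
    eps = 1e-12
    for i in range(soa.size):
        s = subj[i]
        if nocue:
            p = neutral_scalar(_rate(lvn[s]), soa[i])
        else:
            p = p1st_scalar(
                _rate(lvp[s]), _rate(lvr[s]), _rate(lvcp[s]), _rate(lvn[s]),
                soa[i], coa, t0, piecewise,
            )
        if p < eps:
            p = eps
        elif p > 1.0 - eps:
            p = 1.0 - eps
        out[s] += k[i] * math.log(p) + (n[i] - k[i]) * math.log1p(-p)
    return out


@njit(cache=True)
def cell_probs_draws(lvp, lvr, lvcp, lvn, subj, soa, coa, t0, piecewise, nocue):
    """(D, cells) success probabilities from (D, S) log-rate draws."""
    D = lvn.shape[0]
    C = soa.size
    out = np.empty((D, C))
    for d in range(D):
        for i in range(C):
            s = subj[i]
            if nocue:
                out[d, i] = neutral_scalar(_rate(lvn[d, s]), soa[i])
            else:
                out[d, i] = p1st_scalar(
                    _rate(lvp[d, s]), _rate(lvr[d, s]), _rate(lvcp[d, s]),
                    _rate(lvn[d, s]), soa[i], coa, t0, piecewise,
                )
    return out
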