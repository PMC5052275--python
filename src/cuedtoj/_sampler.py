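"""Adaptive Metropolis-within-Gibbs sampler for the hierarchical TOJ model.

The model: for subject ``i`` the log of each rate parameter (per cued
condition: v_p, v_r, v_cp as licensed by the model variant; plus one shared
v_neutral) is drawn from a Gaussian group distribution,

    log v_i ~ Normal(mu, sigma),

and the observed "probe first" counts are Binomial with the closed-form race
probability as success rate.  Subjects are conditionally independent given the
group parameters, so proposals are made for all subjects in parallel and
accepted element-wise.  Within each cued condition the subject's log-rates are
proposed *jointly* with a per-subject covariance adapted from the warmup
history (Haario-style adaptive Metropolis): the posterior carries strong
ridges between (v_p - v_r) and v_cp, and axis-aligned proposals mix poorly
across them.  Group means have conjugate Gaussian full conditionals and are
drawn exactly; group spreads use a random-walk step on log sigma.  All
adaptation happens during warmup and is frozen afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .config import ModelConfig
from .data import TOJDataset

_P_EPS = 1e-12
_ADAPT_WINDOW = 25
_COV_WINDOW = 100
_TARGET_ACCEPT = 0.28  # joint proposals in 1-3 dimensions


@dataclass(frozen=True)
class Prior:
    """Gaussian prior on a group log-mean and half-normal prior on its spread."""

    mu_loc: float
    mu_scale: float
    sigma_scale: float


DEFAULT_PRIORS: Dict[str, Prior] = {
    # Target rates cluster in the tens of Hz; log-scale Gaussians centred at
    # log 30 with generous scale are weakly informative with heavy right tails.
    "v_neutral": Prior(math.log(30.0), 1.5, 0.7),
    "v_p": Prior(math.log(30.0), 1.5, 0.7),
    "v_r": Prior(math.log(30.0), 1.5, 0.7),
    # Cue-as-probe rates are low (units of Hz) and may be near zero.
    "v_cp": Prior(math.log(5.0), 2.0, 0.7),
}


@dataclass(frozen=True)
class McmcConfig:
    chains: int = 4
    warmup: int = 800
    draws: int = 800
    seed: int = 0
    rhat_threshold: float = 1.01

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need >= 2 chains for split-chain diagnostics")
        if self.warmup < 1 or self.draws < 1:
            raise ValueError("warmup and draws must be >= 1")


@dataclass
class _Unit:
    """One likelihood unit: all cells of one condition (or the no-cue rows)."""

    label: str
    subj: np.ndarray  # int index into the subject list, per cell
    soa: np.ndarray
    n: np.ndarray
    k: np.ndarray
    coa: float  # nan for the no-cue unit

    @property
    def is_nocue(self) -> bool:
        return not np.isfinite(self.coa)


@dataclass
class _Block:
    """A jointly proposed subject-level parameter block."""

    name: str
    params: List[str]  # value-dict keys, e.g. ["v_p[COA=80]", ...]
    bases: List[str]  # prior keys, e.g. ["v_p", "v_r", "v_cp"]
    affects: List[str] = field(default_factory=list)  # unit labels


class ModelSpec:
    """Data + parameter layout for one model variant."""

    VARIANTS = ("full", "rates_only", "confusion_only")

    def __init__(
        self,
        dataset: TOJDataset,
        variant: str,
        config: ModelConfig,
        priors: Optional[Dict[str, Prior]] = None,
    ) -> None:
        if variant not in self.VARIANTS:
            raise ValueError(f"variant must be one of {self.VARIANTS}, got {variant!r}")
        self.variant = variant
        self.config = config
        self.priors = dict(DEFAULT_PRIORS, **(priors or {}))
        self.subjects = dataset.subjects
        self.n_subjects = len(self.subjects)
        subj_index = {s: i for i, s in enumerate(self.subjects)}

        df = dataset.table
        self.units: Dict[str, _Unit] = {}
        for label, grp in df.groupby("condition_label", sort=False):
            coa_vals = grp["coa_ms"].to_numpy(dtype=float)
            coa = float(coa_vals[0]) if np.isfinite(coa_vals[0]) else float("nan")
            self.units[label] = _Unit(
                label=label,
                subj=grp["subject_id"].map(subj_index).to_numpy(dtype=int),
                soa=grp["soa_ms"].to_numpy(dtype=float),
                n=grp["n_trials"].to_numpy(dtype=float),
                k=grp["n_probe_first"].to_numpy(dtype=float),
                coa=coa,
            )
        self.cued_labels = [u for u, unit in self.units.items() if not unit.is_nocue]
        self.nocue_label = next(
            (u for u, unit in self.units.items() if unit.is_nocue), None
        )

        # v_neutral enters every no-cue cell; under the piecewise regime it
        # also enters cued cells whose reference precedes the cue, and under
        # the confusion-only variant it replaces both target rates everywhere.
        neutral_affects = [] if self.nocue_label is None else [self.nocue_label]
        for label in self.cued_labels:
            unit = self.units[label]
            tied = variant == "confusion_only"
            regime = config.regime_rule == "piecewise" and bool(
                np.any(unit.soa - unit.coa > config.t0_ms)
            )
            fixed = config.regime_rule == "fixed" and bool(
                np.any(unit.soa - unit.coa > 0.0)
            )
            if tied or regime or fixed:
                neutral_affects.append(label)

        self.blocks: List[_Block] = [
            _Block("v_neutral", ["v_neutral"], ["v_neutral"], neutral_affects)
        ]
        for label in self.cued_labels:
            params, bases = [], []
            if variant in ("full", "rates_only"):
                params += [f"v_p[{label}]", f"v_r[{label}]"]
                bases += ["v_p", "v_r"]
            if variant in ("full", "confusion_only"):
                params += [f"v_cp[{label}]"]
                bases += ["v_cp"]
            self.blocks.append(_Block(label, params, bases, [label]))
        self.param_names: List[str] = [p for b in self.blocks for p in b.params]
        self.param_base: Dict[str, str] = {
            p: base for b in self.blocks for p, base in zip(b.params, b.bases)
        }

    # -- likelihood ---------------------------------------------------------

    def unit_rates(
        self, label: str, values: Dict[str, np.ndarray]
    ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Per-subject rate arrays (Hz) for one cued unit under the variant."""
        vn = _bounded_exp(values["v_neutral"])
        if self.variant == "confusion_only":
            vp = vr = vn
        else:
            vp = _bounded_exp(values[f"v_p[{label}]"])
            vr = _bounded_exp(values[f"v_r[{label}]"])
        if self.variant == "rates_only":
            vcp = np.zeros_like(vn)
        else:
            vcp = _bounded_exp(values[f"v_cp[{label}]"])
        return vp, vr, vcp, vn

    def unit_logrates(
        self, label: str, values: Dict[str, np.ndarray]
    ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(log v_p, log v_r, log v_cp, log v_neutral) arrays for one unit."""
        unit = self.units[label]
        lvn = values["v_neutral"]
        if unit.is_nocue:
            return lvn, lvn, lvn, lvn  # only v_neutral is read downstream
        if self.variant == "confusion_only":
            lvp = lvr = lvn
        else:
            lvp = values[f"v_p[{label}]"]
            lvr = values[f"v_r[{label}]"]
        if self.variant == "rates_only":
            lvcp = np.broadcast_to(-1e3, lvn.shape)  # rate ~ 0 Hz
        else:
            lvcp = values[f"v_cp[{label}]"]
        return lvp, lvr, lvcp, lvn

    def cell_probabilities(
        self, label: str, values: Dict[str, np.ndarray]
    ) -> np.ndarray:
        """Success probabilities per cell; values may carry a draw dimension."""
        from ._kernels import cell_probs_draws

        unit = self.units[label]
        lvp, lvr, lvcp, lvn = self.unit_logrates(label, values)
        squeeze = lvn.ndim == 1
        lvp, lvr, lvcp, lvn = (
            np.atleast_2d(np.ascontiguousarray(a)) for a in (lvp, lvr, lvcp, lvn)
        )
        p = cell_probs_draws(
            lvp, lvr, lvcp, lvn,
            unit.subj, unit.soa,
            0.0 if unit.is_nocue else unit.coa,
            self.config.t0_ms,
            self.config.regime_rule == "piecewise",
            unit.is_nocue,
        )
        p = np.clip(p, _P_EPS, 1.0 - _P_EPS)
        return p[0] if squeeze else p

    def unit_loglik(self, label: str, values: Dict[str, np.ndarray]) -> np.ndarray:
        """Per-subject log-likelihood sums, shape (S,)."""
        from ._kernels import unit_loglik as _kernel_ll

        unit = self.units[label]
        lvp, lvr, lvcp, lvn = self.unit_logrates(label, values)
        out = np.empty(self.n_subjects)
        return _kernel_ll(
            lvp, lvr, lvcp, lvn,
            unit.subj, unit.soa, unit.n, unit.k,
            0.0 if unit.is_nocue else unit.coa,
            self.config.t0_ms,
            self.config.regime_rule == "piecewise",
            unit.is_nocue,
            out,
        )

    def pointwise_loglik(self, label: str, values: Dict[str, np.ndarray]) -> np.ndarray:
        """Per-cell binomial log-likelihood; values may carry draw dimensions."""
        from scipy.special import gammaln

        unit = self.units[label]
        p = self.cell_probabilities(label, values)
        n, k = unit.n, unit.k
        const = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        return const + k * np.log(p) + (n - k) * np.log1p(-p)


def _bounded_exp(x: np.ndarray) -> np.ndarray:
    """exp with the log-rate clamped to a physically absurd but finite range,
    so far-out proposals cannot overflow (they are rejected by the prior)."""
    return np.exp(np.clip(x, -30.0, 15.0))


class GibbsSampler:
    """Runs one chain of the Metropolis-within-Gibbs scheme."""

    def __init__(self, spec: ModelSpec, mcmc: McmcConfig, rng: np.random.Generator):
        self.spec = spec
        self.mcmc = mcmc
        self.rng = rng
        S = spec.n_subjects
        self.values: Dict[str, np.ndarray] = {}
        self.mu: Dict[str, float] = {}
        self.sigma: Dict[str, float] = {}
        for name in spec.param_names:
            prior = spec.priors[spec.param_base[name]]
            init = prior.mu_loc + 0.15 * rng.standard_normal(S)
            self.values[name] = init
            self.mu[name] = float(np.mean(init))
            self.sigma[name] = 0.3
        # Per-block joint proposal state.
        self.chol = {
            b.name: np.broadcast_to(
                0.12 * np.eye(len(b.params)), (S, len(b.params), len(b.params))
            ).copy()
            for b in spec.blocks
        }
        self._hist = {
            b.name: np.empty((mcmc.warmup, S, len(b.params))) for b in spec.blocks
        }
        self.sigma_steps = {p: 0.5 for p in spec.param_names}
        self._sigma_acc = {p: 0.0 for p in spec.param_names}
        self.asis_steps = {p: 0.1 for p in spec.param_names}
        self._asis_acc = {p: 0.0 for p in spec.param_names}
        self._param_affects = {
            p: b.affects for b in spec.blocks for p in b.params
        }
        # Joint translation moves of a block's group means (ridge traversal).
        self.mu_chol = {
            b.name: 0.05 * np.eye(len(b.params)) for b in spec.blocks
        }
        self._mu_hist = {
            b.name: np.empty((mcmc.warmup, len(b.params))) for b in spec.blocks
        }
        self.unit_ll = {
            label: spec.unit_loglik(label, self.values) for label in spec.units
        }
        self._force_slice = True

    def _update_block(self, block: _Block, adapt: bool) -> None:
        """Directional slice update of one block, all subjects in parallel.

        Each subject gets an independent random direction drawn from its
        adapted proposal covariance; a univariate slice sampler (step-out +
        shrinkage) then moves the subject along that line.  Slice sampling
        never rejects, which matters on the long flat likelihood ridges
        between (v_p - v_r) and v_cp.
        """
        spec, rng = self.spec, self.rng
        S, k = spec.n_subjects, len(block.params)
        # The shared-neutral block touches every condition's likelihood and is
        # nearly Gaussian; a covariance-scaled Metropolis step mixes it well at
        # a quarter of the slice cost (the slice pass still runs periodically).
        if len(block.affects) > 1 and not self._force_slice:
            self._update_block_metropolis(block)
            return
        cur = np.stack([self.values[p] for p in block.params], axis=1)  # (S, k)
        direction = np.einsum(
            "sij,sj->si", self.chol[block.name], rng.standard_normal((S, k))
        )
        mus = np.array([self.mu[p] for p in block.params])
        sigmas = np.array([self.sigma[p] for p in block.params])

        def eval_at(t):
            theta = cur + t[:, None] * direction
            trial = dict(self.values)
            for j, name in enumerate(block.params):
                trial[name] = theta[:, j]
            lls = {label: spec.unit_loglik(label, trial) for label in block.affects}
            lp = -0.5 * np.sum(((theta - mus) / sigmas) ** 2, axis=1)
            for label in block.affects:
                lp = lp + lls[label]
            return lp, lls

        lp0 = -0.5 * np.sum(((cur - mus) / sigmas) ** 2, axis=1)
        for label in block.affects:
            lp0 = lp0 + self.unit_ll[label]
        y = lp0 + np.log(rng.random(S))
        width = 1.0
        lo = -width * rng.random(S)
        hi = lo + width
        for _ in range(6):
            still_open = eval_at(lo)[0] > y
            if not still_open.any():
                break
            lo[still_open] -= width
        for _ in range(6):
            still_open = eval_at(hi)[0] > y
            if not still_open.any():
                break
            hi[still_open] += width
        t_final = np.zeros(S)
        active = np.ones(S, dtype=bool)
        for _ in range(25):
            t = np.where(active, lo + rng.random(S) * (hi - lo), t_final)
            lp_t = eval_at(t)[0]
            newly = active & (lp_t > y)
            t_final[newly] = t[newly]
            active &= ~newly
            if not active.any():
                break
            shrink_lo = active & (t < 0.0)
            lo[shrink_lo] = t[shrink_lo]
            shrink_hi = active & (t >= 0.0)
            hi[shrink_hi] = t[shrink_hi]
        _, lls_final = eval_at(t_final)
        theta = cur + t_final[:, None] * direction
        for j, name in enumerate(block.params):
            self.values[name] = theta[:, j]
        for label in block.affects:
            self.unit_ll[label] = lls_final[label]

    def _update_block_metropolis(self, block: _Block) -> None:
        spec, rng = self.spec, self.rng
        S, k = spec.n_subjects, len(block.params)
        jump = 1.6 * np.einsum(
            "sij,sj->si", self.chol[block.name], rng.standard_normal((S, k))
        )
        trial = dict(self.values)
        prior_delta = np.zeros(S)
        for j, name in enumerate(block.params):
            cur = self.values[name]
            prop = cur + jump[:, j]
            trial[name] = prop
            mu, sigma = self.mu[name], self.sigma[name]
            prior_delta += -0.5 * ((prop - mu) / sigma) ** 2 + 0.5 * (
                (cur - mu) / sigma
            ) ** 2
        new_ll = {label: spec.unit_loglik(label, trial) for label in block.affects}
        ll_delta = sum(new_ll[label] - self.unit_ll[label] for label in block.affects)
        accept = np.log(rng.random(S)) < prior_delta + ll_delta
        for name in block.params:
            self.values[name][accept] = trial[name][accept]
        for label in block.affects:
            self.unit_ll[label][accept] = new_ll[label][accept]

    def _update_group(self, name: str, adapt: bool) -> None:
        spec, rng = self.spec, self.rng
        prior = spec.priors[spec.param_base[name]]
        theta = self.values[name]
        S = theta.size
        sigma = self.sigma[name]
        # Conjugate Gaussian draw for the group mean.
        prec = S / sigma**2 + 1.0 / prior.mu_scale**2
        mean = (theta.sum() / sigma**2 + prior.mu_loc / prior.mu_scale**2) / prec
        self.mu[name] = rng.normal(mean, 1.0 / math.sqrt(prec))
        mu = self.mu[name]

        # Random-walk MH on log sigma (half-normal prior, log-Jacobian term).
        def logp(s: float) -> float:
            if not s > 0:
                return -np.inf
            return (
                -S * math.log(s)
                - 0.5 * float(np.sum((theta - mu) ** 2)) / s**2
                - 0.5 * (s / prior.sigma_scale) ** 2
                + math.log(s)
            )

        prop = sigma * math.exp(self.sigma_steps[name] * rng.standard_normal())
        if math.log(rng.random()) < logp(prop) - logp(sigma):
            self.sigma[name] = prop
            if adapt:
                self._sigma_acc[name] += 1.0

    def _update_group_asis(self, name: str, adapt: bool) -> None:
        """Non-centered (ancillary) group move, interleaved with the centered
        updates: propose (mu, log sigma) holding the standardized subject
        effects z = (theta - mu)/sigma fixed, so all subject rates translate
        and rescale coherently.  This traverses the funnel between group
        spread and subject values that the centered steps cannot."""
        spec, rng = self.spec, self.rng
        prior = spec.priors[spec.param_base[name]]
        mu, sigma = self.mu[name], self.sigma[name]
        theta = self.values[name]
        z = (theta - mu) / sigma
        step = self.asis_steps[name]
        if rng.random() < 0.5:
            mu_prop = mu + step * rng.standard_normal()
            sigma_prop = sigma * math.exp(step * rng.standard_normal())
        else:
            # sigma-only rescale around the group mean.
            mu_prop = mu
            sigma_prop = sigma * math.exp(step * rng.standard_normal())
        theta_prop = mu_prop + sigma_prop * z

        trial = dict(self.values)
        trial[name] = theta_prop
        affects = self._param_affects[name]
        new_ll = {label: spec.unit_loglik(label, trial) for label in affects}
        ll_delta = sum(
            float(new_ll[label].sum() - self.unit_ll[label].sum())
            for label in affects
        )
        prior_delta = (
            -0.5 * ((mu_prop - prior.mu_loc) / prior.mu_scale) ** 2
            + 0.5 * ((mu - prior.mu_loc) / prior.mu_scale) ** 2
            - 0.5 * (sigma_prop / prior.sigma_scale) ** 2
            + 0.5 * (sigma / prior.sigma_scale) ** 2
            + math.log(sigma_prop)
            - math.log(sigma)
        )
        if math.log(rng.random()) < ll_delta + prior_delta:
            self.mu[name] = mu_prop
            self.sigma[name] = sigma_prop
            self.values[name] = theta_prop
            for label in affects:
                self.unit_ll[label] = new_ll[label]
            if adapt:
                self._asis_acc[name] += 1.0

    def _update_group_sigma_slice(self, name: str) -> None:
        """Slice move on log sigma with the standardized subject effects held
        fixed (theta rescales around mu): the funnel direction the random-walk
        ancillary move crosses too slowly for weakly identified rates."""
        spec, rng = self.spec, self.rng
        prior = spec.priors[spec.param_base[name]]
        mu, sigma0 = self.mu[name], self.sigma[name]
        z = (self.values[name] - mu) / sigma0
        affects = self._param_affects[name]

        def logp(ls: float):
            s = math.exp(ls)
            trial = dict(self.values)
            trial[name] = mu + s * z
            lls = {label: spec.unit_loglik(label, trial) for label in affects}
            lp = sum(float(lls[label].sum()) for label in affects)
            lp += -0.5 * (s / prior.sigma_scale) ** 2 + ls
            return lp, trial[name], lls, s

        ls0 = math.log(sigma0)
        y = logp(ls0)[0] + math.log(rng.random())
        w = 0.5
        lo = ls0 - w * rng.random()
        hi = lo + w
        for _ in range(6):
            if logp(lo)[0] <= y:
                break
            lo -= w
        for _ in range(6):
            if logp(hi)[0] <= y:
                break
            hi += w
        for _ in range(20):
            ls = rng.uniform(lo, hi)
            lp, theta, lls, s = logp(ls)
            if lp > y:
                self.sigma[name] = s
                self.values[name] = theta
                for label in affects:
                    self.unit_ll[label] = lls[label]
                break
            if ls < ls0:
                lo = ls
            else:
                hi = ls

    def _update_group_translation(self, block: _Block, adapt: bool) -> None:
        """Directional slice sampling of a block's group means, dragging every
        subject's log-rates along (standardized effects fixed).  Directions
        are drawn from a covariance adapted over the warmup history of the
        mean vector, so moves follow the group-level ridge between
        (mu_vp - mu_vr) and mu_vcp; slice sampling steps out across the flat
        stretches of that ridge that random-walk proposals diffuse along
        too slowly."""
        spec, rng = self.spec, self.rng
        k = len(block.params)
        direction = self.mu_chol[block.name] @ rng.standard_normal(k)

        def logp(t: float):
            trial = dict(self.values)
            lp = 0.0
            for j, name in enumerate(block.params):
                prior = spec.priors[spec.param_base[name]]
                mu_prop = self.mu[name] + t * direction[j]
                trial[name] = self.values[name] + t * direction[j]
                lp += -0.5 * ((mu_prop - prior.mu_loc) / prior.mu_scale) ** 2
            lls = {label: spec.unit_loglik(label, trial) for label in block.affects}
            lp += sum(float(lls[label].sum()) for label in block.affects)
            return lp, trial, lls

        lp0, _, _ = logp(0.0)
        y = lp0 + math.log(rng.random())
        w = 1.0
        lo = -w * rng.random()
        hi = lo + w
        for _ in range(8):
            if logp(lo)[0] <= y:
                break
            lo -= w
        for _ in range(8):
            if logp(hi)[0] <= y:
                break
            hi += w
        for _ in range(30):
            t = rng.uniform(lo, hi)
            lp, trial, lls = logp(t)
            if lp > y:
                for j, name in enumerate(block.params):
                    self.mu[name] += t * direction[j]
                    self.values[name] = trial[name]
                for label in block.affects:
                    self.unit_ll[label] = lls[label]
                break
            if t < 0.0:
                lo = t
            else:
                hi = t

    def _adapt_scales(self, batch: int) -> None:
        gamma = min(0.5, 3.0 / math.sqrt(batch + 1.0))
        for name in self.sigma_steps:
            srate = self._sigma_acc[name] / _ADAPT_WINDOW
            self.sigma_steps[name] *= math.exp(gamma * (srate - _TARGET_ACCEPT))
            self.sigma_steps[name] = float(np.clip(self.sigma_steps[name], 1e-3, 3.0))
            self._sigma_acc[name] = 0.0
            arate = self._asis_acc[name] / _ADAPT_WINDOW
            self.asis_steps[name] *= math.exp(gamma * (arate - _TARGET_ACCEPT))
            self.asis_steps[name] = float(np.clip(self.asis_steps[name], 1e-3, 2.0))
            self._asis_acc[name] = 0.0

    def _adapt_covariance(self, it: int) -> None:
        """Refresh per-subject proposal covariances from recent history."""
        lo = max(0, it - 4 * _COV_WINDOW)
        for block in self.spec.blocks:
            hist = self._hist[block.name][lo : it + 1]  # (T, S, k)
            if hist.shape[0] < 50:
                continue
            k = hist.shape[2]
            centred = hist - hist.mean(axis=0, keepdims=True)
            cov = np.einsum("tsi,tsj->sij", centred, centred) / (hist.shape[0] - 1)
            cov *= 2.38**2 / k
            cov += 1e-5 * np.eye(k)
            self.chol[block.name] = np.linalg.cholesky(cov)
            mu_hist = self._mu_hist[block.name][lo : it + 1]
            mu_centred = mu_hist - mu_hist.mean(axis=0, keepdims=True)
            mu_cov = mu_centred.T @ mu_centred / (mu_hist.shape[0] - 1)
            mu_cov = mu_cov * (2.38**2 / k) + 1e-6 * np.eye(k)
            self.mu_chol[block.name] = np.linalg.cholesky(mu_cov)

    def run(self) -> Dict[str, Dict[str, np.ndarray]]:
        spec, mcmc = self.spec, self.mcmc
        out_values = {
            p: np.empty((mcmc.draws, spec.n_subjects)) for p in spec.param_names
        }
        out_mu = {p: np.empty(mcmc.draws) for p in spec.param_names}
        out_sigma = {p: np.empty(mcmc.draws) for p in spec.param_names}
        batch = 0
        for it in range(mcmc.warmup + mcmc.draws):
            warm = it < mcmc.warmup
            self._force_slice = it % 4 == 0
            for block in spec.blocks:
                self._update_block(block, adapt=warm)
            for name in spec.param_names:
                self._update_group(name, adapt=warm)
                self._update_group_asis(name, adapt=warm)
                if it % 2 == 0 and len(self._param_affects[name]) == 1:
                    self._update_group_sigma_slice(name)
            for block in spec.blocks:
                if len(block.affects) == 1:
                    self._update_group_translation(block, adapt=warm)
            if warm:
                for block in spec.blocks:
                    self._hist[block.name][it] = np.stack(
                        [self.values[p] for p in block.params], axis=1
                    )
                    self._mu_hist[block.name][it] = [
                        self.mu[p] for p in block.params
                    ]
                if (it + 1) % _ADAPT_WINDOW == 0:
                    batch += 1
                    self._adapt_scales(batch)
                if it >= 150 and (it + 1) % _COV_WINDOW == 0:
                    self._adapt_covariance(it)
            else:
                j = it - mcmc.warmup
                for p in spec.param_names:
                    out_values[p][j] = self.values[p]
                    out_mu[p][j] = self.mu[p]
                    out_sigma[p][j] = self.sigma[p]
        return {"values": out_values, "mu": out_mu, "sigma": out_sigma}


def run_chains(spec: ModelSpec, mcmc: McmcConfig) -> Dict[str, Dict[str, np.ndarray]]:
    """Run all chains; returns stacked arrays with a leading chain dimension."""
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    chains = [GibbsSampler(spec, mcmc, np.random.default_rng(s)).run() for s in seeds]
    stacked: Dict[str, Dict[str, np.ndarray]] = {"values": {}, "mu": {}, "sigma": {}}
    for kind in stacked:
        for name in chains[0][kind]:
            stacked[kind][name] = np.stack([c[kind][name] for c in chains])
    return stacked
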