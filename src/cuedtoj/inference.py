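"""Hierarchical Bayesian estimation of race-model rates from TOJ counts.

`HierarchicalTOJModel` is a scikit-learn-style estimator: construct with the
model variant and sampler settings, call :meth:`fit` on a tidy count dataset,
then read fitted attributes (``posterior_``, ``summary_``, ``diagnostics_``)
or call :meth:`contrast` / :meth:`posterior_predict`.  Group-level rate
parameters are reported on the Hz scale as the group median ``exp(mu)`` of
the log-normal hierarchy, named ``v_p_mu[<condition>]`` etc.; log-scale
spreads are ``v_p_sigma[<condition>]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Union

import arviz as az
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._sampler import DEFAULT_PRIORS, GibbsSampler, McmcConfig, ModelSpec, Prior, run_chains
from .config import DEFAULT_CONFIG, ModelConfig
from .data import TOJDataset
from .design import ExperimentDesign

__all__ = [
    "HierarchicalTOJModel",
    "PosteriorResult",
    "ContrastSummary",
    "McmcConfig",
    "fit",
    "contrast",
    "posterior_predict",
]


@dataclass(frozen=True)
class ContrastSummary:
    """Draw-wise difference between two posterior parameters."""

    name: str
    mean: float
    hdi_low: float
    hdi_high: float
    draws: np.ndarray

    @property
    def excludes_zero(self) -> bool:
        return self.hdi_low > 0.0 or self.hdi_high < 0.0


@dataclass
class PosteriorResult:
    """Posterior draws, summaries, diagnostics, and model metadata."""

    idata: az.InferenceData
    variant: str
    config: ModelConfig
    subjects: List
    condition_coa: Dict[str, float]  # cued label -> COA (ms); nocue excluded
    nocue_label: Optional[str]
    spec: ModelSpec
    diagnostics: Dict[str, float]

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics["max_rhat"] <= self.diagnostics["rhat_threshold"])

    def summary(self, group_only: bool = True) -> pd.DataFrame:
        names = [v for v in self.idata.posterior.data_vars]
        if group_only:
            names = [v for v in names if "_mu" in v or "_sigma" in v]
        return az.summary(self.idata, var_names=names, hdi_prob=0.95, kind="stats")

    def parameter_draws(self, name: str) -> np.ndarray:
        """Flattened (chain*draw, ...) draws of one posterior variable."""
        post = self.idata.posterior
        if name not in post:
            raise KeyError(
                f"unknown parameter {name!r}; available: {sorted(post.data_vars)}"
            )
        arr = post[name].to_numpy()
        return arr.reshape((-1,) + arr.shape[2:])

    def contrast(self, a: str, b: str) -> ContrastSummary:
        """Posterior difference ``a - b`` with mean and 95% HDI."""
        da, db = self.parameter_draws(a), self.parameter_draws(b)
        diff = da - db
        if diff.ndim != 1:
            raise ValueError("contrast expects scalar (group-level) parameters")
        if np.allclose(diff, 0.0):
            lo = hi = 0.0
        else:
            lo, hi = az.hdi(diff, hdi_prob=0.95)
        return ContrastSummary(
            name=f"{a} - {b}",
            mean=float(diff.mean()),
            hdi_low=float(lo),
            hdi_high=float(hi),
            draws=diff,
        )

    def subject_rate_draws(self, label: str) -> Dict[str, np.ndarray]:
        """(chain, draw, subject) Hz draws of v_p, v_r, v_cp, v_neutral for a
        cued condition under this result's variant."""
        post = self.idata.posterior
        values = {
            name: np.log(post[name].to_numpy()) for name in self.spec.param_names
        }
        vp, vr, vcp, vn = self.spec.unit_rates(label, values)
        return {"v_p": vp, "v_r": vr, "v_cp": vcp, "v_neutral": vn}


class HierarchicalTOJModel(BaseEstimator):
    """Hierarchical Bayesian race model of cued temporal-order judgments.

    Parameters
    ----------
    variant:
        ``"full"`` (target-rate effects and cue-as-probe confusions),
        ``"rates_only"`` (v_cp fixed at 0), or ``"confusion_only"``
        (v_p = v_r = v_neutral, only the confusion rate free).
    chains, warmup, draws, seed:
        Sampler settings; 4 chains by default.
    rhat_threshold:
        Split-chain convergence threshold; exceeding it flags (not fails)
        the result.
    config:
        Race-model configuration (t0, regime rule).
    priors:
        Optional overrides of the group-level priors, keyed by base parameter
        name ("v_p", "v_r", "v_cp", "v_neutral").
    """

    def __init__(
        self,
        variant: str = "full",
        chains: int = 4,
        warmup: int = 600,
        draws: int = 600,
        seed: int = 0,
        rhat_threshold: float = 1.01,
        config: ModelConfig = DEFAULT_CONFIG,
        priors: Optional[Dict[str, Prior]] = None,
    ) -> None:
        self.variant = variant
        self.chains = chains
        self.warmup = warmup
        self.draws = draws
        self.seed = seed
        self.rhat_threshold = rhat_threshold
        self.config = config
        self.priors = priors

    # -- estimator API ------------------------------------------------------

    def fit(self, dataset: Union[TOJDataset, pd.DataFrame], y=None) -> "HierarchicalTOJModel":
        if isinstance(dataset, pd.DataFrame):
            dataset = TOJDataset(dataset)
        mcmc = McmcConfig(
            chains=self.chains,
            warmup=self.warmup,
            draws=self.draws,
            seed=self.seed,
            rhat_threshold=self.rhat_threshold,
        )
        spec = ModelSpec(dataset, self.variant, self.config, self.priors)
        stacked = run_chains(spec, mcmc)

        posterior = {}
        for name in spec.param_names:
            posterior[name] = np.exp(stacked["values"][name])
            posterior[_group_name(name, "mu")] = np.exp(stacked["mu"][name])
            posterior[_group_name(name, "sigma")] = stacked["sigma"][name]
        coords = {"subject": spec.subjects}
        dims = {name: ["subject"] for name in spec.param_names}
        idata = az.from_dict(posterior=posterior, coords=coords, dims=dims)

        group_vars = [v for v in posterior if "_mu" in v or "_sigma" in v]
        rhat = az.rhat(idata, var_names=group_vars)
        ess = az.ess(idata, var_names=group_vars)
        diagnostics = {
            "max_rhat": float(rhat.to_array().max()),
            "min_ess_bulk": float(ess.to_array().min()),
            "rhat_threshold": self.rhat_threshold,
        }

        self.posterior_ = PosteriorResult(
            idata=idata,
            variant=self.variant,
            config=self.config,
            subjects=spec.subjects,
            condition_coa={l: spec.units[l].coa for l in spec.cued_labels},
            nocue_label=spec.nocue_label,
            spec=spec,
            diagnostics=diagnostics,
        )
        self.summary_ = self.posterior_.summary()
        self.diagnostics_ = diagnostics
        self.converged_ = self.posterior_.converged
        return self

    def contrast(self, a: str, b: str) -> ContrastSummary:
        self._check_fitted()
        return self.posterior_.contrast(a, b)

    def posterior_predict(
        self,
        dataset: Union[TOJDataset, pd.DataFrame, None] = None,
        n_draws: int = 200,
        band: float = 0.95,
        seed: int = 0,
    ) -> pd.DataFrame:
        """Posterior-predictive count bands per subject x condition x SOA.

        Predicts for the fitted dataset's cells by default, or for the cells
        of a compatible dataset (same subjects and condition labels).
        Returns the central ``band`` interval and median of predictive
        ``Binomial(n, p)`` draws, plus the posterior-mean success rate.
        """
        self._check_fitted()
        result = self.posterior_
        spec = result.spec
        if dataset is None:
            pred_spec = spec
        else:
            if isinstance(dataset, ExperimentDesign):
                dataset = _design_to_empty_dataset(dataset, spec.subjects)
            if isinstance(dataset, pd.DataFrame):
                dataset = TOJDataset(dataset)
            pred_spec = ModelSpec(dataset, self.variant, self.config, self.priors)
            if pred_spec.subjects != spec.subjects:
                raise ValueError("dataset subjects do not match the fitted result")
            unknown = set(pred_spec.units) - set(spec.units)
            if unknown:
                raise ValueError(f"conditions not in the fitted result: {sorted(unknown)}")
        units = pred_spec.units

        rng = np.random.default_rng(seed)
        post = result.idata.posterior
        values = {
            name: np.log(post[name].to_numpy()) for name in spec.param_names
        }
        # Thin to at most n_draws total draws.
        chains, draws = next(iter(values.values())).shape[:2]
        total = chains * draws
        take = np.linspace(0, total - 1, min(n_draws, total)).astype(int)
        flat = {
            name: arr.reshape(total, -1)[take] for name, arr in values.items()
        }
        lo_q, hi_q = (1 - band) / 2, 1 - (1 - band) / 2

        frames = []
        for label, unit in units.items():
            p = pred_spec.cell_probabilities(label, flat)  # (take, cells)
            ks = rng.binomial(unit.n.astype(int), p)
            frames.append(
                pd.DataFrame(
                    {
                        "condition_label": label,
                        "subject_id": np.asarray(spec.subjects)[unit.subj],
                        "soa_ms": unit.soa,
                        "n_trials": unit.n.astype(int),
                        "p_mean": p.mean(axis=0),
                        "k_median": np.median(ks, axis=0),
                        "k_lo": np.quantile(ks, lo_q, axis=0),
                        "k_hi": np.quantile(ks, hi_q, axis=0),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    def classify_disadvantageous(self, vcp_quantile: float = 0.75, vcp_cut: float = 2.0) -> pd.DataFrame:
        """Optional, transparent subject filter (off by default everywhere).

        A subject is classified disadvantageous when the posterior mean of
        (v_p - v_r) is negative in every cued condition and the posterior
        mass of v_cp concentrates near zero (the ``vcp_quantile`` quantile
        below ``vcp_cut`` Hz) in every cued condition.
        """
        self._check_fitted()
        result = self.posterior_
        rows = []
        for i, subject in enumerate(result.subjects):
            neg_all, low_cp_all = True, True
            for label in result.condition_coa:
                draws = result.subject_rate_draws(label)
                diff = draws["v_p"][..., i] - draws["v_r"][..., i]
                neg_all &= bool(diff.mean() < 0)
                low_cp_all &= bool(
                    np.quantile(draws["v_cp"][..., i], vcp_quantile) < vcp_cut
                )
            rows.append(
                {
                    "subject_id": subject,
                    "disadvantageous": neg_all and low_cp_all,
                }
            )
        return pd.DataFrame(rows)

    def _check_fitted(self) -> None:
        if not hasattr(self, "posterior_"):
            raise RuntimeError("call fit() first")


def _design_to_empty_dataset(design: ExperimentDesign, subjects: List) -> TOJDataset:
    rows = []
    for subject in subjects:
        for cond in design.conditions:
            for soa in sorted(cond.repetitions):
                rows.append(
                    {
                        "subject_id": subject,
                        "condition_label": cond.label,
                        "soa_ms": float(soa),
                        "coa_ms": np.nan if cond.coa is None else cond.coa,
                        "cld_px": np.nan if cond.cld is None else cond.cld,
                        "n_trials": cond.repetitions[soa],
                        "n_probe_first": 0,
                    }
                )
    return TOJDataset(pd.DataFrame(rows))


def _group_name(block_name: str, kind: str) -> str:
    if "[" in block_name:
        base, rest = block_name.split("[", 1)
        return f"{base}_{kind}[{rest}"
    return f"{block_name}_{kind}"


# -- thin functional wrappers ------------------------------------------------


def fit(
    dataset: Union[TOJDataset, pd.DataFrame],
    variant: str = "full",
    mcmc: Optional[McmcConfig] = None,
    config: ModelConfig = DEFAULT_CONFIG,
    priors: Optional[Dict[str, Prior]] = None,
) -> PosteriorResult:
    mcmc = mcmc or McmcConfig()
    est = HierarchicalTOJModel(
        variant=variant,
        chains=mcmc.chains,
        warmup=mcmc.warmup,
        draws=mcmc.draws,
        seed=mcmc.seed,
        rhat_threshold=mcmc.rhat_threshold,
        config=config,
        priors=priors,
    )
    return est.fit(dataset).posterior_


def contrast(result: PosteriorResult, a: str, b: str) -> ContrastSummary:
    return result.contrast(a, b)


def posterior_predict(
    result: PosteriorResult,
    dataset: Union[TOJDataset, pd.DataFrame, None] = None,
    n_draws: int = 200,
    band: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    est = HierarchicalTOJModel(variant=result.variant, config=result.config)
    est.posterior_ = result
    return est.posterior_predict(dataset, n_draws=n_draws, band=band, seed=seed)
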