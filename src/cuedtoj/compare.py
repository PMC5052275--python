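"""Nested model comparison: full vs rates-only vs confusion-only.

Each variant is fitted to the data and scored by approximate leave-one-out
cross-validated predictive density (PSIS-LOO, computed by arviz from
pointwise posterior log-likelihoods), with standard-error-aware ranking.
The default mode compares per cued condition (fitting the no-cue condition
alongside for the shared neutral rate, scoring only the cued condition's
cells); a joint mode scores all cued cells at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Union

import arviz as az
import numpy as np
import pandas as pd

from ._sampler import McmcConfig, ModelSpec
from .config import DEFAULT_CONFIG, ModelConfig
from .data import TOJDataset
from .inference import HierarchicalTOJModel, PosteriorResult

__all__ = ["ComparisonReport", "compare"]

CRITERION = "PSIS-LOO expected log predictive density (arviz)"

#: Split-chain convergence gate for comparison fits.  Fits whose worst group
#: R-hat exceeds this abort the comparison for that condition.
DEFAULT_CONVERGENCE_GATE = 1.2


@dataclass
class ComparisonReport:
    """Per-condition variant scores, rankings, and pairwise differences."""

    mode: str
    criterion: str
    tables: Dict[str, pd.DataFrame]
    pairwise: Dict[str, pd.DataFrame]
    failures: Dict[str, str] = field(default_factory=dict)

    def ranking(self, condition: str) -> List[str]:
        """Variant names, best first."""
        return self.tables[condition].index.tolist()

    def best(self, condition: str) -> str:
        return self.ranking(condition)[0]

    def worst(self, condition: str) -> str:
        return self.ranking(condition)[-1]

    def to_text(self) -> str:
        lines = [f"Model comparison ({self.mode}); criterion: {self.criterion}", ""]
        for cond, table in self.tables.items():
            lines.append(f"== {cond} ==")
            lines.append(table.to_string())
            lines.append("")
        for cond, msg in self.failures.items():
            lines.append(f"== {cond} == ABORTED: {msg}")
        return "\n".join(lines)


def _pointwise_loglik(
    result: PosteriorResult, labels: Sequence[str], max_draws: int = 1600
) -> np.ndarray:
    """(chains, draws', cells) log-likelihood for the given condition labels."""
    spec = result.spec
    post = result.idata.posterior
    values = {name: np.log(post[name].to_numpy()) for name in spec.param_names}
    chains, draws = next(iter(values.values())).shape[:2]
    per_chain = max(1, min(draws, max_draws // chains))
    take = np.linspace(0, draws - 1, per_chain).astype(int)
    thinned = {name: arr[:, take] for name, arr in values.items()}
    flat = {
        name: arr.reshape(chains * per_chain, -1) for name, arr in thinned.items()
    }
    parts = []
    for label in labels:
        ll = spec.pointwise_loglik(label, flat)  # (chain*draws', cells)
        parts.append(ll)
    cells = np.concatenate(parts, axis=-1)
    return cells.reshape(chains, per_chain, -1)


#: Free subject-level rate parameters per cued condition; used by the
#: one-standard-error parsimony rule to order nested variants.
_COMPLEXITY = {"confusion_only": 1, "rates_only": 2, "full": 3}


def _paired_dse(a: np.ndarray, b: np.ndarray) -> float:
    diff = a - b
    return float(np.sqrt(diff.size * np.var(diff)))


def _rank_with_parsimony(
    elpds: Dict[str, float], pointwise: Dict[str, np.ndarray]
) -> List[str]:
    """ELPD ordering with a one-standard-error rule for nested variants.

    Variants are sorted by ELPD; a more complex variant only outranks a
    simpler one when its advantage exceeds the paired difference SE
    (otherwise predictive performance is indistinguishable and the simpler
    model wins, the standard 1-SE parsimony convention)."""
    order = sorted(elpds, key=elpds.get, reverse=True)
    changed = True
    while changed:
        changed = False
        for i in range(len(order) - 1):
            a, b = order[i], order[i + 1]
            if _COMPLEXITY[a] > _COMPLEXITY[b]:
                gap = elpds[a] - elpds[b]
                if gap <= _paired_dse(pointwise[a], pointwise[b]):
                    order[i], order[i + 1] = b, a
                    changed = True
    return order


def _loo_frame(
    fits: Dict[str, PosteriorResult], score_labels: Sequence[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rank variants by PSIS-LOO; return (score table, pairwise differences)."""
    elpds: Dict[str, float] = {}
    ses: Dict[str, float] = {}
    pointwise: Dict[str, np.ndarray] = {}
    for variant, result in fits.items():
        ll = _pointwise_loglik(result, score_labels)
        # az.loo requires a posterior group; a dummy variable of matching
        # chain/draw shape satisfies it (ESS-based subsampling is not used).
        idata = az.from_dict(
            posterior={"_dummy": np.zeros(ll.shape[:2])},
            log_likelihood={"y": ll},
        )
        loo = az.loo(idata, pointwise=True)
        elpds[variant] = float(loo.elpd_loo)
        ses[variant] = float(loo.se)
        pointwise[variant] = np.asarray(loo.loo_i)

    order = _rank_with_parsimony(elpds, pointwise)
    best = order[0]
    rows = []
    for rank, variant in enumerate(order):
        rows.append(
            {
                "rank": rank,
                "elpd_loo": elpds[variant],
                "se": ses[variant],
                "elpd_diff": elpds[best] - elpds[variant],
                "dse": _paired_dse(pointwise[best], pointwise[variant]),
            }
        )
    table = pd.DataFrame(rows, index=pd.Index(order, name="variant"))

    pair = pd.DataFrame(
        {
            a: {b: elpds[a] - elpds[b] for b in order}
            for a in order
        }
    ).T
    pair.index.name = "variant"
    return table, pair


def compare(
    dataset: Union[TOJDataset, pd.DataFrame],
    variants: Sequence[str] = ("full", "rates_only", "confusion_only"),
    mcmc: Optional[McmcConfig] = None,
    config: ModelConfig = DEFAULT_CONFIG,
    mode: str = "per_condition",
    convergence_gate: float = DEFAULT_CONVERGENCE_GATE,
) -> ComparisonReport:
    """Fit and rank nested model variants.

    Parameters
    ----------
    variants:
        Subset of {"full", "rates_only", "confusion_only"}; a single variant
        yields a trivial rank-1 report.
    mode:
        "per_condition" (default) fits no-cue + one cued condition at a time
        and scores the cued cells; "joint" fits everything at once and scores
        all cued cells together.
    convergence_gate:
        Worst allowed group-level split-chain R-hat; a fit beyond it aborts
        the comparison for that condition with a diagnostic (the result is
        recorded in ``failures``, not silently dropped).
    """
    if isinstance(dataset, pd.DataFrame):
        dataset = TOJDataset(dataset)
    if not variants:
        raise ValueError("need at least one variant")
    for v in variants:
        if v not in ModelSpec.VARIANTS:
            raise ValueError(f"unknown variant {v!r}")
    mcmc = mcmc or McmcConfig()
    if mode not in ("per_condition", "joint"):
        raise ValueError(f"mode must be per_condition or joint, got {mode!r}")

    probe_spec = ModelSpec(dataset, "full", config)
    cued = probe_spec.cued_labels
    nocue = probe_spec.nocue_label

    groups: Dict[str, List[str]]
    if mode == "per_condition":
        groups = {label: [label] for label in cued}
    else:
        groups = {"all_conditions": list(cued)}

    tables: Dict[str, pd.DataFrame] = {}
    pairwise: Dict[str, pd.DataFrame] = {}
    failures: Dict[str, str] = {}
    for group_name, score_labels in groups.items():
        fit_labels = ([nocue] if nocue else []) + (
            score_labels if mode == "per_condition" else list(cued)
        )
        sub = dataset.subset(fit_labels)
        fits: Dict[str, PosteriorResult] = {}
        aborted = None
        for variant in variants:
            est = HierarchicalTOJModel(
                variant=variant,
                chains=mcmc.chains,
                warmup=mcmc.warmup,
                draws=mcmc.draws,
                seed=mcmc.seed,
                rhat_threshold=mcmc.rhat_threshold,
                config=config,
            ).fit(sub)
            rhat = est.diagnostics_["max_rhat"]
            if rhat > convergence_gate:
                aborted = (
                    f"variant {variant!r} did not converge "
                    f"(max group R-hat {rhat:.3f} > gate {convergence_gate})"
                )
                break
            fits[variant] = est.posterior_
        if aborted:
            failures[group_name] = aborted
            continue
        tables[group_name], pairwise[group_name] = _loo_frame(fits, score_labels)

    return ComparisonReport(
        mode=mode, criterion=CRITERION, tables=tables, pairwise=pairwise,
        failures=failures,
    )
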