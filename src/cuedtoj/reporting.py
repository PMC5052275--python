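"""Figure-style outputs: posterior density panels, posterior-predictive
curves, and cue-contribution decomposition plots.

All judgment curves are plotted on data normalized into [0, 1]; decomposition
panels shade the portion of the "probe first" probability carried by
cue-as-probe categorizations.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, ModelConfig
from .data import TOJDataset
from .inference import PosteriorResult, posterior_predict
from .model import RateSet, TrialCondition, decompose_contributions

__all__ = [
    "decomposition_curve",
    "plot_group_densities",
    "plot_posterior_predictive",
    "plot_decomposition",
    "render_reports",
]


def decomposition_curve(
    rates: RateSet,
    coa: Optional[float],
    soa_grid: Sequence[float],
    config: ModelConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Model curve with its cue/probe split over an SOA grid."""
    rows = []
    for soa in soa_grid:
        via_cue, via_probe = decompose_contributions(
            rates, TrialCondition(float(soa), coa), config
        )
        rows.append(
            {
                "soa_ms": float(soa),
                "p_probe_first": via_cue + via_probe,
                "p_via_cue": via_cue,
                "p_via_probe": via_probe,
            }
        )
    return pd.DataFrame(rows)


def plot_group_densities(result: PosteriorResult, path: Path) -> Path:
    """Posterior density panels of the group-level rates, one row per
    condition, with 95% HDI brackets."""
    import arviz as az

    conds = [None] + list(result.condition_coa)
    fig, axes = plt.subplots(
        len(conds), 1, figsize=(7, 2.2 * len(conds)), squeeze=False
    )
    for row, cond in enumerate(conds):
        ax = axes[row, 0]
        if cond is None:
            names = ["v_neutral_mu"]
            title = result.nocue_label or "no-cue"
        else:
            names = [
                n
                for n in (f"v_p_mu[{cond}]", f"v_r_mu[{cond}]", f"v_cp_mu[{cond}]")
                if n in result.idata.posterior
            ]
            title = cond
        for name in names:
            draws = result.parameter_draws(name)
            az.plot_kde(draws, ax=ax, label=name.split("_mu")[0], plot_kwargs={})
            lo, hi = az.hdi(draws, hdi_prob=0.95)
            ax.plot([lo, hi], [0, 0], lw=3)
        ax.set_title(title)
        ax.set_xlabel("rate (Hz)")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_posterior_predictive(
    result: PosteriorResult,
    dataset: TOJDataset,
    path: Path,
    subjects: Optional[Sequence] = None,
) -> Path:
    """Normalized predictive bands with the raw relative frequencies."""
    pred = posterior_predict(result, dataset)
    subjects = list(subjects or result.subjects[:3])
    conds = dataset.conditions
    fig, axes = plt.subplots(
        len(subjects), len(conds),
        figsize=(2.6 * len(conds), 2.2 * len(subjects)),
        squeeze=False, sharey=True,
    )
    obs = dataset.table
    for i, subject in enumerate(subjects):
        for j, cond in enumerate(conds):
            ax = axes[i, j]
            sel = pred[
                (pred.subject_id == subject) & (pred.condition_label == cond)
            ].sort_values("soa_ms")
            with np.errstate(invalid="ignore", divide="ignore"):
                norm = sel.n_trials.to_numpy().astype(float)
                norm[norm == 0] = np.nan
                ax.fill_between(
                    sel.soa_ms, sel.k_lo / norm, sel.k_hi / norm, alpha=0.3
                )
                ax.plot(sel.soa_ms, sel.p_mean, lw=1.5)
            o = obs[
                (obs.subject_id == subject) & (obs.condition_label == cond)
            ].sort_values("soa_ms")
            with np.errstate(invalid="ignore", divide="ignore"):
                ax.plot(o.soa_ms, o.n_probe_first / o.n_trials, "k.", ms=4)
            if i == 0:
                ax.set_title(cond, fontsize=9)
            if j == 0:
                ax.set_ylabel(f"subj {subject}\nP(probe first)", fontsize=8)
            ax.set_ylim(-0.05, 1.05)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def plot_decomposition(
    rates: RateSet,
    coas: Sequence[float],
    path: Path,
    soa_grid: Optional[Sequence[float]] = None,
    config: ModelConfig = DEFAULT_CONFIG,
) -> Path:
    """Model curves per COA with the cue-borne contribution shaded."""
    soa_grid = np.asarray(
        soa_grid if soa_grid is not None else np.linspace(-150, 250, 161)
    )
    fig, axes = plt.subplots(
        1, len(coas), figsize=(3.0 * len(coas), 2.6), squeeze=False, sharey=True
    )
    for j, coa in enumerate(coas):
        ax = axes[0, j]
        df = decomposition_curve(rates, coa, soa_grid, config)
        ax.fill_between(df.soa_ms, 0, df.p_via_cue, alpha=0.5, label="via cue")
        ax.plot(df.soa_ms, df.p_probe_first, lw=1.5, label="P(probe first)")
        ax.set_title(f"COA = {coa:g} ms", fontsize=9)
        ax.set_xlabel("SOA (ms)")
        ax.set_ylim(0, 1)
        if j == 0:
            ax.set_ylabel("probability")
            ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def render_reports(
    results: Dict[str, PosteriorResult],
    datasets: Dict[str, TOJDataset],
    output_dir: str | Path,
    decomposition_rates: Optional[RateSet] = None,
    decomposition_coas: Sequence[float] = (40.0, 80.0, 140.0),
    fmt: str = "svg",
) -> List[Path]:
    """Write the full report set for one or more fitted results.

    Raises ``ValueError`` on an empty result set (no files are produced).
    """
    if not results:
        raise ValueError("no results to report")
    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    for name, result in results.items():
        written.append(
            plot_group_densities(result, output_dir / f"{name}_densities.{fmt}")
        )
        if name in datasets:
            written.append(
                plot_posterior_predictive(
                    result, datasets[name], output_dir / f"{name}_predictive.{fmt}"
                )
            )
        result.summary().to_csv(output_dir / f"{name}_summary.csv")
    if decomposition_rates is not None:
        written.append(
            plot_decomposition(
                decomposition_rates,
                decomposition_coas,
                output_dir / f"decomposition.{fmt}",
            )
        )
    return written
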