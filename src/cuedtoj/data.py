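"""Tidy TOJ count data: container, validation, I/O, and synthetic generation.

The canonical schema is one row per subject x condition x SOA:

    subject_id, condition_label, soa_ms, coa_ms (empty for no-cue), cld_px,
    n_trials, n_probe_first

Datasets written by :func:`write_dataset` carry a JSON sidecar recording the
design, population spec, and seed for full provenance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, ModelConfig
from .design import ExperimentDesign
from .model import probe_first_probability_arrays
from .population import PopulationSpec, SubjectRates, sample_population

__all__ = ["TOJDataset", "generate_dataset", "read_dataset", "write_dataset"]

COLUMNS = [
    "subject_id",
    "condition_label",
    "soa_ms",
    "coa_ms",
    "cld_px",
    "n_trials",
    "n_probe_first",
]


@dataclass
class TOJDataset:
    """Per subject x condition x SOA counts of "probe first" responses."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset is missing columns {missing}")
        if len(df) == 0:
            raise ValueError("dataset is empty")
        n = df["n_trials"].to_numpy()
        k = df["n_probe_first"].to_numpy()
        if not np.all((n >= 0) & (k >= 0) & (k <= n)):
            raise ValueError("counts must satisfy 0 <= n_probe_first <= n_trials")
        if not np.all(np.isfinite(df["soa_ms"].to_numpy(dtype=float))):
            raise ValueError("soa_ms must be finite")
        coa = df["coa_ms"].to_numpy(dtype=float)
        nocue_labels = df.loc[~np.isfinite(coa), "condition_label"].unique()
        if len(nocue_labels) > 1:
            raise ValueError("at most one no-cue condition is permitted")
        if np.any(coa[np.isfinite(coa)] < 0):
            raise ValueError("coa_ms must be >= 0 where present")
        counts = (
            df[df["n_trials"] > 0]
            .groupby(["subject_id", "condition_label"])["soa_ms"]
            .nunique()
        )
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise ValueError(
                f"every (subject, condition) needs >= 2 distinct SOAs; violated by {bad}"
            )

    @property
    def subjects(self) -> List:
        return sorted(self.table["subject_id"].unique().tolist())

    @property
    def conditions(self) -> List[str]:
        return list(dict.fromkeys(self.table["condition_label"]))

    def subset(self, conditions: List[str]) -> "TOJDataset":
        sub = self.table[self.table["condition_label"].isin(conditions)]
        return TOJDataset(sub.reset_index(drop=True))


def generate_dataset(
    design: ExperimentDesign,
    population: PopulationSpec | List[SubjectRates],
    seed: int = 0,
    config: ModelConfig = DEFAULT_CONFIG,
) -> TOJDataset:
    """Binomial synthetic TOJ counts from the race model.

    For each subject x condition x SOA cell, the success probability comes
    from the closed-form model at that subject's rates and
    ``k ~ Binomial(n, p)``.  ``population`` may be a :class:`PopulationSpec`
    (subjects are sampled with a seed spawned from ``seed``) or an already
    sampled subject list.
    """
    seq = np.random.SeedSequence(seed)
    pop_seed, resp_seed = seq.spawn(2)
    if isinstance(population, PopulationSpec):
        subjects = sample_population(
            population, design, seed=int(pop_seed.generate_state(1)[0] % (2**31))
        )
    else:
        subjects = population
        if len(subjects) != design.n_subjects:
            raise ValueError("population size does not match design.n_subjects")

    rng = np.random.default_rng(resp_seed)
    rows = []
    for subj in subjects:
        for cond in design.conditions:
            if cond.coa is None:
                v_p = v_r = v_cp = 0.0
                coa = np.nan
            else:
                rs = subj.conditions[cond.label]
                v_p, v_r, v_cp = rs.v_p, rs.v_r, rs.v_cp
                coa = cond.coa
            soas = np.array(sorted(cond.repetitions), dtype=float)
            ns = np.array([cond.repetitions[s] for s in sorted(cond.repetitions)])
            p = probe_first_probability_arrays(
                v_p, v_r, v_cp, subj.v_neutral, soas, coa,
                t0=config.t0_ms, regime_rule=config.regime_rule,
            )
            ks = rng.binomial(ns, p)
            for soa, n, k in zip(soas, ns, ks):
                rows.append(
                    {
                        "subject_id": subj.subject,
                        "condition_label": cond.label,
                        "soa_ms": soa,
                        "coa_ms": coa,
                        "cld_px": np.nan if cond.cld is None else cond.cld,
                        "n_trials": int(n),
                        "n_probe_first": int(k),
                    }
                )
    return TOJDataset(pd.DataFrame(rows, columns=COLUMNS))


def write_dataset(
    dataset: TOJDataset,
    path: str | Path,
    provenance: Optional[dict] = None,
) -> Path:
    """Write the dataset as CSV (+ ``<stem>.provenance.json`` if given)."""
    path = Path(path)
    dataset.table.to_csv(path, index=False)
    if provenance is not None:
        sidecar = path.with_suffix(".provenance.json")
        sidecar.write_text(json.dumps(provenance, indent=2, default=_jsonable))
    return path


def read_dataset(path: str | Path) -> TOJDataset:
    df = pd.read_csv(path)
    return TOJDataset(df)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
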