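import warnings

import numpy as np
import pytest

from cuedtoj.data import generate_dataset
from cuedtoj.design import ExperimentDesign, make_design
from cuedtoj.inference import HierarchicalTOJModel
from cuedtoj.population import ConditionRates, PopulationSpec, RateDistribution

warnings.filterwarnings("ignore", message="ArviZ is undergoing")
warnings.filterwarnings("ignore", message="Estimated shape parameter")


def subdesign(preset: str, labels, n_subjects: int) -> ExperimentDesign:
    """Preset design restricted to a subset of condition labels."""
    full = make_design(preset, n_subjects=n_subjects)
    conds = [c for c in full.conditions if c.label in labels]
    return ExperimentDesign(f"{preset}-sub", conds, n_subjects)


@pytest.fixture(scope="session")
def coa80_population():
    """Beneficial-cueing population for a no-cue + COA=80 design."""
    return PopulationSpec(
        v_neutral=RateDistribution(29.0),
        beneficial={
            "COA=80": ConditionRates(
                RateDistribution(69.0),
                RateDistribution(22.0),
                RateDistribution(5.0, 0.5),
            )
        },
        weight_disadvantageous=0.0,
    )


@pytest.fixture(scope="session")
def coa80_subjects(coa80_population):
    from cuedtoj.population import sample_population

    design = subdesign("exp1", ("no-cue", "COA=80"), 12)
    return sample_population(coa80_population, design, seed=19)


@pytest.fixture(scope="session")
def coa80_dataset(coa80_subjects):
    design = subdesign("exp1", ("no-cue", "COA=80"), 12)
    return generate_dataset(design, coa80_subjects, seed=11)


@pytest.fixture(scope="session")
def coa80_fit(coa80_dataset):
    """One reusable hierarchical fit (full variant) at small scale."""
    est = HierarchicalTOJModel(
        variant="full", chains=4, warmup=600, draws=600, seed=2
    )
    return est.fit(coa80_dataset)


@pytest.fixture(scope="session")
def ior_dataset():
    """IOR-patterned data: reference faster than probe, confusions present."""
    design = subdesign("exp1", ("no-cue", "COA=140"), 30)
    population = PopulationSpec(
        v_neutral=RateDistribution(29.0),
        beneficial={
            "COA=140": ConditionRates(
                RateDistribution(58.0),
                RateDistribution(113.0),
                RateDistribution(10.0, 0.5),
            )
        },
        weight_disadvantageous=0.0,
    )
    return generate_dataset(design, population, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
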