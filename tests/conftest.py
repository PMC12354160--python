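import numpy as np
import pytest

from ctdna_horizon.genome import GenomeModel
from ctdna_horizon.simulate import (
    ErrorModel,
    ParticipantTruth,
    ScenarioConfig,
    TumorProfile,
    simulate_cohort,
)
from ctdna_horizon.variants import Variant


@pytest.fixture
def genome() -> GenomeModel:
    return GenomeModel.synthetic()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def small_config() -> ScenarioConfig:
    """A fast 3-case / 2-control scenario with one strong shedder."""
    return ScenarioConfig(
        n_cases=3,
        n_controls=2,
        seed=11,
        plasma_templates=300,
        leukocyte_templates=1200,
        n_germline=8,
        shedders=(
            TumorProfile.from_early_maf(
                0.05, n_driver_mutations=2, n_passenger_mutations=20,
                fold_decrease=10.0,
            ),
        ),
    )


@pytest.fixture
def small_cohort(small_config):
    return simulate_cohort(small_config)


def make_clean_somatic(genome: GenomeModel, rng: np.random.Generator,
                       n: int, cell_fraction: float = 1.0) -> list[Variant]:
    """Clonal somatic mutations at unflagged, non-CpG-transition sites."""
    out = []
    while len(out) < n:
        site = genome.random_site(rng)
        v = Variant(site, "somatic", cell_fraction)
        if not v.flags:
            out.append(v)
    return out
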