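import numpy as np
import pandas as pd
import pytest

from twinace import (
    StratumSim,
    SimulationConfig,
    VarianceComponents,
    default_config,
    simulate_dataset,
)

#: pooled variance components used throughout as generating truth
POOLED = VarianceComponents(0.43, 0.31, 0.26)


def two_cohort_config(n_per_group: int = 5000, seed: int = 21) -> SimulationConfig:
    """Two broad birth cohorts with different generating heritabilities.

    Early cohort (1900-1949) a2=0.44/c2=0.31, late cohort (1950-1989)
    a2=0.38/c2=0.34 — a drop in heritability with a compensating rise in
    shared environment.  Survey year 2020 keeps even the youngest twins
    past age 30.
    """
    counts = {
        "MZM": n_per_group, "MZF": n_per_group,
        "DZM": n_per_group, "DZF": n_per_group, "OSDZ": n_per_group // 2,
    }
    strata = [
        StratumSim(
            registry="EARLY", region="Europe", pair_counts=counts,
            components=VarianceComponents(0.44, 0.31, 0.25),
            birth_year_range=(1900, 1949), survey_year=2020,
        ),
        StratumSim(
            registry="LATE", region="Europe", pair_counts=counts,
            components=VarianceComponents(0.38, 0.34, 0.28),
            birth_year_range=(1950, 1989), survey_year=2020,
        ),
    ]
    return SimulationConfig(strata=strata, seed=seed)


@pytest.fixture(scope="session")
def small_dataset():
    """Small default-mix registry dataset shared across tests."""
    return simulate_dataset(default_config(n_pairs=800, seed=11))


@pytest.fixture(scope="session")
def small_records(small_dataset):
    return small_dataset.records


def double_entry_corr(pairs: np.ndarray) -> float:
    x = np.concatenate([pairs[:, 0], pairs[:, 1]])
    y = np.concatenate([pairs[:, 1], pairs[:, 0]])
    return float(np.corrcoef(x, y)[0, 1])
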