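import numpy as np
import pandas as pd
import pytest

from cernet import (
    CohortConfig,
    ExpressionMatrix,
    PlantedDE,
    PlantedInfiltration,
    PlantedTriplet,
    SurvivalConfig,
    generate_cohort,
)


def small_config(seed: int = 0, **overrides) -> CohortConfig:
    """A compact cohort with one planted triplet, hazard gene and infiltration."""
    defaults = dict(
        n_tumor=120,
        n_normal=40,
        n_mirna=8,
        n_mrna=16,
        n_lncrna=12,
        planted_de=[
            PlantedDE("miR-0001", 2.0, "down"),
            PlantedDE("miR-0002", 2.0, "down"),
            PlantedDE("gene-0010", 2.0, "up"),
        ],
        planted_triplets=[
            PlantedTriplet("lnc-0001", "miR-0001", "gene-0001", 3.0),
            PlantedTriplet("lnc-0003", "miR-0002", "gene-0002", 3.0),
        ],
        survival=SurvivalConfig(coefficients={"gene-0010": 0.8}),
        infiltration=[PlantedInfiltration("lnc-0002", "neutrophil", 0.6)],
        n_decoy_mrna=15,
        n_decoy_lncrna=15,
        seed=seed,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config(seed=7))


@pytest.fixture
def toy_matrix():
    """4 features × 6 samples, deterministic values, mixed conditions."""
    rng = np.random.default_rng(0)
    vals = pd.DataFrame(
        rng.normal(5, 1, size=(4, 6)),
        index=[f"g{i}" for i in range(4)],
        columns=[f"s{i}" for i in range(6)],
    )
    cond = {f"s{i}": ("tumor" if i < 4 else "normal") for i in range(6)}
    return ExpressionMatrix(vals, "mRNA", cond)
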