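import numpy as np
import pandas as pd
import pytest

from plastigene import SimulationParams, simulate_counts, simulate_design


@pytest.fixture
def toy_design() -> pd.DataFrame:
    """Balanced 2 families x 2 seasons x 2 foods x 2 replicates."""
    params = SimulationParams(n_genes=10, n_families=2, reps_per_cell=2, seed=0)
    return simulate_design(params)


@pytest.fixture
def small_experiment():
    """A small but realistic simulated experiment (200 genes, 72 samples)."""
    params = SimulationParams(n_genes=200, seed=7)
    design = simulate_design(params)
    counts, truth = simulate_counts(design, params)
    return params, design, counts, truth


def make_expression(design: pd.DataFrame, values_fn) -> pd.DataFrame:
    """Build a genes x samples frame from a function of (family, season,
    food) returning a list of per-gene values."""
    cols = {
        sid: values_fn(row["family"], row["season"], row["food"])
        for sid, row in design.iterrows()
    }
    return pd.DataFrame(cols)
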