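import numpy as np
import pandas as pd
import pytest

from hydroniche import (
    LandscapeSpec,
    NicheSpec,
    extract_values,
    generate_climate_stack,
    generate_species_occurrences,
    summarize_species,
)


@pytest.fixture(scope="session")
def stack():
    """The standard synthetic landscape used across the suite."""
    return generate_climate_stack(LandscapeSpec(seed=11))


@pytest.fixture(scope="session")
def cohort(stack):
    """A 12-species occurrence set with MAP-defined Gaussian niches."""
    rng = np.random.default_rng(5)
    v = stack["MAP"].ravel()
    lo, hi = np.percentile(v, [15, 85])
    full = v.max() - v.min()
    niches = [
        NicheSpec(
            f"Sp_{i:02d}",
            {"MAP": float(rng.uniform(lo, hi))},
            {"MAP": float(rng.uniform(0.08, 0.35) * full)},
            n_points=40,
        )
        for i in range(12)
    ]
    occ, truth = generate_species_occurrences(stack, niches, seed=2)
    return occ, truth


@pytest.fixture(scope="session")
def summaries(stack, cohort):
    occ, _ = cohort
    values, dropped = extract_values(stack, occ)
    assert dropped.empty
    table, excluded = summarize_species(values)
    assert not excluded
    return table


@pytest.fixture(scope="session")
def genera():
    return pd.DataFrame(
        {"species": [f"Sp_{i:02d}" for i in range(12)], "group": ["GenA"] * 6 + ["GenB"] * 6}
    )
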