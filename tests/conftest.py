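import numpy as np
import pandas as pd
import pytest

import lipidrank as lr


@pytest.fixture(scope="session")
def default_tax():
    return lr.make_default_taxonomy()


@pytest.fixture(scope="session")
def small_tax():
    """Toy panel: 4 classes x 5 species."""
    class_of = {f"{cls}.{30 + 2 * i}.{i}": cls
                for cls in ("A", "B", "C", "D") for i in range(5)}
    return lr.LipidTaxonomy(class_of)


@pytest.fixture(scope="session")
def spiked_cohort(small_tax):
    """Small cohort with one strongly informative class (A, effect +2)."""
    effects = lr.EffectSpec(class_effects={"A": 2.0})
    m, meta, truth = lr.simulate_cohort(
        small_tax, n_case=15, n_control=15, effects=effects,
        noise_sd=0.5, seed=11)
    return m, meta, truth


@pytest.fixture(scope="session")
def null_cohort(small_tax):
    m, meta, truth = lr.simulate_cohort(
        small_tax, n_case=12, n_control=14, effects=lr.EffectSpec(),
        noise_sd=1.0, seed=5)
    return m, meta, truth


@pytest.fixture
def tiny_grid():
    return [lr.RFConfig(n_estimators=50)]
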