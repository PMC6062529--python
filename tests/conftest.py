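import numpy as np
import pytest

from riskpipe import (
    GeneratorSpec,
    LabeledDataset,
    assemble_cohort,
    build_default_registry,
    build_small_registry,
    generate_registry,
)


@pytest.fixture(scope="session")
def registry():
    return build_default_registry()


@pytest.fixture(scope="session")
def small_registry():
    return build_small_registry()


@pytest.fixture(scope="session")
def toy_cohort():
    """A small synthetic registry cohort shared across tests (n = 300)."""
    spec = GeneratorSpec(n=300, prevalence=0.12, seed=42)
    dataset, flow = assemble_cohort(generate_registry(spec))
    return dataset, flow


@pytest.fixture(scope="session")
def separable_dataset():
    """Linearly separable outcome with a wide margin."""
    rng = np.random.default_rng(5)
    import pandas as pd

    n = 300
    y = (rng.uniform(size=n) < 0.3).astype(int)
    x1 = y * 4.0 + rng.normal(0, 0.3, n)
    x2 = rng.normal(0, 1, n)
    return LabeledDataset(pd.DataFrame({"x1": x1, "x2": x2}), y)
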