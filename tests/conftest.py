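import numpy as np
import pandas as pd
import pytest

from beprog import io
from beprog.simulate import DatasetSpec, SimulationConfig, generate_meta_cohort
from beprog.types import ExpressionMatrix, SampleInfo


@pytest.fixture(scope="session")
def clinical_records():
    """The packaged 19-patient validation-cohort table."""
    return io.read_clinical(io.clinical_fixture_path())


def planted_config(seed: int, n_genes: int = 2000, n_planted: int = 20,
                   effect: float = 2.0) -> SimulationConfig:
    """Cohort config with progression genes planted both DE and exclusive."""
    rng = np.random.default_rng([seed, 17])
    planted = sorted(rng.choice(n_genes, size=n_planted, replace=False).tolist())
    return SimulationConfig(
        n_genes=n_genes,
        planted_de=[(i, effect) for i in planted],
        planted_exclusive=planted,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 200-gene paper-shaped cohort (8 + 7 + 18 samples), no planted signal."""
    cfg = SimulationConfig(n_genes=200, seed=42)
    return generate_meta_cohort(cfg)


def tiny_matrix(values, groups, dataset="D1", prefix="s") -> ExpressionMatrix:
    """Build an ExpressionMatrix from a 2-d array and per-column group labels."""
    values = np.asarray(values, dtype=float)
    cols = [f"{prefix}{j}" for j in range(values.shape[1])]
    samples = [
        SampleInfo(sample_id=c, dataset_id=dataset, group=g)
        for c, g in zip(cols, groups)
    ]
    df = pd.DataFrame(
        values, index=[f"g{i}" for i in range(values.shape[0])], columns=cols
    )
    return ExpressionMatrix(df, samples)
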