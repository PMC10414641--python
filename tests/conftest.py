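import numpy as np
import pandas as pd
import pytest

from monomeg.matrix import STAGES, ExpressionMatrix
from monomeg.synthetic import SimulationConfig, generate


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded small cohort with all five planted classes (raw FPKM scale)."""
    config = SimulationConfig(
        group_sizes=(25, 25, 25, 25),
        n_genes_per_class={
            "mono_inc": 30,
            "mono_dec": 30,
            "u_shape": 20,
            "waved": 20,
            "null": 300,
        },
        effect_size=1.5,
        seed=42,
    )
    return generate(config)


@pytest.fixture(scope="session")
def standardized_small(small_cohort):
    from monomeg.diffexpr import preprocess

    matrix, truth = small_cohort
    return preprocess(matrix), truth


def make_matrix(values: np.ndarray, stages: list[str], scale_state: str = "standardized"):
    """Wrap a plain genes x samples array as an ExpressionMatrix."""
    values = np.asarray(values, dtype=float)
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        stages=pd.Series(stages, index=samples),
        scale_state=scale_state,
    )


def balanced_stages(n_per_stage: int) -> list[str]:
    return [s for s in STAGES for _ in range(n_per_stage)]
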