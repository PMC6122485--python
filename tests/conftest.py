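import numpy as np
import pandas as pd
import pytest

from spongescout.matrix import ExpressionMatrix
from spongescout.synthetic_data import SimulationConfig, simulate_expression


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """Tiny raw-RPKM matrix with all three RNA classes."""
    rng = np.random.default_rng(0)
    vals = pd.DataFrame(
        rng.lognormal(2.0, 1.0, size=(6, 12)),
        index=["L1", "L2", "M1", "M2", "G1", "G2"],
        columns=[f"S{i}" for i in range(12)],
    )
    classes = pd.Series(
        ["lncRNA", "lncRNA", "miRNA", "miRNA", "mRNA", "mRNA"],
        index=vals.index,
    )
    return ExpressionMatrix(values=vals, rna_class=classes)


@pytest.fixture(scope="session")
def planted_dataset():
    """Moderate planted simulation reused across test modules."""
    cfg = SimulationConfig(
        n_samples=200, n_planted=5, n_null_confounded=5,
        n_null_independent=5, coupling_strength=1.0, noise_sd=0.3, seed=11,
    )
    expr, truth = simulate_expression(cfg)
    return cfg, expr, truth
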