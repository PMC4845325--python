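from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from signalome.preprocess import ExpressionMatrix
from signalome.synthetic import SimulationConfig, ModuleSpec, TraitSpec, simulate_cohort


def make_zscored(values: np.ndarray, antibody_ids=None, sample_ids=None) -> ExpressionMatrix:
    """Wrap an array as a Z-scored ExpressionMatrix (rows scaled to mean 0, SD 1)."""
    X = np.asarray(values, dtype=float)
    X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, ddof=0, keepdims=True)
    antibody_ids = antibody_ids or [f"AB{i + 1:04d}" for i in range(X.shape[0])]
    sample_ids = sample_ids or [f"S{j + 1:03d}" for j in range(X.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(X, index=antibody_ids, columns=sample_ids), stage="zscored"
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structured cohort reused across test modules."""
    cfg = SimulationConfig(
        n_proteins=120,
        n_ctrl=24,
        n_dis=24,
        n_differential=12,
        effect_size=1.5,
        modules=[ModuleSpec(12, 0.0, 0.6), ModuleSpec(12, 0.6, 0.0)],
        trait=TraitSpec(n_linked=10, missing_frac=0.2),
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    from signalome.preprocess import preprocess_cohort

    matrix, qc = preprocess_cohort(small_cohort.spots)
    return matrix


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)
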