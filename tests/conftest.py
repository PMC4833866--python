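import numpy as np
import pandas as pd
import pytest

from gisnet.patch_scoring import score_patch_table, strain_score_table
from gisnet.synthetic import CancerConfig, ScreenConfig, simulate_cancer, simulate_screen


@pytest.fixture(scope="session")
def small_screen():
    """Compact simulated screen shared across tests (dGCR assay only)."""
    cfg = ScreenConfig(
        n_baits=60, n_queries=5, assays=(("dGCR", 1e-9),), seed=11,
    )
    patches, truth = simulate_screen(cfg)
    return cfg, patches, truth


@pytest.fixture(scope="session")
def small_screen_scores(small_screen):
    _, patches, _ = small_screen
    return strain_score_table(score_patch_table(patches))


@pytest.fixture(scope="session")
def small_cohort():
    cfg = CancerConfig(n_samples=200, n_genes=300, planted_ts_genes=10, seed=7)
    tables, truth = simulate_cancer(cfg)
    return cfg, tables, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_rate_score_pairs(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Random rate/score tables for oracle-equivalence checks."""
    return pd.DataFrame({
        "gene": [f"g{i}" for i in range(n)],
        "rate_fold": rng.lognormal(0.5, 1.0, n),
        "score": np.round(rng.uniform(0, 5, n), 2),
    })
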