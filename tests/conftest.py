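import numpy as np
import pandas as pd
import pytest

from copex import (
    ExpressionMatrix,
    RankedGeneList,
    SimulationConfig,
    analyze_corpus,
    preprocess,
    simulate_dataset,
)


@pytest.fixture
def toy_ranked() -> RankedGeneList:
    """A 4-entry ranked list (target t, genes a > b > c > d by correlation)."""
    return RankedGeneList(
        target="t", genes=["a", "b", "c", "d"], corrs=np.array([0.9, 0.8, 0.7, 0.6])
    )


@pytest.fixture
def tiny_logged() -> ExpressionMatrix:
    """A tiny deterministic logged matrix (5 genes x 6 samples)."""
    rng = np.random.default_rng(42)
    vals = rng.normal(5.0, 1.0, size=(5, 6))
    return ExpressionMatrix(
        values=pd.DataFrame(
            vals, index=[f"g{i}" for i in range(5)], columns=[f"s{j}" for j in range(6)]
        ),
        stage="logged",
    )


@pytest.fixture(scope="session")
def small_corpus():
    """A small planted-pathway corpus analyzed end-to-end (shared, read-only).

    150 genes x 40 samples with a tightly co-expressed 15-gene block and a
    near-background 15-gene block (10% member fraction, so the pooled
    observed-ES distributions are only mildly member-contaminated);
    thresholds scaled to the corpus size.
    """
    cfg = SimulationConfig(
        n_genes=150, n_samples=40, pathways=((15, 0.6), (15, 0.1)), seed=7
    )
    ds = simulate_dataset(cfg)
    _, logged = preprocess(ds.expression)
    result = analyze_corpus(
        logged,
        ds.truth,
        thresholds=(10, 25, 50),
        min_set_size=5,
        max_set_size=100,
        gsea_pvalues=True,
    )
    return ds, result
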