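import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import cytosynergy as cs

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def strong_sim():
    """Strong-effect simulated dataset shared across tests (read-only)."""
    config = cs.SimConfig.strong_effect(n_genes=400, seed=42)
    matrix, truth = cs.simulate_factorial_counts(config)
    return matrix, truth


@pytest.fixture(scope="session")
def strong_run(strong_sim):
    """DE results, triplets, and interaction calls for the shared dataset."""
    matrix, truth = strong_sim
    factors = cs.size_factors(matrix)
    de = cs.de_all_contrasts(matrix, factors)
    triplets = cs.build_triplets(cs.estimate_effects(matrix, factors))
    calls, summary = cs.classify_all(triplets, de)
    return {"de": de, "triplets": triplets, "calls": calls,
            "summary": summary, "truth": truth}


def make_matrix(counts: dict[str, list[int]], conditions: dict[str, str],
                genes: list[str] | None = None) -> cs.CountMatrix:
    """Small hand-built count matrix helper."""
    df = pd.DataFrame(counts)
    df.index = genes or [f"g{i}" for i in range(len(df))]
    return cs.CountMatrix(df, pd.Series(conditions))


@pytest.fixture
def flat_matrix():
    """Four-condition matrix with two identical replicates per condition."""
    rng = np.random.default_rng(3)
    base = rng.poisson(100, size=30)
    counts, conditions = {}, {}
    for cond in cs.CONDITIONS:
        for r in (1, 2):
            name = f"{cond}_r{r}"
            counts[name] = base
            conditions[name] = cond
    return make_matrix(counts, conditions)
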