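import numpy as np
import pandas as pd
import pytest

from pairratio import CountTable, PairData, SimulationScenario, simulate_pair


@pytest.fixture
def rng():
    return np.random.default_rng(20230120)


def two_group_design(n: int) -> pd.DataFrame:
    return pd.DataFrame({"treatment": np.repeat([0, 1], n // 2)})


@pytest.fixture
def nonsparse_pair(rng) -> PairData:
    """A well-measured null pair: moderate proportion, moderate dispersion."""
    sc = SimulationScenario(control_odds=1 / 9, delta_p=0.0, theta=0.46, n=60,
                            totals_source="nonsparse", n_reps=1, seed=5)
    return simulate_pair(sc, rng=rng)


@pytest.fixture
def small_table() -> CountTable:
    counts = pd.DataFrame(
        [[10, 20, 30, 5], [5, 1, 7, 9], [100, 80, 90, 120]],
        index=["taxonA", "taxonB", "taxonC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    metadata = pd.DataFrame(
        {"group": ["control", "control", "treatment", "treatment"]},
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample_id"),
    )
    return CountTable(counts=counts, metadata=metadata)


def simulate_pair_direct(n, p0, p1, theta, totals, rng) -> PairData:
    """Pair data with explicit per-group means, outside the scenario grid."""
    g = np.repeat([0, 1], n // 2)
    t = np.asarray(totals) if np.ndim(totals) else np.full(n, int(totals))
    mu = np.where(g == 1, p1, p0)
    if theta < 1e-8:
        y = rng.binomial(t, mu)
    else:
        y = rng.binomial(t, rng.beta(mu / theta, (1 - mu) / theta))
    return PairData(numerator_counts=y, pair_totals=t, design=pd.DataFrame({"treatment": g}))
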