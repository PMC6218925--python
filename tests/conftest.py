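import numpy as np
import pandas as pd
import pytest

from subsetsig import (
    AnalysisConfig,
    CountMatrix,
    NormalizedMatrix,
    simulate_counts,
    simulate_second_species,
)


def brute_force_similarity(list_a, list_b, n_tail, alpha):
    """Independent oracle: explicit set intersections at every depth."""
    s = 0.0
    for j in range(1, n_tail + 1):
        top = len(set(list_a[:j]) & set(list_b[:j]))
        bottom = len(set(list_a[-j:]) & set(list_b[-j:]))
        s += np.exp(-alpha * j) * (top + bottom)
    return s


def brute_force_bh(p):
    """O(m^2) step-up reference: q_(i) = min_{k>=i} p_(k) * m / k, capped at 1."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_i, idx in enumerate(order, start=1):
        q[idx] = min(
            min(p[order[k - 1]] * m / k for k in range(rank_i, m + 1)), 1.0
        )
    return q


@pytest.fixture(scope="session")
def small_sim():
    """Small planted-marker dataset shared across tests (2000 genes)."""
    cm, truth = simulate_counts(
        n_genes=2000, n_markers_per_subset=40, effect_log2=3.0, dispersion=0.1, seed=11
    )
    return cm, truth


@pytest.fixture(scope="session")
def small_two_species(small_sim):
    cm, truth = small_sim
    im, om, truth2 = simulate_second_species(truth, conserved_frac=0.8, seed=12)
    return cm, im, om, truth2


@pytest.fixture
def toy_count_matrix():
    counts = pd.DataFrame(
        {"s1": [10, 30, 5], "s2": [20, 60, 9]},
        index=["g1", "g2", "g3"],
    )
    return CountMatrix(counts=counts, subset_of={"s1": "pDC", "s2": "cM"})


def null_normalized_matrix(rng, n_genes=500, n_a=3, n_b=6, dispersion=0.1):
    """NB draws with no group effect, wrapped as a NormalizedMatrix."""
    mu = 2 ** rng.normal(5, 2, n_genes)
    n = 1 / dispersion
    mean = np.tile(mu[:, None], (1, n_a + n_b))
    counts = rng.negative_binomial(n, n / (n + mean)).astype(float)
    samples = [f"s{i}" for i in range(n_a + n_b)]
    subset = {s: ("A" if i < n_a else "B") for i, s in enumerate(samples)}
    return NormalizedMatrix(
        pd.DataFrame(counts, index=[f"g{i}" for i in range(n_genes)], columns=samples),
        subset,
    )


@pytest.fixture
def config_fast():
    return AnalysisConfig(n_tail=50, n_perm=100, rng_seed=7)
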