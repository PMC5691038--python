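import numpy as np
import pytest

from heteroflux.central import CentralModelOptions, build_central_model
from heteroflux.synth import make_chain_model, make_toy_models


def signed_rank_null_p_cdf(n: int):
    """Exact null CDF of the two-sided Wilcoxon signed-rank p-value for a
    sample of n untied non-zero values — the independent oracle for
    checking the test's null behaviour (the p-value is discrete, so the
    continuous-uniform CDF is the wrong reference).

    Returns (atoms, cdf): achievable p-values and P(p <= atom).
    """
    # distribution of W+ = sum of ranks with positive sign, by DP
    counts = np.zeros(n * (n + 1) // 2 + 1, dtype=float)
    counts[0] = 1.0
    for rank in range(1, n + 1):
        counts[rank:] += counts[:-rank].copy()
    pmf = counts / counts.sum()
    cdf_w = np.cumsum(pmf)
    sf_w = np.cumsum(pmf[::-1])[::-1]
    pvals = np.minimum(1.0, 2.0 * np.minimum(cdf_w, sf_w))
    atoms, idx = np.unique(pvals, return_inverse=True)
    mass = np.bincount(idx, weights=pmf)
    return atoms, np.cumsum(mass)


def ks_against_discrete_null(pvalues, n: int) -> float:
    """Sup-distance between the empirical p-value CDF and the exact
    discrete signed-rank null CDF."""
    atoms, cdf = signed_rank_null_p_cdf(n)
    emp = np.asarray(pvalues, dtype=float)
    return float(max(abs((emp <= a + 1e-12).mean() - c)
                     for a, c in zip(atoms, cdf)))


@pytest.fixture
def chain_model():
    """EX_A -> T -> R -> EX_B with uptake bound 10."""
    return make_chain_model(uptake=10.0, n_internal=2)


@pytest.fixture(scope="session")
def central_model():
    return build_central_model(CentralModelOptions())


@pytest.fixture(scope="session")
def toy_suite():
    """30 random small models with brute-force oracle optima."""
    return make_toy_models(30, seed=42)
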