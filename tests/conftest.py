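import numpy as np
import pytest
from hypothesis import settings
from scipy.stats import norm

from miss_ars import builtin_table, default_config, simulate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

#: Published grouped 30-day mortality counts used as probit input.
PAPER_COUNTS = [(6.0, 20, 0), (8.0, 20, 4), (10.0, 26, 25), (14.0, 26, 26)]


def grid_probit(data, mu_range=(4.0, 16.0), sigma_range=(0.05, 5.0), rounds=4, size=121):
    """Independent brute-force oracle: pure grid refinement over (mu, sigma).

    Maximizes the grouped binomial probit log-likelihood on a dense grid,
    zooming around the argmax each round.  Final resolution ~1e-5 in the
    parameters, far below 1e-6 in log-likelihood.
    """
    mu_lo, mu_hi = mu_range
    s_lo, s_hi = sigma_range
    best = None
    for _ in range(rounds):
        mus = np.linspace(mu_lo, mu_hi, size)
        sigmas = np.linspace(s_lo, s_hi, size)
        M, S = np.meshgrid(mus, sigmas, indexing="ij")
        ll = np.zeros_like(M)
        for dose, n, deaths in data:
            Z = (dose - M) / S
            ll += deaths * norm.logcdf(Z) + (n - deaths) * norm.logsf(Z)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        best = (float(mus[i]), float(sigmas[j]), float(ll[i, j]))
        dm = (mu_hi - mu_lo) / (size - 1)
        ds = (s_hi - s_lo) / (size - 1)
        mu_lo, mu_hi = mus[i] - 2 * dm, mus[i] + 2 * dm
        s_lo, s_hi = max(1e-3, sigmas[j] - 2 * ds), sigmas[j] + 2 * ds
    return best


@pytest.fixture(scope="session")
def miss1():
    return builtin_table("MISS1")


@pytest.fixture(scope="session")
def miss2():
    return builtin_table("MISS2")


@pytest.fixture(scope="session")
def miss3():
    return builtin_table("MISS3")


@pytest.fixture(scope="session")
def paper_counts():
    return list(PAPER_COUNTS)


@pytest.fixture(scope="session")
def small_sim():
    """A small observation-bearing simulated cohort shared across tests."""
    from miss_ars import SimConfig

    return simulate_cohort(SimConfig(seed=11, design={"8": 6, "10": 8, "14": 8}))


@pytest.fixture(scope="session")
def default_sim_truth_only():
    """The full default-design cohort at the shipped seed, truth only."""
    return simulate_cohort(default_config(sample_observations=False))
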