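import numpy as np
import pytest

import rvbayes as rv
from rvbayes.mcmc import MCMCSettings, TemperatureLadder, run_power_posterior


@pytest.fixture(scope="session", autouse=True)
def warm_jit():
    """Compile the numba kernels once up front so per-test timings are honest."""
    d = rv.GenotypeData(np.array([[1], [0]]), np.array([2, 2]))
    y = rv.Phenotype(np.array([1, 0]))
    run_power_posterior(
        d,
        y,
        None,
        rv.ModeOfInheritance.DOMINANT,
        rv.Hyperparameters(),
        MCMCSettings(5, 2, 0, TemperatureLadder(np.array([0.0, 1.0]))),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def random_instance(rng, k, N=100, af=0.05, mode=None, pi=0.8, tau=0.2):
    """A small random case/control dataset with the first half of variants causal."""
    from rvbayes.likelihood import pathogenic_configurations

    mode = mode or rv.ModeOfInheritance.DOMINANT
    while True:
        G = rng.binomial(2, af, size=(N, k))
        d = rv.GenotypeData(G, np.full(N, 2))
        z = np.zeros(k, dtype=int)
        z[: max(1, k // 2)] = 1
        f = pathogenic_configurations(d, z, mode)
        y = (rng.random(N) < np.where(f == 1, pi, tau)).astype(int)
        if 0 < y.sum() < N:
            return d, rv.Phenotype(y)
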