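import numpy as np
import pytest

import divprof as dp


@pytest.fixture(scope="session")
def worked_pair():
    """The six-clone intersecting-profile example pair."""
    from divprof.examples import intersecting_pair

    return intersecting_pair()


@pytest.fixture(scope="session")
def small_cohort():
    """Twenty simulated Zipf-Mandelbrot repertoires at modest depth."""
    return dp.simulate_cohort(n_repertoires=20, n_reads=10**5, seed=11)


def random_distribution(rng, n_clones=None):
    """A random clonal frequency distribution (Dirichlet draw)."""
    if n_clones is None:
        n_clones = int(rng.integers(2, 40))
    f = rng.dirichlet(np.ones(n_clones) * rng.uniform(0.2, 2.0))
    f = np.clip(f, 1e-12, None)
    f = f / f.sum()
    return dp.ClonalFrequencyDistribution.from_frequencies(f)
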