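import numpy as np
import pytest

import crossfeed as cf


@pytest.fixture(scope="session")
def baseline():
    """Baseline parameter set and environment (S0 = 350 umol/L, D = 0.2/h)."""
    return cf.baseline_parameters()


@pytest.fixture(scope="session")
def params(baseline):
    return baseline[0]


@pytest.fixture(scope="session")
def env(baseline):
    return baseline[1]


@pytest.fixture(scope="session")
def env_fig4(env):
    """The 0.025 % w/v glucose environment of the bistable-invasion analysis."""
    return env.replace(S0=cf.percent_wv_to_umolL(0.025))


@pytest.fixture(scope="session")
def nmax_fig4(params, env_fig4):
    """Strain-1 monoculture maximum density at 0.025 % w/v glucose."""
    return cf.monoculture_max_density(params, env_fig4)


@pytest.fixture(scope="session")
def equilibria_350(params, env):
    return cf.find_equilibria(params, env, n_starts=48, seed=11)


def same_equilibrium_sets(eqs_a, eqs_b, scales, tol=1e-5):
    """True if two equilibrium lists match pairwise within a scaled distance
    tolerance (order-free)."""
    def matched(xs, ys):
        return all(any(np.linalg.norm((x.state - y.state) / scales) < tol
                       for y in ys) for x in xs)
    return matched(eqs_a, eqs_b) and matched(eqs_b, eqs_a)


def random_states(env, n, seed):
    """Physically plausible random states for property checks."""
    rng = np.random.default_rng(seed)
    states = np.empty((n, 6))
    states[:, 0] = rng.uniform(0, env.S0, n)
    states[:, 1] = rng.uniform(0, 2 * env.S0, n)
    states[:, 2] = 10 ** rng.uniform(6, 12.5, n)
    states[:, 3] = 10 ** rng.uniform(6, 12.5, n)
    states[:, 4] = rng.uniform(0, 2 * env.S0, n)
    states[:, 5] = rng.uniform(0, 2 * env.S0, n)
    return states
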