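import numpy as np
import pytest

from speechdcm import (
    CohortSpec, default_network, default_priors, fit_vl, make_design,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def spec():
    return default_network()


@pytest.fixture(scope="session")
def word_design():
    return make_design("word")


@pytest.fixture(scope="session")
def priors(spec):
    return default_priors(spec)


@pytest.fixture(scope="session")
def fitted_subject(spec, word_design):
    """One noisy synthetic subject inverted by variational Laplace.

    Session-scoped: several tests inspect the same estimate (recovery,
    free-energy trace, model reduction).
    """
    cohort = CohortSpec(n_subjects=1, tasks=("word",),
                        configurations=("M1-f&dpOp",), seed=7)
    series, records = simulate_cohort(cohort)
    est = fit_vl(series[(0, "word", "M1-f&dpOp")], word_design, spec)
    return records[0], est


def rk4(f, x0, t_grid):
    """Classic fixed-step RK4, used as an independent integration oracle."""
    x = np.asarray(x0, float)
    out = [x]
    for t0, t1 in zip(t_grid[:-1], t_grid[1:]):
        h = t1 - t0
        k1 = f(t0, x)
        k2 = f(t0 + h / 2, x + h / 2 * k1)
        k3 = f(t0 + h / 2, x + h / 2 * k2)
        k4 = f(t1, x + h * k3)
        x = x + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        out.append(x)
    return np.array(out)
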