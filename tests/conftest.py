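import numpy as np
import pytest

from powerref import datasets


@pytest.fixture(scope="session")
def priming():
    """10-participant priming reaction-time example (wide)."""
    return datasets.priming_example()


@pytest.fixture(scope="session")
def repeated_wide():
    """6 participants x 4 repetitions reliability example (wide)."""
    return datasets.repeated_measures_example()


@pytest.fixture(scope="session")
def repeated_long():
    """The reliability example in long notation (24 rows)."""
    return datasets.repeated_measures_example_long()


def jzs_bf_oracle(t, n_eff, nu, rscale=np.sqrt(2) / 2):
    """Brute-force JZS t-test BF10: dense trapezoid over g on a log grid.

    Written independently of the package's integrator (different grid,
    different formulation of the prior density) to serve as an oracle.
    """
    from math import gamma, pi, sqrt

    u = np.linspace(-30.0, 30.0, 20001)
    g = np.exp(u)
    # InverseGamma(1/2, rscale^2/2) density, spelled via its definition
    alpha, beta = 0.5, rscale ** 2 / 2.0
    prior = beta ** alpha / gamma(alpha) * g ** (-alpha - 1) * np.exp(-beta / g)
    like = (1.0 + n_eff * g) ** -0.5 * (
        1.0 + t ** 2 / ((1.0 + n_eff * g) * nu)) ** (-(nu + 1) / 2.0)
    num = np.trapezoid(like * prior * g, u)
    den = (1.0 + t ** 2 / nu) ** (-(nu + 1) / 2.0)
    return num / den
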