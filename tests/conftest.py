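import numpy as np
import pytest

from hnsemble.core_thermo import preset


@pytest.fixture(scope="session")
def wt150():
    return preset("wt_150mM")


@pytest.fixture(scope="session")
def wt300():
    return preset("wt_300mM")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240210)


def brute_force_unfolded_root(C, K_o, K_d, K_U, n_iter=200):
    """Independent bracketing-bisection oracle for the mass balance.

    Solves the degree-8 balance polynomial written in the unfolded
    monomer concentration [U] (coefficients in powers of 1/K_U), scanning
    the bracket [0, C].  Kept deliberately separate from the library's
    solver, which works in the folded-monomer variable.
    """

    def f(u):
        return (
            8.0 * K_o**3 * K_d**4 / K_U**8 * u**8
            + 4.0 * K_o * K_d**2 / K_U**4 * u**4
            + 2.0 * K_d / K_U**2 * u**2
            + (1.0 + 1.0 / K_U) * u
            - C
        )

    lo, hi = 0.0, C
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
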