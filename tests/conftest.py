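"""Shared fixtures: model defaults, packaged tables, and the exact
rational-arithmetic binomial oracle used to cross-check thresholds."""

from fractions import Fraction

import pytest

from gistkit import FounderModelParams
from gistkit.resources import (
    load_founder_candidates,
    load_screen_panel,
    load_screen_sites,
    load_zf_motifs,
)


def oracle_threshold(n: int, q: Fraction, inclusion: Fraction = Fraction(95, 100)) -> int:
    """Brute-force threshold via exact rational binomial pmf summation.

    Builds the full pmf of Binomial(n, q) term by term with
    fractions.Fraction and walks the upper tail to find the largest
    k >= 1 with P(X >= k) >= inclusion (floor 1).  Independent of the
    package's floating-point tail computation.
    """
    pmf = [(1 - q) ** n]
    for i in range(1, n + 1):
        pmf.append(pmf[-1] * (n - i + 1) * q / (i * (1 - q)))
    tail = 1 - pmf[0]  # P(X >= 1)
    if tail < inclusion:
        return 1
    k = 1
    while k + 1 <= n:
        tail -= pmf[k]
        if tail < inclusion:
            break
        k += 1
    return k


@pytest.fixture(scope="session")
def default_params() -> FounderModelParams:
    return FounderModelParams()


@pytest.fixture(scope="session")
def founder_candidates():
    return load_founder_candidates()


@pytest.fixture(scope="session")
def screen_table():
    return load_screen_panel()


@pytest.fixture(scope="session")
def screen_sites():
    return load_screen_sites()


@pytest.fixture(scope="session")
def zf_motifs():
    return load_zf_motifs()
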