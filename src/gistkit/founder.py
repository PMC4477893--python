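"""Binomial model for founder-mutation classification in an impure tumour.

A heterozygous somatic mutation carried by every tumour cell ("founding
mutation") is expected on a fraction ``p/2`` of sequenced reads, where ``p``
is the tumour purity: only ``p`` of the cells are tumour cells, and only one
of the two alleles in each carries the mutation.  Sequencing the locus at
coverage ``n`` is modelled as a Bernoulli process, so the number of mutant
reads ``X`` follows ``Binomial(n, p/2)``.

Because allele sampling is stochastic, a true founder may by chance show few
mutant reads.  The classifier therefore accepts a mutation as a founder when
its mutant-read count reaches a coverage-dependent threshold ``k(n)`` chosen
so that an expected 95% (the *inclusion* level) of true founders are
retained:

    k(n) = max{ k >= 1 : P(X >= k) >= inclusion },   X ~ Binomial(n, p/2)

with a floor of ``k = 1`` at coverages too small for any threshold to retain
the target fraction — a call must always be supported by at least one read.

Tail probabilities are computed by exact summation of binomial pmf terms,
accumulated from the smallest terms (the upper tail) first: the threshold
boundaries around n ~ 30 are decided by tail-mass differences of order 1e-3,
too fine for a normal approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InvalidParameterError",
    "FounderModelParams",
    "ThresholdTable",
    "founder_threshold",
    "build_threshold_table",
    "classify_founder",
    "count_founder_snvs",
]


class InvalidParameterError(ValueError):
    """A model parameter lies outside its admissible domain."""


@dataclass(frozen=True)
class FounderModelParams:
    """Parameters of the binomial founder-inclusion model.

    Parameters
    ----------
    purity : float
        Tumour purity ``p``, the fraction of cells in the sample that are
        tumour cells; must lie in (0, 1].  Default 0.6, the lower end of a
        typical histological estimate for a moderately pure resection.
    het_factor : float
        Fraction of alleles in a tumour cell carrying the mutation; 1/2 for
        a heterozygous mutation (the default), 1 for a hemizygous mutation
        on a monosomic arm.
    inclusion : float
        Target fraction of true founder mutations retained by the
        threshold; must lie in (0, 1).  Default 0.95.
    """

    purity: float = 0.6
    het_factor: float = 0.5
    inclusion: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise InvalidParameterError(
                f"purity must be in (0, 1], got {self.purity!r}"
            )
        if not 0.0 < self.inclusion < 1.0:
            raise InvalidParameterError(
                f"inclusion must be in (0, 1), got {self.inclusion!r}"
            )
        if not 0.0 < self.het_factor <= 1.0:
            raise InvalidParameterError(
                f"het_factor must be in (0, 1], got {self.het_factor!r}"
            )

    @property
    def success_prob(self) -> float:
        """Per-read probability of observing the mutant allele."""
        return self.purity * self.het_factor


def _upper_tail(k: int, n: int, q: float) -> float:
    """P(X >= k) for X ~ Binomial(n, q), summed smallest terms first."""
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    ks = np.arange(n, k - 1, -1)
    return float(stats.binom.pmf(ks, n, q).sum())


@lru_cache(maxsize=None)
def _threshold(n: int, purity: float, het_factor: float, inclusion: float) -> int:
    q = purity * het_factor
    if _upper_tail(1, n, q) < inclusion:
        return 1  # floor: no k >= 1 retains the target fraction
    k = 1
    while k + 1 <= n and _upper_tail(k + 1, n, q) >= inclusion:
        k += 1
    return k


def founder_threshold(n: int, params: FounderModelParams | None = None) -> int:
    """Minimal mutant-read count required at coverage ``n``.

    Returns the largest ``k >= 1`` such that ``P(X >= k) >= inclusion`` for
    ``X ~ Binomial(n, purity * het_factor)``; returns 1 when no such ``k``
    exists (very low coverage).

    Raises
    ------
    InvalidParameterError
        If ``n`` is not a positive integer or the parameters are invalid.
    """
    if params is None:
        params = FounderModelParams()
    if int(n) != n or n < 1:
        raise InvalidParameterError(f"coverage n must be a positive integer, got {n!r}")
    return _threshold(int(n), params.purity, params.het_factor, params.inclusion)


@dataclass(frozen=True)
class ThresholdTable:
    """Founder thresholds ``k(n)`` over a coverage range.

    ``thresholds`` maps each coverage ``n`` in ``[n_min, n_max]`` to the
    minimal required mutant-read count; the mapping is non-decreasing in
    ``n`` and every entry is at least 1.
    """

    params: FounderModelParams
    n_min: int
    n_max: int
    thresholds: dict[int, int]

    def __getitem__(self, n: int) -> int:
        return self.thresholds[n]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n": list(self.thresholds), "k": list(self.thresholds.values())}
        )


def build_threshold_table(
    n_min: int, n_max: int, params: FounderModelParams | None = None
) -> ThresholdTable:
    """Tabulate :func:`founder_threshold` over ``n_min..n_max`` inclusive."""
    if params is None:
        params = FounderModelParams()
    if n_min < 1 or n_max < n_min:
        raise InvalidParameterError(
            f"invalid coverage range [{n_min}, {n_max}]: need 1 <= n_min <= n_max"
        )
    thresholds = {n: founder_threshold(n, params) for n in range(n_min, n_max + 1)}
    return ThresholdTable(params=params, n_min=n_min, n_max=n_max, thresholds=thresholds)


def classify_founder(
    alt_count: int, coverage: int, params: FounderModelParams | None = None
) -> bool:
    """True iff ``alt_count`` reaches the founder threshold at ``coverage``."""
    if params is None:
        params = FounderModelParams()
    if coverage < 1:
        raise InvalidParameterError(f"coverage must be >= 1, got {coverage!r}")
    if not 0 <= alt_count <= coverage:
        raise InvalidParameterError(
            f"alt_count must be in [0, coverage], got {alt_count!r} with coverage {coverage!r}"
        )
    return alt_count >= founder_threshold(coverage, params)


def count_founder_snvs(
    table: pd.DataFrame, params: FounderModelParams | None = None
) -> int:
    """Number of SNV rows in ``table`` classified as founder mutations.

    ``table`` needs columns ``alt_count``, ``coverage`` and
    ``variant_class`` (rows labelled ``"SNV"`` are counted; indel rows are
    classified but not counted).  A malformed row raises a ``ValueError``
    naming the row.
    """
    if params is None:
        params = FounderModelParams()
    required = {"alt_count", "coverage", "variant_class"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"variant table lacks columns: {sorted(missing)}")
    count = 0
    for label, row in table.iterrows():
        ident = row.get("gene", label)
        try:
            passed = classify_founder(int(row.alt_count), int(row.coverage), params)
        except (InvalidParameterError, TypeError) as exc:
            raise ValueError(f"malformed variant row {ident!r}: {exc}") from exc
        if passed and row.variant_class == "SNV":
            count += 1
    return count
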