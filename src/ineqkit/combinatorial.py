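"""Combinatorics-model measures: Herfindahl-Hirschman and Simpson family.

Both families estimate the probability that two randomly drawn units
belong to the same component.  The Herfindahl-Hirschman index (HHI) is the
urn model *with* replacement — the sum of squared unit shares — and is
appropriate for metric variables or large-N categorical data.  The Simpson
index is the exact urn model *without* replacement on integer counts and
is the correct measure at small N; the two converge as N grows with fixed
proportions.

The Gini-Simpson index GS = 1 - S is the complementary probability (two
units from *different* components) and the inverse Simpson index IS = 1/S
maps S onto [1, +inf], with +inf corresponding to probability 0.
"""

from __future__ import annotations

import warnings

import numpy as np

from .distribution import UnitDistribution
from .errors import DomainError, NonNumericError

__all__ = ["hhi", "simpson", "gini_simpson", "inverse_simpson"]

#: Below this total count the with-replacement urn model is a poor
#: approximation and the Simpson family should be preferred.
SMALL_N_ADVISORY = 100


def hhi(d: UnitDistribution) -> float:
    """Herfindahl-Hirschman index HHI = sum_i p_i**2 over non-null components.

    Larger shares are weighted disproportionally (0.8**2 = 0.64 but
    0.1**2 = 0.01), which is what makes the HHI a measure of market
    dominance.  Null components are ignored, so the range is [1/k', 1]
    with k' the number of non-null components.

    For categorical counts with small N an advisory warning suggests the
    Simpson index, whose without-replacement urn model is exact there.
    """
    dn = d.nonnull()
    if (
        d.kind.treated_as_categorical
        and d.is_integer_counts()
        and d.total < SMALL_N_ADVISORY
    ):
        warnings.warn(
            f"HHI on categorical counts with small N={d.total:.0f}: the "
            "with-replacement urn model is only asymptotically correct; "
            "consider the Simpson index",
            UserWarning,
            stacklevel=2,
        )
    return float(np.sum(dn.shares**2))


def _integer_counts(d: UnitDistribution) -> np.ndarray:
    n = d.units
    if not d.is_integer_counts():
        bad = np.flatnonzero(n != np.floor(n)).tolist()
        raise NonNumericError(
            f"Simpson-family indices require integer counts; non-integer "
            f"units at indices {bad}"
        )
    return n


def simpson(counts: UnitDistribution) -> float:
    """Simpson index S = sum_i n_i(n_i - 1) / (N(N - 1)).

    The exact probability that two randomly selected units (an unordered
    pair, drawn without replacement) belong to the same component.  Defined
    for integer counts with N >= 2; null categories contribute nothing.
    Range [0, 1]: 0 when every unit is its own category, 1 when all units
    share one category.
    """
    n = _integer_counts(counts)
    total = float(n.sum())
    if total < 2:
        raise DomainError("Simpson index requires at least N = 2 units")
    return float(np.sum(n * (n - 1.0)) / (total * (total - 1.0)))


def gini_simpson(counts: UnitDistribution) -> float:
    """Gini-Simpson index GS = 1 - S: the probability that two random
    units stem from different components (a measure of equality/diversity;
    synonyms: Blau index, Hunter-Gaston index, probability of interspecific
    encounter)."""
    return 1.0 - simpson(counts)


def inverse_simpson(counts: UnitDistribution) -> float:
    """Inverse Simpson index IS = 1/S on [1, +inf].

    Returns ``math.inf`` when S = 0 (all-singleton categories), the value
    corresponding to a same-component probability of zero.
    """
    s = simpson(counts)
    if s == 0.0:
        return float("inf")
    return 1.0 / s
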