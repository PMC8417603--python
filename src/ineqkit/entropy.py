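"""Entropy-model measures: Shannon index and generalized entropy.

The Shannon index measures the average information content of a
categorical unit distribution — with the binary logarithm, the average
number of yes/no questions needed to identify the component of a random
unit.  It is a measure of equality (maximal for evenly distributed
categories) and ignores null categories.

The generalized entropy family GE(alpha) measures inequality of metric
distributions as redundancy: the distance of the observed distribution
from maximum entropy (the uniform distribution).  The parameter alpha
tunes tail sensitivity — the more positive, the more weight on inequality
in the high range; the more negative, the more weight on the low range.
alpha = 1 gives the Theil index and alpha = 0 the mean log deviation, each
as the analytic limit of the generic branch:

    GE(alpha) = 1/(k*alpha*(alpha-1)) * sum_i [(k*p_i)**alpha - 1]   alpha not in {0, 1}
    GE(1)     = 1/k * sum_i (k*p_i) * ln(k*p_i)                       (Theil)
    GE(0)     = -1/k * sum_i ln(k*p_i)                                (mean log deviation)

(k*p_i equals n_i/n_bar, the units relative to the component mean.)
GE is 0 exactly when the distribution is uniform and positive otherwise.
"""

from __future__ import annotations

import math
from typing import Union

import numpy as np

from .distribution import UnitDistribution
from .errors import DomainError

__all__ = ["shannon", "generalized_entropy", "theil", "mean_log_deviation"]

_BASES = {2: 2.0, "2": 2.0, 10: 10.0, "10": 10.0, "e": math.e}


def _resolve_base(base: Union[int, float, str]) -> float:
    if isinstance(base, str):
        if base not in _BASES:
            raise ValueError(f"log base must be one of 2, 'e', 10; got {base!r}")
        return _BASES[base]
    b = float(base)
    if b <= 0 or b == 1.0:
        raise ValueError(f"log base must be positive and != 1; got {base!r}")
    return b


def shannon(counts: UnitDistribution, base: Union[int, float, str] = 2) -> float:
    """Shannon index SI = -sum_i p_i * log_a(p_i) over non-null components.

    With base 2 the result is in bits: the average number of yes/no
    questions needed to pin down the component of a random unit.  A
    single-category distribution scores 0; four equally frequent
    categories score 2 bits; duplicating every observation leaves the
    index unchanged.  Upper bound log_a(k') with k' non-null components.

    ``base`` may be 2 (default), ``"e"`` or 10.
    """
    b = _resolve_base(base)
    p = counts.nonnull().shares
    return float(-np.sum(p * (np.log(p) / math.log(b)))) + 0.0  # avoid -0.0


def generalized_entropy(d: UnitDistribution, alpha: float) -> float:
    """Generalized entropy index GE(alpha) of a metric unit distribution.

    Branch selection is by exact parameter equality: ``alpha == 1``
    computes the Theil index, ``alpha == 0`` the mean log deviation, any
    other alpha the generic power branch (the three agree in the limits;
    a continuity test guards the seams).

    Zero units are allowed for alpha > 0 (the 0*ln 0 = 0 convention at
    alpha = 1; the generic term is finite for 0 < alpha != 1) but raise
    :class:`DomainError` for alpha <= 0, where the formula needs strictly
    positive units.
    """
    alpha = float(alpha)
    r = d.k * d.shares  # k*p_i = n_i / n_bar
    if alpha <= 0 and np.any(r == 0):
        zeros = np.flatnonzero(r == 0).tolist()
        raise DomainError(
            f"GE(alpha={alpha:g}) needs strictly positive units; "
            f"zero units at indices {zeros}"
        )
    k = d.k
    if alpha == 1.0:
        pos = r > 0
        return float(np.sum(r[pos] * np.log(r[pos])) / k)
    if alpha == 0.0:
        return float(-np.sum(np.log(r)) / k)
    return float(np.sum(r**alpha - 1.0) / (k * alpha * (alpha - 1.0)))


def theil(d: UnitDistribution) -> float:
    """Theil index: GE at alpha = 1, the direct generalization of the
    Shannon index to metric variables (more sensitive to inequality in the
    high range than the mean log deviation)."""
    return generalized_entropy(d, 1.0)


def mean_log_deviation(d: UnitDistribution) -> float:
    """Mean log deviation: GE at alpha = 0, the average deviation of log
    units from their log mean."""
    return generalized_entropy(d, 0.0)
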