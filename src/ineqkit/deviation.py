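"""Deviations-model measures: Gini, Hoover and Rosenbluth indices.

These measures quantify inequality through the deviation of component unit
shares from a standard derived from the distribution itself — every other
share (Gini), the mean share 1/k (Hoover), or a rank-weighted sum
(Rosenbluth, also known as the Hall-Tideman index).  Zero components are
retained: they occupy rank positions and contribute deviations, and the
maximum-inequality geometry of the Lorenz and concentration curves counts
them.

The uncorrected Gini and Hoover indices range over [0, 1 - 1/k] and are
measures of absolute inequality; dividing by 1 - 1/k gives the corrected,
relative forms on [0, 1].  The Rosenbluth index ranges over [1/k, 1] and
satisfies R = 1/[k(1 - G)].
"""

from __future__ import annotations

import numpy as np

from .curves import concentration_area_above, concentration_curve
from .distribution import UnitDistribution
from .errors import DomainError

__all__ = ["gini", "gini_corrected", "hoover", "hoover_corrected", "rosenbluth"]


def gini(d: UnitDistribution) -> float:
    """Gini index G = (1/2k) * sum_i sum_j |p_i - p_j|.

    Half the normed average absolute difference between all pairs of
    component shares; graphically, twice the area between the line of
    equality and the Lorenz curve.  0 at equality, 1 - 1/k at maximum
    inequality (all units in one component).
    """
    p = np.sort(d.shares)
    k = p.size
    # Sorted-rank identity for the pairwise double sum:
    # sum_ij |p_i - p_j| = 2 * sum_i (2i - k - 1) p_(i),  i = 1..k ascending.
    ranks = np.arange(1, k + 1)
    pair_sum = 2.0 * float(np.sum((2 * ranks - k - 1) * p))
    return pair_sum / (2.0 * k)


def gini_corrected(d: UnitDistribution) -> float:
    """Corrected Gini index G' = G / (1 - 1/k), normalised to [0, 1].

    Undefined at k = 1 (the correction divides by zero).
    """
    if d.k < 2:
        raise DomainError("corrected Gini requires k >= 2")
    return gini(d) / (1.0 - 1.0 / d.k)


def hoover(d: UnitDistribution) -> float:
    """Hoover index H = (1/2) * sum_i |p_i - 1/k|.

    The share of units that would need to be redistributed across
    components to achieve perfect equality (hence the synonyms Robin-Hood,
    Pietra and Schutz index); equals the maximum vertical distance between
    the Lorenz curve and the line of equality.  Range [0, 1 - 1/k].
    """
    return 0.5 * float(np.sum(np.abs(d.shares - 1.0 / d.k)))


def hoover_corrected(d: UnitDistribution) -> float:
    """Corrected Hoover index H' = H / (1 - 1/k) on [0, 1]."""
    if d.k < 2:
        raise DomainError("corrected Hoover requires k >= 2")
    return hoover(d) / (1.0 - 1.0 / d.k)


def rosenbluth(d: UnitDistribution) -> float:
    """Rosenbluth (Hall-Tideman) index R = 1 / (2 * sum_i i*p_(i) - 1).

    Ranks i = 1..k are assigned after sorting shares descending (rank 1 is
    the largest share).  Equals the reciprocal of twice the area above the
    concentration curve, and satisfies R = 1/[k(1 - G)].  Range [1/k, 1]:
    1/k at equality, 1 when a single component holds all units.

    Equal shares may be ranked in any order without changing the value.
    """
    p = np.sort(d.shares)[::-1]
    ranks = np.arange(1, p.size + 1)
    denom = 2.0 * float(np.sum(ranks * p)) - 1.0
    return 1.0 / denom
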