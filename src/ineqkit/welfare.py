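"""Social-welfare-model measure: the Atkinson index.

The Atkinson index AI(epsilon) expresses inequality as the fraction of the
total unit sum that could be given up if units were redistributed equally
while keeping a society (or sample) at the same welfare level:

    AI(epsilon) = 1 - M_{1-epsilon}(n) / n_bar

where M_q is the power (generalized) mean of order q = 1 - epsilon — the
geometric mean at epsilon = 1 — and n_bar the component mean.  The
*equally distributed equivalent* standard n_eps = n_bar * (1 - AI) is the
common per-component level that would be as good as the observed unequal
distribution; reaching it for every component needs only the fraction
1 - AI of the total unit sum.

epsilon >= 0 is the inequality aversion: 0 makes AI identically zero,
and on any non-uniform distribution AI strictly increases with epsilon,
weighting the low range of the distribution more and more heavily.
Recommended working values are epsilon between 1.5 and 2.

The family is linked to generalized entropy through epsilon = 1 - alpha:

    AI = 1 - [1 + epsilon*(epsilon - 1) * GE(1 - epsilon)]**(1/(1-epsilon)),  epsilon != 1
    AI = 1 - exp(-GE(0))                                                      epsilon = 1

(at epsilon = 1 the relevant GE member is the mean log deviation).  Both
branches are algebraically exact and are cross-validated numerically on
request; see :func:`atkinson_ge_link`.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .distribution import UnitDistribution
from .errors import ConsistencyError, DomainError

__all__ = [
    "atkinson",
    "ede_standard",
    "epsilon_for_standard",
    "atkinson_ge_link",
    "RECOMMENDED_EPSILON_RANGE",
]

#: Inequality-aversion values recommended for applied work.
RECOMMENDED_EPSILON_RANGE = (1.5, 2.0)


def _power_mean(units: np.ndarray, order: float) -> float:
    """Power mean M_q of non-negative units; geometric mean at q = 0.

    For q <= 0 a zero unit drives the mean to 0 (the standard limit)."""
    if order == 0.0:
        if np.any(units == 0):
            return 0.0
        return float(np.exp(np.mean(np.log(units))))
    if order < 0 and np.any(units == 0):
        return 0.0
    return float(np.mean(units**order) ** (1.0 / order))


def atkinson(d: UnitDistribution, epsilon: float) -> float:
    """Atkinson index AI(epsilon) = 1 - M_{1-epsilon}(units)/n_bar, in [0, 1].

    epsilon = 0 returns 0 for every distribution; epsilon = 1 uses the
    geometric mean.  Zero units with epsilon >= 1 force the power mean to
    0 and hence AI = 1; with 0 < epsilon < 1 the index stays finite.
    Negative epsilon is rejected.
    """
    epsilon = float(epsilon)
    if epsilon < 0:
        raise DomainError("inequality aversion epsilon must be non-negative")
    if epsilon == 0.0:
        return 0.0
    return 1.0 - _power_mean(d.units, 1.0 - epsilon) / d.mean


def ede_standard(d: UnitDistribution, epsilon: float) -> float:
    """Equally distributed equivalent standard n_eps = n_bar * (1 - AI).

    The common per-component unit level that, distributed equally, is
    welfare-equivalent to the observed distribution; the fraction of the
    total unit sum needed to grant it to every component is 1 - AI (an
    Atkinson index of 0.4 means 60% of the total would suffice).  At
    epsilon = 0 the standard is the plain mean n_bar.
    """
    return d.mean * (1.0 - atkinson(d, epsilon))


def epsilon_for_standard(
    d: UnitDistribution,
    target_standard: float,
    tol: Optional[float] = None,
) -> float:
    """Invert the EDE standard: find epsilon >= 0 with n_eps = target.

    n_eps falls monotonically from n_bar (at epsilon = 0) towards the
    minimum unit value as epsilon grows, so the root is unique.  The
    target must lie in (min(units), n_bar]; outside that range a
    :class:`DomainError` reports the achievable interval.  This is the
    reverse use of the index: pick a substantively meaningful standard
    (a reaction-time threshold, a clinical cutoff) and read off the
    aversion level that realises it.

    ``tol`` is the absolute tolerance on the standard; default 1e-8*n_bar.
    """
    target = float(target_standard)
    nbar = d.mean
    if tol is None:
        tol = 1e-8 * nbar
    lo_val = float(np.min(d.units))  # infimum of n_eps as epsilon -> inf
    if not (lo_val < target <= nbar):
        raise DomainError(
            f"target standard {target:g} outside achievable interval "
            f"({lo_val:g}, {nbar:g}]"
        )
    if abs(target - nbar) <= tol:
        return 0.0

    def gap(eps: float) -> float:
        return ede_standard(d, eps) - target

    hi = 1.0
    while gap(hi) > 0:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - target ~ lo_val, caught above
            raise DomainError(
                f"target standard {target:g} not reachable below epsilon 1e12"
            )
    eps = float(brentq(gap, 0.0, hi, xtol=1e-12, rtol=8.9e-16))
    if abs(ede_standard(d, eps) - target) > max(tol, 1e-6 * nbar):
        raise ConsistencyError("root finding failed to match the target standard")
    return eps


def atkinson_ge_link(
    ge_value: float,
    epsilon: float,
    d: Optional[UnitDistribution] = None,
) -> float:
    """Convert a generalized entropy value into the Atkinson index.

    ``ge_value`` must be GE computed at alpha = 1 - epsilon (the mean log
    deviation when epsilon = 1).  The conversion used is

        AI = 1 - [1 + epsilon*(epsilon - 1)*GE]**(1/(1 - epsilon)),  epsilon != 1
        AI = 1 - exp(-GE),                                           epsilon = 1

    which follows from writing both families in terms of the power mean of
    order 1 - epsilon and is exact (note the conversion sometimes quoted
    as AI = [eps(eps-1)GE]^(1/(1-eps)) omits the two unit terms and does
    not map into [0, 1]).

    When ``d`` is supplied the result is cross-checked against
    :func:`atkinson` on that distribution; disagreement beyond 1e-8 raises
    :class:`ConsistencyError`, surfacing a mismatched (alpha, epsilon)
    pairing rather than silently returning a wrong value.
    """
    epsilon = float(epsilon)
    if epsilon < 0:
        raise DomainError("inequality aversion epsilon must be non-negative")
    ge_value = float(ge_value)
    if ge_value < 0:
        raise DomainError("generalized entropy value must be non-negative")
    if epsilon == 1.0:
        ai = 1.0 - float(np.exp(-ge_value))
    else:
        base = 1.0 + epsilon * (epsilon - 1.0) * ge_value
        if base < 0:
            raise DomainError(
                f"GE value {ge_value:g} inconsistent with epsilon {epsilon:g}: "
                "conversion base is negative"
            )
        ai = 1.0 - base ** (1.0 / (1.0 - epsilon))
    if d is not None:
        direct = atkinson(d, epsilon)
        if abs(ai - direct) > 1e-8:
            raise ConsistencyError(
                f"GE-converted Atkinson {ai:.12g} disagrees with direct "
                f"value {direct:.12g}; was GE computed at alpha = 1 - epsilon?"
            )
    return ai
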