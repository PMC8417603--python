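"""Distributional tail ratios: Palma, S80:S20, and percentile ratios.

Tail ratios compare the two extremes of the unit distribution while
ignoring its middle, which makes them more informative about distribution
shape than purely area-based measures.  Two families are provided:

* *Share ratios* compare the unit share held by the top fraction of
  components to that held by the bottom fraction, read off the Lorenz
  polyline with linear interpolation at fractional cut points.  The Palma
  ratio uses top 10% vs bottom 40% (equality value 1/4); the S80:S20
  (quintile share) ratio uses top and bottom fifths (equality value 1).
* *Percentile ratios* compare two quantiles of the unit values:
  P90:P10 and P50:P10 are the conventional choices.  Quantiles use linear
  interpolation between order statistics (the "type 7" rule), recorded in
  the result metadata for reproducibility.

Tail ratios are intended for metric variables.  With few components the
tail fractions are poorly resolved (the "richest 20%" of three components
is not a meaningful set), so a caution is emitted when k is small relative
to the narrower tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .curves import lorenz_curve
from .distribution import UnitDistribution
from .errors import DomainError

__all__ = [
    "share_ratio",
    "percentile_ratio",
    "palma",
    "s80_s20",
    "p90_p10",
    "p50_p10",
    "QUANTILE_METHOD",
]

#: numpy quantile method used by percentile ratios (linear interpolation
#: between order statistics).
QUANTILE_METHOD = "linear"


def share_ratio(d: UnitDistribution, top_frac: float, bottom_frac: float) -> float:
    """Ratio of the unit share of the top ``top_frac`` of components to the
    share of the bottom ``bottom_frac``.

    Shares are evaluated on the ascending-sorted Lorenz polyline L with
    linear interpolation: bottom share = L(bottom_frac), top share =
    1 - L(1 - top_frac).  Fractions must lie in (0, 1) and must not
    overlap (top_frac + bottom_frac <= 1).  A zero bottom share returns
    +inf with a warning; a small component count (k < 1/min(frac)) draws
    an interpretation caution.
    """
    top_frac = float(top_frac)
    bottom_frac = float(bottom_frac)
    if not (0.0 < top_frac < 1.0 and 0.0 < bottom_frac < 1.0):
        raise DomainError("tail fractions must lie strictly between 0 and 1")
    if top_frac + bottom_frac > 1.0 + 1e-12:
        raise DomainError("top and bottom tail fractions overlap")
    if d.k < 1.0 / min(top_frac, bottom_frac):
        warnings.warn(
            f"only k={d.k} components: tail shares at fractions "
            f"({top_frac:g}, {bottom_frac:g}) rest on interpolation and "
            "should be interpreted with caution",
            UserWarning,
            stacklevel=2,
        )
    curve = lorenz_curve(d)
    bottom = float(curve.interpolate(bottom_frac))
    top = 1.0 - float(curve.interpolate(1.0 - top_frac))
    if bottom == 0.0:
        warnings.warn(
            "bottom tail holds no units; share ratio is infinite",
            UserWarning,
            stacklevel=2,
        )
        return float("inf")
    return top / bottom


def percentile_ratio(d: UnitDistribution, p_hi: float, p_lo: float) -> float:
    """Ratio of the ``p_hi``-th to the ``p_lo``-th percentile of the unit
    values (0 < p_lo < p_hi < 100), using linear interpolation between
    order statistics.  A zero low percentile returns +inf with a warning.
    """
    p_hi = float(p_hi)
    p_lo = float(p_lo)
    if not (0.0 < p_lo < p_hi < 100.0):
        raise DomainError("percentiles must satisfy 0 < p_lo < p_hi < 100")
    hi = float(np.quantile(d.units, p_hi / 100.0, method=QUANTILE_METHOD))
    lo = float(np.quantile(d.units, p_lo / 100.0, method=QUANTILE_METHOD))
    if lo == 0.0:
        warnings.warn(
            f"P{p_lo:g} is zero; percentile ratio is infinite",
            UserWarning,
            stacklevel=2,
        )
        return float("inf")
    return hi / lo


def palma(d: UnitDistribution) -> float:
    """Palma ratio: unit share of the top 10% of components over the
    bottom 40%.  1/4 at perfect equality; 1.8 means the top tenth holds
    1.8 times the units of the bottom two-fifths."""
    return share_ratio(d, 0.10, 0.40)


def s80_s20(d: UnitDistribution) -> float:
    """S80:S20 (quintile share) ratio: top fifth over bottom fifth of
    components; 1 at perfect equality."""
    return share_ratio(d, 0.20, 0.20)


def p90_p10(d: UnitDistribution) -> float:
    """P90:P10 percentile ratio of the unit values."""
    return percentile_ratio(d, 90.0, 10.0)


def p50_p10(d: UnitDistribution) -> float:
    """P50:P10 percentile ratio (median over 10th percentile)."""
    return percentile_ratio(d, 50.0, 10.0)
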