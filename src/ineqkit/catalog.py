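"""Catalog of the sixteen inequality and concentration measures.

Each :class:`MeasureCatalogEntry` bundles the static metadata of one
measure — canonical name, synonyms, model family, polarity, admissible
scale levels, theoretical limits as a function of the component count —
with the function that computes it.  The catalog drives the measures
report (one row per measure with limits instantiated at the data's k) and
lets callers check any computed value against its own theoretical range.

Polarity records whether the measure grows with inequality (Gini, Hoover,
Rosenbluth, HHI, Simpson, generalized entropy, Atkinson, tail ratios) or
with equality/diversity (Gini-Simpson, inverse Simpson, Shannon).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Tuple

from . import combinatorial, deviation, entropy, tails, welfare
from .distribution import UnitDistribution

__all__ = [
    "Polarity",
    "ModelFamily",
    "MeasureCatalogEntry",
    "MeasureResult",
    "CATALOG",
    "compute_measure",
]

INF = float("inf")


class Polarity(str, enum.Enum):
    INEQUALITY = "inequality"
    EQUALITY = "equality"


class ModelFamily(str, enum.Enum):
    DEVIATIONS = "deviations"
    COMBINATORICS = "combinatorics"
    ENTROPY = "entropy"
    SOCIAL_WELFARE = "social welfare"
    TAIL_RATIO = "tail ratio"


# Limits receive (k, k_nonnull, params) so measures that ignore null
# components (HHI, Shannon) can bound themselves by k' instead of k.
LimitsFn = Callable[[int, int, Mapping], Tuple[float, float]]
ComputeFn = Callable[[UnitDistribution, Mapping], float]


@dataclass(frozen=True)
class MeasureCatalogEntry:
    name: str
    synonyms: Tuple[str, ...]
    family: ModelFamily
    polarity: Polarity
    scale_levels: Tuple[str, ...]
    limits: LimitsFn
    compute: ComputeFn
    interpretation: str
    requires: Tuple[str, ...] = ()  # parameter names that must be supplied


@dataclass(frozen=True)
class MeasureResult:
    """A computed index value with its catalog context.

    ``lower``/``upper`` are the theoretical limits for the supplied data
    (upper may be +inf); for every finite-limit measure the value lies
    within them, up to floating tolerance.
    """

    name: str
    value: float
    polarity: Polarity
    scale_levels: Tuple[str, ...]
    lower: float
    upper: float

    def within_limits(self, tol: float = 1e-9) -> bool:
        if math.isnan(self.value):
            return False
        return self.value >= self.lower - tol and self.value <= self.upper + tol


_CAT = ("categorical", "metric")
_CAT_ONLY = ("categorical",)
_MET = ("metric",)


def _shannon_upper(k: int, k_nonnull: int, params: Mapping) -> Tuple[float, float]:
    base = params.get("log_base", 2)
    b = math.e if base == "e" else float(base)
    return (0.0, math.log(max(k_nonnull, 1)) / math.log(b))


CATALOG: dict[str, MeasureCatalogEntry] = {}


def _register(entry: MeasureCatalogEntry) -> None:
    CATALOG[entry.name] = entry


_register(MeasureCatalogEntry(
    "gini", (), ModelFamily.DEVIATIONS, Polarity.INEQUALITY, _CAT,
    lambda k, kn, p: (0.0, 1.0 - 1.0 / k),
    lambda d, p: deviation.gini(d),
    "Twice the area between the line of equality and the Lorenz curve",
))
_register(MeasureCatalogEntry(
    "gini_corrected", (), ModelFamily.DEVIATIONS, Polarity.INEQUALITY, _CAT,
    lambda k, kn, p: (0.0, 1.0),
    lambda d, p: deviation.gini_corrected(d),
    "Gini corrected for the number of components",
))
_register(MeasureCatalogEntry(
    "hoover", ("Pietra index", "Robin-Hood index", "Schutz index"),
    ModelFamily.DEVIATIONS, Polarity.INEQUALITY, _CAT,
    lambda k, kn, p: (0.0, 1.0 - 1.0 / k),
    lambda d, p: deviation.hoover(d),
    "Greatest vertical distance between line of equality and Lorenz curve",
))
_register(MeasureCatalogEntry(
    "hoover_corrected", (), ModelFamily.DEVIATIONS, Polarity.INEQUALITY, _CAT,
    lambda k, kn, p: (0.0, 1.0),
    lambda d, p: deviation.hoover_corrected(d),
    "Hoover corrected for the number of components",
))
_register(MeasureCatalogEntry(
    "rosenbluth", ("Hall-Tideman index",),
    ModelFamily.DEVIATIONS, Polarity.INEQUALITY, _CAT,
    lambda k, kn, p: (1.0 / k, 1.0),
    lambda d, p: deviation.rosenbluth(d),
    "Reciprocal of twice the area above the concentration curve",
))
_register(MeasureCatalogEntry(
    "hhi", ("Herfindahl index", "Hirschman index"),
    ModelFamily.COMBINATORICS, Polarity.INEQUALITY, _CAT,
    lambda k, kn, p: (1.0 / max(kn, 1), 1.0),
    lambda d, p: combinatorial.hhi(d),
    "Probability that two random units stem from the same component "
    "(urn with replacement)",
))
_register(MeasureCatalogEntry(
    "simpson", ("Simpson's D",),
    ModelFamily.COMBINATORICS, Polarity.INEQUALITY, _CAT_ONLY,
    lambda k, kn, p: (0.0, 1.0),
    lambda d, p: combinatorial.simpson(d),
    "Probability that two random units stem from the same component "
    "(urn without replacement)",
))
_register(MeasureCatalogEntry(
    "gini_simpson",
    ("Blau index", "Hunter-Gaston index", "Gibbs-Martin index",
     "probability of interspecific encounter"),
    ModelFamily.COMBINATORICS, Polarity.EQUALITY, _CAT_ONLY,
    lambda k, kn, p: (0.0, 1.0),
    lambda d, p: combinatorial.gini_simpson(d),
    "Probability that two random units stem from different components",
))
_register(MeasureCatalogEntry(
    "inverse_simpson", (),
    ModelFamily.COMBINATORICS, Polarity.EQUALITY, _CAT_ONLY,
    lambda k, kn, p: (1.0, INF),
    lambda d, p: combinatorial.inverse_simpson(d),
    "Reciprocal of the same-component probability",
))
_register(MeasureCatalogEntry(
    "shannon", ("Shannon-Weaver index", "Shannon-Wiener index"),
    ModelFamily.ENTROPY, Polarity.EQUALITY, _CAT_ONLY,
    _shannon_upper,
    lambda d, p: entropy.shannon(d, p.get("log_base", 2)),
    "Average information content of the unit distribution",
))
_register(MeasureCatalogEntry(
    "generalized_entropy", ("Theil index (alpha=1)", "mean log deviation (alpha=0)"),
    ModelFamily.ENTROPY, Polarity.INEQUALITY, _MET,
    lambda k, kn, p: (0.0, INF),
    lambda d, p: entropy.generalized_entropy(d, p["alpha"]),
    "Average redundancy in the unit distribution (tuning parameter alpha)",
    requires=("alpha",),
))
_register(MeasureCatalogEntry(
    "atkinson", (),
    ModelFamily.SOCIAL_WELFARE, Polarity.INEQUALITY, _MET,
    lambda k, kn, p: (0.0, 1.0),
    lambda d, p: welfare.atkinson(d, p["epsilon"]),
    "Fraction of the total unit sum dispensable at an equally distributed "
    "equivalent standard (aversion parameter epsilon)",
    requires=("epsilon",),
))
_register(MeasureCatalogEntry(
    "palma", (),
    ModelFamily.TAIL_RATIO, Polarity.INEQUALITY, _MET,
    lambda k, kn, p: (0.25, INF),
    lambda d, p: tails.palma(d),
    "Unit share of the top 10% of components over the bottom 40%",
))
_register(MeasureCatalogEntry(
    "s80_s20", ("20:20 ratio", "quintile share ratio"),
    ModelFamily.TAIL_RATIO, Polarity.INEQUALITY, _MET,
    lambda k, kn, p: (1.0, INF),
    lambda d, p: tails.s80_s20(d),
    "Unit share of the top fifth of components over the bottom fifth",
))
_register(MeasureCatalogEntry(
    "p90_p10", (),
    ModelFamily.TAIL_RATIO, Polarity.INEQUALITY, _MET,
    lambda k, kn, p: (1.0, INF),
    lambda d, p: tails.p90_p10(d),
    "90th percentile of the unit values over the 10th percentile",
))
_register(MeasureCatalogEntry(
    "p50_p10", (),
    ModelFamily.TAIL_RATIO, Polarity.INEQUALITY, _MET,
    lambda k, kn, p: (1.0, INF),
    lambda d, p: tails.p50_p10(d),
    "Median of the unit values over the 10th percentile",
))

assert len(CATALOG) == 16


def compute_measure(
    name: str,
    d: UnitDistribution,
    params: Optional[Mapping] = None,
) -> MeasureResult:
    """Compute one catalog measure and package it with its limits.

    ``params`` supplies per-measure parameters (``alpha``, ``epsilon``,
    ``log_base``).  Raises ``KeyError`` for an unknown measure and
    ``ValueError`` when a required parameter is missing.
    """
    entry = CATALOG[name]
    params = dict(params or {})
    missing = [r for r in entry.requires if params.get(r) is None]
    if missing:
        raise ValueError(f"measure {name!r} requires parameter(s) {missing}")
    lower, upper = entry.limits(d.k, d.k_nonnull, params)
    value = entry.compute(d, params)
    return MeasureResult(
        name=name,
        value=value,
        polarity=entry.polarity,
        scale_levels=entry.scale_levels,
        lower=lower,
        upper=upper,
    )
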