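"""Programmatic generation of test distributions.

Provides seeded, reproducible unit distributions from a handful of
families spanning the shapes the measures are designed to distinguish:
perfectly equal (``uniform``), maximally concentrated (``point_mass``),
block-structured replications of a value profile (``two_level``, which
reproduces worked pairs such as (360, 250, 150) and its two-way split
(180, 180, 125, 125, 75, 75)), right-skewed continuous families
(``lognormal``, ``pareto_like``), simplex-random shares
(``random_dirichlet``) and multinomial category counts
(``integer_counts``).

Everything is driven by :class:`FixtureSpec` and a
``numpy.random.default_rng`` seed, so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .distribution import Kind, UnitDistribution

__all__ = ["FixtureSpec", "generate", "FAMILIES"]

FAMILIES = (
    "uniform",
    "point_mass",
    "two_level",
    "lognormal",
    "pareto_like",
    "random_dirichlet",
    "integer_counts",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one generated distribution.

    ``total`` is the unit sum N (or the expected total for continuous
    families, where per-component values are scaled so the mean is
    ``total / k``).  ``values``/``replicate`` configure the two_level
    family: each value is split into ``replicate`` equal components.
    ``concentration`` is the symmetric Dirichlet parameter (smaller means
    more unequal shares).  ``sigma`` is the lognormal shape and ``tail``
    the Pareto tail exponent.
    """

    family: str
    k: int = 10
    total: float = 100.0
    seed: int = 0
    values: Optional[Sequence[float]] = None
    replicate: int = 1
    concentration: float = 1.0
    sigma: float = 1.0
    tail: float = 1.16

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; one of {FAMILIES}")
        if self.family != "two_level" and self.k < 1:
            raise ValueError("k must be at least 1")
        if self.family == "two_level":
            if not self.values:
                raise ValueError("two_level requires a 'values' sequence")
            if self.replicate < 1:
                raise ValueError("replicate must be a positive integer")
        if self.total <= 0:
            raise ValueError("total must be positive")


def generate(spec: FixtureSpec) -> UnitDistribution:
    """Generate the distribution described by ``spec`` (bit-reproducible
    for a fixed seed)."""
    rng = np.random.default_rng(spec.seed)
    fam = spec.family
    if fam == "uniform":
        units = np.full(spec.k, spec.total / spec.k)
        kind = Kind.METRIC
    elif fam == "point_mass":
        units = np.zeros(spec.k)
        units[0] = spec.total
        kind = Kind.METRIC
    elif fam == "two_level":
        vals = np.asarray(spec.values, dtype=float)
        units = np.repeat(vals / spec.replicate, spec.replicate)
        kind = Kind.METRIC
    elif fam == "lognormal":
        raw = rng.lognormal(mean=0.0, sigma=spec.sigma, size=spec.k)
        units = raw * (spec.total / raw.sum())
        kind = Kind.METRIC
    elif fam == "pareto_like":
        raw = rng.pareto(spec.tail, size=spec.k) + 1.0
        units = raw * (spec.total / raw.sum())
        kind = Kind.METRIC
    elif fam == "random_dirichlet":
        shares = rng.dirichlet(np.full(spec.k, spec.concentration))
        units = shares * spec.total
        kind = Kind.METRIC
    else:  # integer_counts
        n = int(round(spec.total))
        probs = rng.dirichlet(np.full(spec.k, spec.concentration))
        units = rng.multinomial(n, probs).astype(float)
        kind = Kind.CATEGORICAL
    return UnitDistribution(units, kind)
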