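"""The unit distribution: the central data model of ineqkit.

Every inequality or concentration measure in this package summarises a
*unit distribution*: a vector of non-negative units ``n_i`` (raw metric
values for individuals, or counts for the categories of a categorical
variable), one per *component*.  The total is ``N = sum(n_i)``, the number
of components is ``k``, the unit share of component *i* is
``p_i = n_i / N`` and the component mean is ``n_bar = N / k``.

This module defines :class:`UnitDistribution` together with construction
(with missing-value and negative-value policies), the per-component
distribution table, and the aliquot merging used for plotting large
inputs.  Zero components are retained at construction; individual measures
decide whether to drop them (the Herfindahl-Hirschman and Shannon indices
do, the deviation measures do not).
"""

from __future__ import annotations

import enum
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, NegativeValueError, NonNumericError

__all__ = [
    "Kind",
    "UnitDistribution",
    "make_distribution",
    "counts_from_labels",
    "shares",
    "distribution_table",
    "merge_to_aliquots",
]

_SHARE_TOL = 1e-12


class Kind(str, enum.Enum):
    """Scale level of the underlying variable.

    ``categorical``: units are counts of category occurrences (components
    are the categories).  ``metric``: units are raw non-negative values
    (components are the individuals).  ``ordinal``: an ordered categorical
    variable whose ordering is ignored — treated exactly as categorical.
    """

    CATEGORICAL = "categorical"
    METRIC = "metric"
    ORDINAL = "ordinal"

    @property
    def treated_as_categorical(self) -> bool:
        return self in (Kind.CATEGORICAL, Kind.ORDINAL)


@dataclass(frozen=True)
class UnitDistribution:
    """A validated vector of non-negative units, one per component.

    Parameters
    ----------
    units
        Non-negative reals ``n_i``; counts for categorical variables,
        raw values for metric variables.  Zeros are retained.
    kind
        Scale level of the variable (see :class:`Kind`).
    labels
        Optional component identifiers, same length as ``units``.

    Attributes (derived)
    --------------------
    k : number of components.
    total : total unit sum ``N`` (must be > 0).
    mean : component mean ``n_bar = N / k``.
    shares : unit shares ``p_i = n_i / N`` (sum to 1).
    """

    units: np.ndarray
    kind: Kind = Kind.METRIC
    labels: Optional[tuple] = None
    _shares: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.units, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise EmptyInputError("a unit distribution needs at least one component")
        if np.any(~np.isfinite(arr)):
            raise NonNumericError("units must be finite numbers")
        if np.any(arr < 0):
            bad = np.flatnonzero(arr < 0).tolist()
            raise NegativeValueError(f"negative units at indices {bad}")
        total = float(arr.sum())
        if total <= 0:
            raise EmptyInputError("total unit sum N must be positive")
        object.__setattr__(self, "units", arr)
        object.__setattr__(self, "kind", Kind(self.kind))
        if self.labels is not None:
            labels = tuple(self.labels)
            if len(labels) != arr.size:
                raise ValueError(
                    f"{len(labels)} labels for {arr.size} components"
                )
            object.__setattr__(self, "labels", labels)
        p = arr / total
        assert abs(p.sum() - 1.0) < 1e-9
        object.__setattr__(self, "_shares", p)

    # -- basic quantities -------------------------------------------------

    @property
    def k(self) -> int:
        """Number of components (zero components included)."""
        return int(self.units.size)

    @property
    def total(self) -> float:
        """Total unit sum N."""
        return float(self.units.sum())

    @property
    def mean(self) -> float:
        """Component mean n_bar = N / k."""
        return self.total / self.k

    @property
    def shares(self) -> np.ndarray:
        """Unit shares p_i = n_i / N; sum to 1 within 1e-12."""
        return self._shares

    @property
    def k_nonnull(self) -> int:
        """Number of non-null components (those with positive units)."""
        return int(np.count_nonzero(self.units))

    def nonnull(self) -> "UnitDistribution":
        """A copy with null (zero-unit) components dropped."""
        mask = self.units > 0
        if mask.all():
            return self
        labels = (
            tuple(l for l, m in zip(self.labels, mask) if m)
            if self.labels is not None
            else None
        )
        return UnitDistribution(self.units[mask], self.kind, labels)

    def sorted(self, descending: bool = False) -> "UnitDistribution":
        """A copy sorted by units (stable, so ties keep input order)."""
        order = np.argsort(self.units, kind="stable")
        if descending:
            order = order[::-1]
        labels = (
            tuple(self.labels[i] for i in order) if self.labels is not None else None
        )
        return UnitDistribution(self.units[order], self.kind, labels)

    def is_integer_counts(self, tol: float = 0.0) -> bool:
        return bool(np.all(self.units == np.floor(self.units)))

    def __len__(self) -> int:
        return self.k


def make_distribution(
    units: Iterable,
    kind: str | Kind = Kind.METRIC,
    na_policy: str = "drop",
    negative_policy: str = "error",
    labels: Optional[Sequence] = None,
) -> UnitDistribution:
    """Build a validated :class:`UnitDistribution` from raw input.

    Missing entries (``None`` or NaN) are dropped (``na_policy="drop"`` is
    the only policy, mirroring automatic NA handling in interactive use).
    Negative entries raise :class:`NegativeValueError` naming the offending
    indices unless ``negative_policy="remove"``, in which case they are
    removed.  Zeros are always retained.

    Raises
    ------
    NonNumericError
        If an entry is not interpretable as a number.
    EmptyInputError
        If no entries remain after NA removal.
    NegativeValueError
        If negatives are present under ``negative_policy="error"``.
    """
    if na_policy != "drop":
        raise ValueError(f"unknown na_policy {na_policy!r}")
    if negative_policy not in ("error", "remove"):
        raise ValueError(f"unknown negative_policy {negative_policy!r}")

    raw = list(units)
    values: list[float] = []
    kept_labels: list = []
    label_seq = list(labels) if labels is not None else None
    if label_seq is not None and len(label_seq) != len(raw):
        raise ValueError(f"{len(label_seq)} labels for {len(raw)} entries")
    for i, v in enumerate(raw):
        if v is None:
            continue
        try:
            x = float(v)
        except (TypeError, ValueError) as exc:
            raise NonNumericError(f"entry {i} ({v!r}) is not numeric") from exc
        if math.isnan(x):
            continue
        values.append(x)
        if label_seq is not None:
            kept_labels.append(label_seq[i])
    if not values:
        raise EmptyInputError("no numeric entries remain after dropping missing values")

    arr = np.asarray(values, dtype=float)
    neg = np.flatnonzero(arr < 0)
    if neg.size:
        if negative_policy == "error":
            raise NegativeValueError(
                f"negative units at indices {neg.tolist()}; "
                "pass negative_policy='remove' to drop them"
            )
        keep = arr >= 0
        arr = arr[keep]
        if label_seq is not None:
            kept_labels = [l for l, m in zip(kept_labels, keep) if m]
        if arr.size == 0:
            raise EmptyInputError("no entries remain after removing negative values")

    return UnitDistribution(
        arr, Kind(kind), tuple(kept_labels) if label_seq is not None else None
    )


def counts_from_labels(
    observations: Iterable, kind: str | Kind = Kind.CATEGORICAL
) -> UnitDistribution:
    """Tabulate category observations (e.g. the letters of a string) into a
    categorical count distribution.

    ``counts_from_labels("ABCD")`` yields four components with one unit
    each; ``counts_from_labels("AABB")`` two components with two units each.
    """
    counter = Counter(observations)
    if not counter:
        raise EmptyInputError("no observations to tabulate")
    cats = sorted(counter, key=str)
    return UnitDistribution(
        np.array([counter[c] for c in cats], dtype=float),
        Kind(kind),
        tuple(cats),
    )


def shares(d: UnitDistribution) -> np.ndarray:
    """Unit shares p_i = n_i / N of a distribution (sum to 1)."""
    return d.shares


def distribution_table(d: UnitDistribution) -> pd.DataFrame:
    """Per-component distribution table, sorted ascending by units.

    Columns (percentages on the 0–100 scale):

    - ``value``: the units of the component, sorted ascending;
    - ``unit_share_pct`` and ``cum_unit_share_pct``;
    - ``component_share_pct`` and ``cum_component_share_pct``.

    Both cumulative columns end at 100 (within floating tolerance); the
    cumulative unit-share column equals the Lorenz-curve y-values at the
    component boundaries.
    """
    ds = d.sorted()
    p = ds.shares
    k = ds.k
    comp = np.full(k, 100.0 / k)
    table = pd.DataFrame(
        {
            "value": ds.units,
            "unit_share_pct": 100.0 * p,
            "cum_unit_share_pct": 100.0 * np.cumsum(p),
            "component_share_pct": comp,
            "cum_component_share_pct": 100.0 * np.arange(1, k + 1) / k,
        }
    )
    if ds.labels is not None:
        table.insert(0, "component", list(ds.labels))
    return table


def merge_to_aliquots(d: UnitDistribution, parts: int = 20) -> UnitDistribution:
    """Merge an ascending-sorted distribution into ``parts`` aliquot parts.

    Intended for plotting only: when k exceeds ``parts`` the components are
    merged into ``parts`` equal slices (5% each for the default 20) of the
    ascending-sorted distribution, each aliquot holding exactly ``k/parts``
    component-equivalents.  When k does not divide evenly, boundary
    components are split proportionally so the total N is preserved
    exactly.  All index calculations must use the unmerged distribution;
    this function never changes any index computed on its input.

    Returns the distribution unchanged when ``k <= parts``.
    """
    if parts < 1:
        raise ValueError("parts must be a positive integer")
    if d.k <= parts:
        return d
    ds = d.sorted()
    # Cumulative units as a function of (fractional) component index; the
    # aliquot sums are differences of this piecewise-linear function at
    # equally spaced cut points.
    cum = np.concatenate([[0.0], np.cumsum(ds.units)])
    cuts = np.linspace(0.0, ds.k, parts + 1)
    cum_at_cuts = np.interp(cuts, np.arange(ds.k + 1), cum)
    cum_at_cuts[-1] = cum[-1]  # exact N at the right edge
    merged = np.diff(cum_at_cuts)
    return UnitDistribution(merged, ds.kind)
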