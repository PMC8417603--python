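"""Lorenz and concentration curves.

The Lorenz curve plots cumulative unit share against cumulative component
share with components sorted ascending; for discrete components it is
exactly piecewise linear, so it is stored as a vertex polyline and all
areas use the trapezoid rule.  The concentration curve (used by the
Rosenbluth index) sorts components descending and runs over component
ranks 0..k on the x-axis, so it lies on or above the diagonal of the k-by-1
rectangle.

The geometry computed here gives the deviation-model measures their
graphical meaning: the Gini index is twice the area between the diagonal
and the Lorenz curve, the Hoover index is the maximum vertical distance
between them, and the Rosenbluth index is the reciprocal of twice the area
above the concentration curve.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .distribution import UnitDistribution
from .errors import CurveKindError

__all__ = [
    "CurveKind",
    "CurveCoordinates",
    "lorenz_curve",
    "concentration_curve",
    "lorenz_gap_area",
    "max_vertical_gap",
    "concentration_area_above",
]


class CurveKind(str, enum.Enum):
    LORENZ = "lorenz"
    CONCENTRATION = "concentration"


@dataclass(frozen=True)
class CurveCoordinates:
    """Vertex polyline of a Lorenz or concentration curve.

    ``x`` is the cumulative component share in [0, 1] (Lorenz) or the
    component rank 0..k (concentration); ``y`` is the cumulative unit share
    in [0, 1].  Linear interpolation between vertices is the intended
    reading.
    """

    x: np.ndarray
    y: np.ndarray
    kind: CurveKind
    ordering: str  # "ascending" (lorenz) or "descending" (concentration)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1 or x.size < 2:
            raise ValueError("curve needs matching 1-d x and y with >= 2 vertices")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @property
    def k(self) -> int:
        return self.x.size - 1

    def interpolate(self, at: float | np.ndarray) -> np.ndarray:
        """Curve height by linear interpolation between vertices."""
        return np.interp(at, self.x, self.y)


def lorenz_curve(d: UnitDistribution) -> CurveCoordinates:
    """Lorenz curve of a distribution: k+1 vertices from (0,0) to (1,1).

    Vertex j has x = j/k and y = cumulative share of the j smallest
    components.  Equality puts every vertex on the diagonal; with all units
    in one component the curve hugs the x-axis and rises to (1, 1) at the
    final component.
    """
    ds = d.sorted()
    y = np.concatenate([[0.0], np.cumsum(ds.shares)])
    y[-1] = 1.0
    x = np.arange(ds.k + 1) / ds.k
    return CurveCoordinates(x, y, CurveKind.LORENZ, "ascending")


def concentration_curve(d: UnitDistribution) -> CurveCoordinates:
    """Concentration (Rosenbluth) curve: components sorted descending,
    vertices (0,0), (1, p_(1)), ..., (k, 1) over component ranks."""
    ds = d.sorted(descending=True)
    y = np.concatenate([[0.0], np.cumsum(ds.shares)])
    y[-1] = 1.0
    x = np.arange(ds.k + 1, dtype=float)
    return CurveCoordinates(x, y, CurveKind.CONCENTRATION, "descending")


def _require(curve: CurveCoordinates, kind: CurveKind) -> None:
    if curve.kind is not kind:
        raise CurveKindError(f"expected a {kind.value} curve, got {curve.kind.value}")


def lorenz_gap_area(curve: CurveCoordinates) -> float:
    """Area A between the line of equality and the Lorenz curve.

    Trapezoid rule on the polyline; lies in [0, 0.5).  The Gini index is
    G = A / (A + B) = 2A, where A + B = 0.5 is the whole triangle below
    the diagonal.
    """
    _require(curve, CurveKind.LORENZ)
    under = float(np.trapezoid(curve.y, curve.x))
    return 0.5 - under


def max_vertical_gap(curve: CurveCoordinates) -> float:
    """Maximum vertical distance between the Lorenz curve and the line of
    equality; equals the Hoover index.  The maximum over the polyline is
    attained at a vertex."""
    _require(curve, CurveKind.LORENZ)
    return float(np.max(curve.x - curve.y))


def concentration_area_above(curve: CurveCoordinates) -> float:
    """Area A above the concentration curve within the k-by-1 rectangle.

    Ranges from 0.5 (all units in one component: the curve jumps to (1,1)
    and the area above it is the right triangle of area 1/2) to k/2
    (equality: the curve is the rectangle diagonal).  The Rosenbluth index
    is 1/(2A).
    """
    _require(curve, CurveKind.CONCENTRATION)
    under = float(np.trapezoid(curve.y, curve.x))
    return float(curve.x[-1]) - under
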