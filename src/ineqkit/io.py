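"""Dataset input and report output.

Mirrors the dataset-processing workflow of an interactive calculator:
read a delimited text file (configurable separator, optional header),
select one numeric column, drop missing values (with a logged count),
guard against negative values, then compute a measures report — one row
per requested measure with its polarity, admissible scale levels,
theoretical limits instantiated at the data's k, and the computed value —
and export distribution tables and curve coordinates.

Display values are rounded to 5 decimal places; every exported table also
carries a full-precision machine-readable column so round-tripping does
not lose accuracy.  Dropped-NA and removed-negative counts are reported
on every run, because silently modified data is unacceptable in a
statistics tool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .catalog import CATALOG, compute_measure
from .curves import concentration_curve, lorenz_curve
from .distribution import (
    Kind,
    UnitDistribution,
    distribution_table,
    make_distribution,
    merge_to_aliquots,
)
from .errors import IneqkitError, NonNumericError

__all__ = ["RunConfig", "read_column", "measures_report", "export_curve"]

logger = logging.getLogger("ineqkit")

DISPLAY_DECIMALS = 5

#: Components are merged into this many aliquot parts for plotting when k
#: exceeds it; calculations always use the unmerged distribution.
PLOT_ALIQUOTS = 20


@dataclass
class RunConfig:
    """Configuration of one calculation run.

    ``measures`` defaults to the full catalog.  ``params`` carries the
    per-measure parameters: ``alpha`` (generalized entropy), ``epsilon``
    (Atkinson), ``log_base`` (Shannon), ``top_frac``/``bottom_frac``
    (user-defined share ratio), ``percentiles`` (user-defined percentile
    ratio as a (hi, lo) pair).
    """

    column: Optional[Union[str, int]] = None
    separator: str = ","
    header: bool = True
    negative_policy: str = "error"
    kind: Kind = Kind.METRIC
    measures: Optional[Sequence[str]] = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.measures is not None:
            unknown = [m for m in self.measures if m not in CATALOG]
            if unknown:
                raise ValueError(
                    f"unknown measure(s) {unknown}; available: {sorted(CATALOG)}"
                )


def read_column(
    path: Union[str, Path],
    column: Optional[Union[str, int]] = None,
    separator: str = ",",
    header: bool = True,
    negative_policy: str = "error",
    kind: Union[str, Kind] = Kind.METRIC,
) -> UnitDistribution:
    """Read one numeric column of a delimited text file into a distribution.

    ``column`` selects by header name (or 0-based position when there is
    no header, or as an integer); ``None`` takes the first column.
    Missing values are dropped and counted; negative values follow
    ``negative_policy`` ("error" or "remove").  A missing column raises an
    error listing the available columns; a non-numeric column raises
    :class:`NonNumericError`.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=separator, header=0 if header else None)
    if column is None:
        series = frame.iloc[:, 0]
    else:
        if isinstance(column, int) and column not in frame.columns:
            if not 0 <= column < frame.shape[1]:
                raise KeyError(
                    f"column index {column} out of range; file has "
                    f"{frame.shape[1]} column(s): {list(frame.columns)}"
                )
            series = frame.iloc[:, column]
        elif column in frame.columns:
            series = frame[column]
        else:
            raise KeyError(
                f"column {column!r} not found; available columns: "
                f"{list(frame.columns)}"
            )
    numeric = pd.to_numeric(series, errors="coerce")
    # entries that are present but not parseable as numbers are an error,
    # not silently-dropped NAs
    bad = series.notna() & numeric.isna()
    if bad.any():
        examples = series[bad].head(3).tolist()
        raise NonNumericError(
            f"column {series.name!r} contains non-numeric entries, e.g. {examples}"
        )
    n_missing = int(numeric.isna().sum())
    if n_missing:
        logger.info("dropped %d missing value(s) from column %r", n_missing, series.name)
    values = numeric.dropna().to_numpy(dtype=float)
    n_neg = int(np.sum(values < 0))
    dist = make_distribution(
        values, kind=kind, negative_policy=negative_policy
    )
    if n_neg and negative_policy == "remove":
        logger.info("removed %d negative value(s) from column %r", n_neg, series.name)
    return dist


def measures_report(
    d: UnitDistribution,
    config: Optional[RunConfig] = None,
) -> pd.DataFrame:
    """Compute the requested measures into a report table.

    One row per measure with columns: ``measure``, ``polarity``,
    ``scale_levels``, ``lower``, ``upper`` (limits at the data's k),
    ``value`` (rounded to 5 decimals) and ``value_exact`` (full
    precision).  A measure that is inapplicable to the data (e.g. the
    Simpson index on non-integer metric values) or missing a parameter
    gets an error marker in its row and the run continues.
    """
    config = config or RunConfig()
    names = list(config.measures) if config.measures is not None else list(CATALOG)
    rows = []
    for name in names:
        entry = CATALOG[name]
        try:
            res = compute_measure(name, d, config.params)
            value, exact, note = round(res.value, DISPLAY_DECIMALS), res.value, ""
            lower, upper = res.lower, res.upper
        except (IneqkitError, ValueError, TypeError) as exc:
            value, exact, note = np.nan, np.nan, f"error: {exc}"
            lower, upper = entry.limits(d.k, d.k_nonnull, config.params)
        rows.append(
            {
                "measure": name,
                "polarity": entry.polarity.value,
                "scale_levels": ", ".join(entry.scale_levels),
                "lower": lower,
                "upper": upper,
                "value": value,
                "value_exact": exact,
                "note": note,
            }
        )
    return pd.DataFrame(rows)


def export_distribution_table(
    d: UnitDistribution, path: Union[str, Path], separator: str = ","
) -> pd.DataFrame:
    """Write the per-component distribution table as delimited text."""
    table = distribution_table(d)
    table.to_csv(path, sep=separator, index=False)
    return table


def export_curve(
    d: UnitDistribution,
    which: str,
    path: Union[str, Path],
    png: Optional[Union[str, Path]] = None,
) -> pd.DataFrame:
    """Export Lorenz or concentration curve coordinates (and optionally a
    rendered plot).

    ``which`` is ``"lorenz"`` or ``"concentration"``.  For plotting, a
    distribution with more than 20 components is first merged into 20
    aliquot parts — the exported polyline then has 21 vertices — but no
    index calculation ever uses the merged distribution.  Coordinates are
    written as two-column delimited text; ``png`` additionally renders the
    curve with the gap to the line of equality shaded.
    """
    if which not in ("lorenz", "concentration"):
        raise ValueError(f"which must be 'lorenz' or 'concentration', got {which!r}")
    plotted = merge_to_aliquots(d, PLOT_ALIQUOTS)
    curve = lorenz_curve(plotted) if which == "lorenz" else concentration_curve(plotted)
    frame = pd.DataFrame({"x": curve.x, "y": curve.y})
    frame.to_csv(path, index=False)
    if png is not None:
        _render_curve(curve, which, png)
    return frame


def _render_curve(curve, which: str, png: Union[str, Path]) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    diag_y = curve.x / curve.x[-1]
    ax.plot(curve.x, diag_y, "--", color="grey", label="line of equality")
    ax.plot(curve.x, curve.y, color="C0", label=f"{which} curve")
    ax.fill_between(curve.x, curve.y, diag_y, color="C0", alpha=0.25)
    ax.set_xlabel(
        "cumulative component share" if which == "lorenz" else "component rank"
    )
    ax.set_ylabel("cumulative unit share")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(png, dpi=150)
    plt.close(fig)
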