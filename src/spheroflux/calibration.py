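"""Standard curves linking spheroid area (or protein/DNA content) to viable
cells, and size-class binning of the resulting cell-count estimates.

Calibration points come from pooled digestion counts: a tube of 8-15
spheroids is trypsinized and counted, and the pool totals are averaged to
per-spheroid values before the ordinary-least-squares fit. The intercept is
estimated rather than forced through the origin (dead-core material
contributes area but no viable cells).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError, ValidationError

METHODS = ("area", "protein", "dna")

#: Default size-class bin edges in cells. The published class labels are
#: gapped ((07-10)k, (11-15)k, (16-22)k); boundaries between them sit at the
#: label midpoints so every count in [7000, 22000] maps to exactly one class.
DEFAULT_SIZE_CLASS_EDGES = (7_000, 10_500, 15_500, 22_000)
DEFAULT_SIZE_CLASS_LABELS = ("(07-10)k", "(11-15)k", "(16-22)k")
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class CalibrationPoint:
    """One (predictor, viable-cell) observation, already per-spheroid.

    ``from_pool`` converts pooled-digestion totals (8-15 spheroids per tube)
    to per-spheroid means.
    """

    predictor: float  # um^2 (area), ug (protein) or ng (DNA)
    viable_cells: float
    n_spheroids_pooled: int = 1

    def __post_init__(self) -> None:
        if self.n_spheroids_pooled < 1:
            raise ValidationError("n_spheroids_pooled must be >= 1")
        if self.viable_cells < 0:
            raise ValidationError("viable_cells must be >= 0")
        if self.viable_cells > 0 and self.predictor <= 0:
            raise ValidationError("predictor must be positive when viable_cells > 0")

    @classmethod
    def from_pool(cls, predictor_total: float, viable_cells_total: float,
                  n_spheroids_pooled: int) -> "CalibrationPoint":
        n = int(n_spheroids_pooled)
        return cls(
            predictor=predictor_total / n,
            viable_cells=viable_cells_total / n,
            n_spheroids_pooled=n,
        )


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear map viable_cells = slope * predictor + intercept."""

    method: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    predictor_min: float
    predictor_max: float

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"method must be one of {METHODS}")
        if self.n_points < 2:
            raise ValidationError("a curve needs >= 2 points")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValidationError("r_squared outside [0, 1]")


@dataclass(frozen=True)
class ContentPerCell:
    """Per-cell protein (ug) or DNA (ng) content with a coating blank."""

    method: str
    value: float
    blank: float = 0.0

    def __post_init__(self) -> None:
        if self.method not in ("protein", "dna"):
            raise ValidationError("content method must be 'protein' or 'dna'")
        if self.value <= 0:
            raise ValidationError("per-cell content must be positive")
        if self.blank < 0:
            raise ValidationError("blank must be >= 0")


def fit_calibration(
    points: list[CalibrationPoint],
    method: str = "area",
    weight_by_pool_size: bool = False,
) -> CalibrationCurve:
    """Ordinary least squares of viable cells on the predictor.

    With ``weight_by_pool_size`` each point is weighted by the number of
    spheroids pooled into it (off by default).
    """
    x = np.array([p.predictor for p in points], dtype=float)
    y = np.array([p.viable_cells for p in points], dtype=float)
    if np.unique(x).size < 2:
        raise FitError("need >= 2 distinct predictor values to fit a line")

    if weight_by_pool_size:
        w = np.array([p.n_spheroids_pooled for p in points], dtype=float)
        slope, intercept = np.polyfit(x, y, 1, w=np.sqrt(w))
        yhat = slope * x + intercept
        ybar = np.average(y, weights=w)
        ss_res = np.sum(w * (y - yhat) ** 2)
        ss_tot = np.sum(w * (y - ybar) ** 2)
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    else:
        res = stats.linregress(x, y)
        slope, intercept = res.slope, res.intercept
        r2 = res.rvalue**2

    return CalibrationCurve(
        method=method,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(np.clip(r2, 0.0, 1.0)),
        n_points=len(points),
        predictor_min=float(x.min()),
        predictor_max=float(x.max()),
    )


def read_calibration_table(path) -> list[CalibrationPoint]:
    """Read ``predictor_value,viable_cells,n_pooled,method`` CSV rows.

    Rows are interpreted as per-spheroid values (pool averaging is assumed
    done upstream when n_pooled > 1 totals are recorded; use
    ``CalibrationPoint.from_pool`` for raw pool totals).
    """
    df = pd.read_csv(path)
    required = {"predictor_value", "viable_cells"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"calibration table missing columns {sorted(missing)}")
    n_pooled = df["n_pooled"] if "n_pooled" in df.columns else pd.Series(1, index=df.index)
    return [
        CalibrationPoint(
            predictor=float(r.predictor_value),
            viable_cells=float(r.viable_cells),
            n_spheroids_pooled=int(n),
        )
        for r, n in zip(df.itertuples(), n_pooled)
    ]


def estimate_cells_from_area(
    curve: CalibrationCurve, area_um2: float
) -> tuple[int, bool]:
    """Cell count from area via the calibration line.

    Returns ``(cells, extrapolated_flag)``; the flag is set when the area
    falls outside twice the calibrated predictor range. Negative raw
    estimates clamp to zero with a warning.
    """
    if curve.method != "area":
        raise ValidationError(f"curve method is {curve.method!r}, expected 'area'")
    raw = curve.slope * area_um2 + curve.intercept
    extrapolated = not (curve.predictor_min / 2.0 <= area_um2 <= curve.predictor_max * 2.0)
    if raw < 0:
        warnings.warn(
            f"negative cell estimate ({raw:.1f}) clamped to 0 for area {area_um2:.0f} um^2",
            stacklevel=2,
        )
        return 0, extrapolated
    return int(round(raw)), extrapolated


def estimate_cells_from_content(total: float, per_cell: ContentPerCell) -> int:
    """Cell count from total protein/DNA content after blank subtraction."""
    net = total - per_cell.blank
    if net < 0:
        warnings.warn(
            f"total content {total} below blank {per_cell.blank}; returning 0",
            stacklevel=2,
        )
        return 0
    return int(round(net / per_cell.value))


def assign_size_class(
    cells: float,
    edges: tuple[float, ...] = DEFAULT_SIZE_CLASS_EDGES,
    labels: tuple[str, ...] = DEFAULT_SIZE_CLASS_LABELS,
) -> str:
    """Bin a cell count into a size class; outside the edges -> unclassified.

    Bins are half-open [edge_i, edge_{i+1}) except the last, which includes
    its upper edge.
    """
    if len(edges) != len(labels) + 1:
        raise ValidationError("need len(edges) == len(labels) + 1")
    if cells < 0:
        raise ValidationError("cells must be >= 0")
    for i, label in enumerate(labels):
        lo, hi = edges[i], edges[i + 1]
        if lo <= cells < hi or (i == len(labels) - 1 and cells == hi):
            return label
    return UNCLASSIFIED
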