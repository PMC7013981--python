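"""Areal-weighted transfer of gridded surfaces onto county polygons.

Gridded emission masses, land-use class areas and night-light luminosities
are extensive quantities: when a cell straddles a county border its value
is split among counties in proportion to overlap area, so county totals
conserve the grid total exactly.  From the county totals the module builds
the model's indicators: annual emission intensity (kg/km2, logged), the
urban land development intensity ULDI (urban construction land area over
county area, in [0, 1]) and the luminosity density LD.

Grids are supplied as cell tables (x, y cell centres + value, optionally a
month column) or as explicit shapely cell polygons; no reprojection is
performed — supply geometries and areas in one equal-area CRS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

__all__ = [
    "GridSurface",
    "areal_weight_transfer",
    "annualize_monthly",
    "emission_intensity",
    "uldi",
    "luminosity_density",
]

_EXTENSIVE = "extensive"
_INTENSIVE = "intensive"


@dataclass
class GridSurface:
    """A collection of non-overlapping cells with one value each."""

    cells: list[BaseGeometry]
    values: np.ndarray
    semantics: str = _EXTENSIVE  # mass-like quantities split by area share
    period: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.cells) != len(self.values):
            raise ValueError("one value per cell required")
        if not np.isfinite(self.values).all():
            raise ValueError("cell values must be finite")
        if self.semantics not in (_EXTENSIVE, _INTENSIVE):
            raise ValueError(f"unknown semantics {self.semantics!r}")

    @property
    def total(self) -> float:
        return float(self.values.sum())

    @classmethod
    def regular(
        cls,
        values: np.ndarray,
        origin: tuple[float, float] = (0.0, 0.0),
        resolution: float = 1.0,
        **kw,
    ) -> "GridSurface":
        """Build from a 2-D array laid out row-major from ``origin`` upward."""
        values = np.asarray(values, dtype=float)
        x0, y0 = origin
        cells, flat = [], []
        for i in range(values.shape[0]):
            for j in range(values.shape[1]):
                cells.append(
                    box(
                        x0 + j * resolution,
                        y0 + i * resolution,
                        x0 + (j + 1) * resolution,
                        y0 + (i + 1) * resolution,
                    )
                )
                flat.append(values[i, j])
        return cls(cells, np.array(flat), **kw)

    @classmethod
    def from_cell_table(
        cls, df: pd.DataFrame, resolution: float, value: str = "value", **kw
    ) -> "GridSurface":
        """Cells as squares of side ``resolution`` centred at (x, y)."""
        half = resolution / 2.0
        cells = [
            box(x - half, y - half, x + half, y + half)
            for x, y in zip(df["x"], df["y"])
        ]
        return cls(cells, df[value].to_numpy(dtype=float), **kw)


def areal_weight_transfer(
    surface: GridSurface,
    polygons: list[BaseGeometry],
    unit_ids: list[str] | None = None,
) -> pd.Series:
    """Split each cell's value among intersecting units by overlap-area share.

    County totals over any tiling of the grid footprint conserve the grid
    total.  Only extensive (mass-like) surfaces may be transferred this way.
    """
    if surface.semantics != _EXTENSIVE:
        raise ValueError(
            "areal weighting applies to extensive quantities; intensive "
            "surfaces must be converted to totals per cell first"
        )
    if unit_ids is None:
        unit_ids = [str(i) for i in range(len(polygons))]
    totals = np.zeros(len(polygons))
    tree = STRtree(surface.cells)
    for u, poly in enumerate(polygons):
        for ci in tree.query(poly):
            ci = int(ci)
            cell = surface.cells[ci]
            overlap = poly.intersection(cell).area
            if overlap > 0.0:
                totals[u] += surface.values[ci] * overlap / cell.area
    return pd.Series(totals, index=pd.Index(unit_ids, name="unit_id"))


def annualize_monthly(monthly: pd.DataFrame, value: str = "value") -> pd.DataFrame:
    """Sum 12 monthly unit totals into annual cumulative totals.

    ``monthly`` needs columns unit_id, year, month, and the value column;
    every unit-year must have exactly the months 1..12.
    """
    required = {"unit_id", "year", "month", value}
    if not required.issubset(monthly.columns):
        raise ValueError(f"monthly table needs columns {sorted(required)}")
    gaps = []
    for (u, yr), grp in monthly.groupby(["unit_id", "year"]):
        months = sorted(grp["month"].tolist())
        if months != list(range(1, 13)):
            missing = sorted(set(range(1, 13)) - set(months))
            gaps.append((u, yr, missing))
    if gaps:
        raise ValueError(f"incomplete months for unit-years: {gaps}")
    out = (
        monthly.groupby(["unit_id", "year"], as_index=False)[value]
        .sum()
        .rename(columns={value: "annual_total"})
    )
    return out


def emission_intensity(
    total: float | np.ndarray,
    area: float | np.ndarray,
    log_base: float | None = math.e,
    zero_policy: str = "error",
    zero_floor: float | None = None,
) -> float | np.ndarray:
    """Log of annual emission mass per unit area (kg/km2 by default scale).

    ``log_base=None`` returns the raw intensity.  Zero totals either raise
    (default) or are replaced by ``zero_floor`` (an intensity value, e.g.
    half the smallest positive intensity in the batch) when
    ``zero_policy='floor'``.
    """
    total = np.asarray(total, dtype=float)
    area = np.asarray(area, dtype=float)
    if np.any(area <= 0):
        raise ValueError("county area must be positive")
    if np.any(total < 0):
        raise ValueError("emission totals must be non-negative")
    intensity = total / area
    if np.any(intensity == 0):
        if zero_policy == "floor" and zero_floor is not None:
            intensity = np.where(intensity == 0, zero_floor, intensity)
        else:
            raise ValueError(
                "zero annual total: log intensity undefined "
                "(use zero_policy='floor' with a zero_floor)"
            )
    if log_base is None:
        out = intensity
    else:
        out = np.log(intensity) / np.log(log_base)
    return float(out) if out.ndim == 0 else out


def uldi(urban_land_area: float, county_area: float) -> float:
    """Urban construction land area over county area, a fraction in [0, 1]."""
    if county_area <= 0:
        raise ValueError("county area must be positive")
    if urban_land_area < 0:
        raise ValueError("urban land area must be non-negative")
    if urban_land_area > county_area * (1 + 1e-12):
        raise ValueError("urban land area exceeds county area")
    return min(urban_land_area / county_area, 1.0)


def luminosity_density(total_luminosity: float, county_area: float) -> float:
    """Total night-light output of a county divided by its area (LD)."""
    if county_area <= 0:
        raise ValueError("county area must be positive")
    if total_luminosity < 0:
        raise ValueError("luminosity must be non-negative")
    return total_luminosity / county_area
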