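"""Areal-weighted transfer of gridded surfaces onto counties.

Builds a toy monthly emission grid and a land-use grid over two counties,
transfers the cell values by overlap-area share, and derives the county
indicators: annual log emission intensity, ULDI and luminosity density.
"""

import numpy as np
import pandas as pd
from shapely.geometry import box

from stcar import (
    GridSurface,
    annualize_monthly,
    areal_weight_transfer,
    emission_intensity,
    luminosity_density,
    uldi,
)

rng = np.random.default_rng(5)
counties = [box(0, 0, 6, 10), box(6, 0, 10, 10)]  # 60 and 40 km2
ids = ["west", "east"]

# monthly emission surfaces (kg per 1-km2 cell), aggregated to annual totals
monthly_rows = []
for month in range(1, 13):
    surface = GridSurface.regular(rng.exponential(30.0, size=(10, 10)))
    totals = areal_weight_transfer(surface, counties, ids)
    for uid, val in totals.items():
        monthly_rows.append(
            {"unit_id": uid, "year": 2015, "month": month, "value": val}
        )
annual = annualize_monthly(pd.DataFrame(monthly_rows))
print(annual)

for _, row in annual.iterrows():
    area = 60.0 if row["unit_id"] == "west" else 40.0
    print(
        f"{row['unit_id']}: {row['annual_total']:.0f} kg over {area:.0f} km2 "
        f"-> log intensity {emission_intensity(row['annual_total'], area):.3f}"
    )

# urban land and night lights on the same geography
urban = (rng.random((10, 10)) < 0.15).astype(float)  # 1 km2 urban cells
lights = urban * rng.uniform(20, 60, size=(10, 10))
urban_area = areal_weight_transfer(GridSurface.regular(urban), counties, ids)
lum = areal_weight_transfer(GridSurface.regular(lights), counties, ids)
for uid, area in zip(ids, (60.0, 40.0)):
    print(
        f"{uid}: ULDI {uldi(urban_area[uid], area):.3f}, "
        f"LD {luminosity_density(lum[uid], area):.3f}"
    )
# Mass is conserved exactly: county totals sum to the grid totals, however
# the county borders cut the cells.
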