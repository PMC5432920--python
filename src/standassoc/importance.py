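"""Importance values: density, frequency, dominance and their relative forms.

The importance value (IV) of a species is the mean of its relative density
(RD), relative frequency (RF) and relative dominance (Rd), each expressed
as a percentage of the stand total, so that IV sums to 100 % over species.
Dominance is basal area: the summed stem cross-section at breast height.
"""

from __future__ import annotations

import math
import warnings

import pandas as pd

from .stemmap import STAGES, QuadratGrid, Stage, StemMap, locate_quadrat, quadrat_index

IV_COLUMNS = [
    "species",
    "n_trees",
    "density",
    "relative_density",
    "frequency",
    "relative_frequency",
    "dominance",
    "relative_dominance",
    "importance_value",
]


def basal_area(dbh: float) -> float:
    """Cross-sectional area (m^2) at breast height of one stem of DBH `dbh` cm.

    pi * (dbh / 200)^2 — the diameter is halved for the radius and divided
    by 100 to convert cm to m.
    """
    if not dbh > 0:
        raise ValueError(f"DBH must be positive, got {dbh}")
    return math.pi * (dbh / 200.0) ** 2


def iv_components(
    stemmap: StemMap,
    grid: QuadratGrid,
    stage_filter: Stage | None = None,
    printed_variants: bool = False,
) -> pd.DataFrame:
    """Per-species density, frequency, dominance and importance value.

    Density D is trees per hectare; frequency F the proportion of quadrats
    occupied; dominance d basal area in m^2/ha.  The relative forms divide by
    the stand totals (RD = D_i / sum_j D_j * 100 etc.) so each sums to 100 %,
    and IV = (RD + RF + Rd) / 3.

    ``printed_variants`` switches RD/RF to the denominators some survey
    manuals print (count over total density; frequency over species count);
    those columns no longer sum to 100 % and are offered only for
    comparability.
    """
    df = stemmap.subset(stage=stage_filter)
    if df.empty:
        warnings.warn(
            f"no trees{f' in stage {stage_filter!r}' if stage_filter else ''}; "
            "empty importance-value table",
            stacklevel=2,
        )
        return pd.DataFrame(columns=IV_COLUMNS)

    area_ha = stemmap.geometry.area_ha
    rows = []
    for sp, grp in df.groupby("species", sort=True):
        occupied = {
            quadrat_index(*locate_quadrat(x, y, grid), grid)
            for x, y in zip(grp["x"], grp["y"])
        }
        rows.append(
            {
                "species": sp,
                "n_trees": len(grp),
                "density": len(grp) / area_ha,
                "frequency": len(occupied) / grid.n_quadrats,
                "dominance": sum(basal_area(v) for v in grp["dbh"]) / area_ha,
            }
        )
    tab = pd.DataFrame(rows)

    if printed_variants:
        tab["relative_density"] = tab["n_trees"] / tab["density"].sum() * 100
        tab["relative_frequency"] = tab["frequency"] / len(tab) * 100
    else:
        tab["relative_density"] = tab["density"] / tab["density"].sum() * 100
        tab["relative_frequency"] = tab["frequency"] / tab["frequency"].sum() * 100
    tab["relative_dominance"] = tab["dominance"] / tab["dominance"].sum() * 100
    tab["importance_value"] = (
        tab["relative_density"] + tab["relative_frequency"] + tab["relative_dominance"]
    ) / 3
    return tab[IV_COLUMNS]


def iv_table_by_stage(
    stemmap: StemMap, grid: QuadratGrid
) -> dict[str, pd.DataFrame]:
    """Importance-value tables per development stage plus the pooled stand.

    Each stage table self-normalises (denominators are that stage's totals).
    Keys: 'juvenile', 'medium', 'large', 'all'.  All tables are sorted by
    pooled density, descending, so stages line up row-wise where species
    overlap.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tables = {st: iv_components(stemmap, grid, stage_filter=st) for st in STAGES}
    pooled = iv_components(stemmap, grid)
    order = pooled.sort_values(
        ["density", "species"], ascending=[False, True], kind="mergesort"
    )["species"].tolist()
    rank = {sp: i for i, sp in enumerate(order)}
    out: dict[str, pd.DataFrame] = {}
    for key, tab in {**tables, "all": pooled}.items():
        if tab.empty:
            out[key] = tab
        else:
            out[key] = (
                tab.assign(_r=tab["species"].map(rank))
                .sort_values("_r", kind="mergesort")
                .drop(columns="_r")
                .reset_index(drop=True)
            )
    return out
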