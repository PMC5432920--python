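"""Stem-map data model: trees, plot geometry, quadrat gridding, occurrence matrices.

A stem map is a census of every tree in a rectangular plot: position (x, y)
in metres from the plot's south-west corner, species code, and diameter at
breast height (DBH, cm).  Trees are binned into development stages by DBH
and the plot is tiled into square quadrats that serve as the sampling units
for all presence/absence statistics downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("standassoc")

Stage = Literal["juvenile", "medium", "large"]

#: Development stages in increasing DBH order.
STAGES: tuple[Stage, ...] = ("juvenile", "medium", "large")

#: Default DBH class breaks in cm: juvenile [5, 10), medium [10, 25), large [25, inf).
DEFAULT_STAGE_BREAKS: tuple[float, float, float] = (5.0, 10.0, 25.0)

#: Minimum DBH included in the census (cm).
DBH_THRESHOLD = 5.0

STEMMAP_COLUMNS = ("tree_id", "species", "x", "y", "dbh")


class StemMapError(ValueError):
    """Raised for malformed stem-map input."""


def assign_stage(
    dbh: float, breaks: Sequence[float] = DEFAULT_STAGE_BREAKS
) -> Stage:
    """Classify a DBH value (cm) into a development stage.

    Intervals are left-closed/right-open: juvenile [b0, b1), medium
    [b1, b2), large [b2, inf).  DBH below the survey threshold ``b0``
    (default 5 cm) is rejected — such stems are outside the census.
    """
    if not np.isfinite(dbh):
        raise StemMapError(f"DBH must be finite, got {dbh!r}")
    b0, b1, b2 = breaks
    if dbh < b0:
        raise StemMapError(
            f"DBH {dbh} cm is below the survey threshold ({b0} cm); "
            "stems that small are not censused"
        )
    if dbh < b1:
        return "juvenile"
    if dbh < b2:
        return "medium"
    return "large"


@dataclass(frozen=True)
class PlotGeometry:
    """Rectangular plot dimensions and sampling parameters, all in metres."""

    width: float
    height: float
    quadrat_size: float = 14.0
    buffer_width: float = 5.0

    def __post_init__(self) -> None:
        for name in ("width", "height", "quadrat_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.buffer_width < 0:
            raise ValueError("buffer_width must be non-negative")
        if self.buffer_width >= min(self.width, self.height) / 2:
            raise ValueError(
                "buffer_width must be smaller than half the shorter plot side "
                f"({self.buffer_width} vs {min(self.width, self.height) / 2})"
            )

    @property
    def area_m2(self) -> float:
        return self.width * self.height

    @property
    def area_ha(self) -> float:
        return self.area_m2 / 10_000.0


@dataclass(frozen=True)
class QuadratGrid:
    """Regular grid of square quadrats tiling the plot from its origin."""

    n_cols: int
    n_rows: int
    quadrat_size: float

    @property
    def n_quadrats(self) -> int:
        return self.n_cols * self.n_rows

    # alias matching the contingency-table notation (total number of samples)
    @property
    def N(self) -> int:
        return self.n_quadrats


def build_quadrat_grid(geometry: PlotGeometry, strict: bool = True) -> QuadratGrid:
    """Tile the plot with square quadrats of ``geometry.quadrat_size``.

    In strict mode (default) the plot sides must divide evenly by the
    quadrat size; a leftover margin is an error because trees falling in it
    would be silently dropped from quadrat statistics.
    """
    s = geometry.quadrat_size
    if s > min(geometry.width, geometry.height):
        raise ValueError("quadrat_size exceeds a plot dimension")
    n_cols = int(geometry.width // s)
    n_rows = int(geometry.height // s)
    if strict:
        rem_w = geometry.width - n_cols * s
        rem_h = geometry.height - n_rows * s
        if rem_w > 1e-9 or rem_h > 1e-9:
            raise ValueError(
                f"plot {geometry.width} x {geometry.height} m does not divide "
                f"evenly into {s} m quadrats (remainders {rem_w:g} m, {rem_h:g} m)"
            )
    return QuadratGrid(n_cols=n_cols, n_rows=n_rows, quadrat_size=s)


def locate_quadrat(
    x: float, y: float, grid: QuadratGrid
) -> tuple[int, int]:
    """Map a point to its (col, row) quadrat.

    Cells are half-open ``[k*s, (k+1)*s)``; points exactly on the far east
    or north edge of the gridded region are clamped into the last cell so
    every in-plot point has a home.
    """
    s = grid.quadrat_size
    if x < 0 or y < 0 or x > grid.n_cols * s or y > grid.n_rows * s:
        raise ValueError(f"point ({x}, {y}) lies outside the gridded region")
    col = min(int(x // s), grid.n_cols - 1)
    row = min(int(y // s), grid.n_rows - 1)
    return col, row


def quadrat_index(col: int, row: int, grid: QuadratGrid) -> int:
    """Flatten a (col, row) cell to a single quadrat index (row-major)."""
    return row * grid.n_cols + col


@dataclass
class StemMap:
    """A censused stand: one row per tree plus the plot geometry.

    ``trees`` columns: tree_id, species, x, y, dbh, stage.
    """

    trees: pd.DataFrame
    geometry: PlotGeometry
    stage_breaks: tuple[float, float, float] = DEFAULT_STAGE_BREAKS

    def __post_init__(self) -> None:
        df = self.trees
        missing = [c for c in STEMMAP_COLUMNS if c not in df.columns]
        if missing:
            raise StemMapError(f"stem map missing columns: {missing}")
        if df["tree_id"].duplicated().any():
            dupes = df.loc[df["tree_id"].duplicated(), "tree_id"].tolist()
            raise StemMapError(f"duplicate tree ids: {dupes[:5]}")
        if "stage" not in df.columns:
            df = df.copy()
            df["stage"] = [assign_stage(v, self.stage_breaks) for v in df["dbh"]]
            self.trees = df

    def __len__(self) -> int:
        return len(self.trees)

    @property
    def species_labels(self) -> list[str]:
        return sorted(self.trees["species"].unique())

    def subset(self, stage: Stage | None = None, species: str | None = None) -> pd.DataFrame:
        df = self.trees
        if stage is not None:
            df = df[df["stage"] == stage]
        if species is not None:
            df = df[df["species"] == species]
        return df

    def write_csv(self, path: str | Path) -> None:
        self.trees[list(STEMMAP_COLUMNS)].to_csv(path, index=False)


def read_stemmap(
    path: str | Path,
    geometry: PlotGeometry,
    strict: bool = True,
    stage_breaks: tuple[float, float, float] = DEFAULT_STAGE_BREAKS,
) -> StemMap:
    """Read a stem-map CSV (columns tree_id, species, x, y, dbh).

    Rows outside the plot rectangle or below the DBH survey threshold are an
    error in strict mode (default); in lenient mode they are dropped and the
    count logged.  Malformed rows (non-numeric fields, duplicate ids) are an
    error in either mode.
    """
    df = pd.read_csv(path, dtype={"tree_id": str, "species": str})
    missing = [c for c in STEMMAP_COLUMNS if c not in df.columns]
    if missing:
        raise StemMapError(f"{path}: missing columns {missing}")
    for col in ("x", "y", "dbh"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise StemMapError(
                f"{path}: non-numeric {col!r} in row(s) {list(bad[:5])}"
            )
        df[col] = vals
    if df["tree_id"].duplicated().any():
        row = int(df.index[df["tree_id"].duplicated()][0])
        raise StemMapError(f"{path}: duplicate tree_id at row {row}")

    inside = (
        (df["x"] >= 0)
        & (df["x"] <= geometry.width)
        & (df["y"] >= 0)
        & (df["y"] <= geometry.height)
    )
    big_enough = df["dbh"] >= stage_breaks[0]
    ok = inside & big_enough
    if not ok.all():
        bad_rows = df.index[~ok].tolist()
        if strict:
            raise StemMapError(
                f"{path}: {len(bad_rows)} row(s) outside the plot or below the "
                f"{stage_breaks[0]} cm DBH threshold (first: row {bad_rows[0]})"
            )
        logger.warning(
            "%s: dropped %d row(s) outside the plot or below the DBH threshold",
            path,
            len(bad_rows),
        )
        df = df[ok].reset_index(drop=True)
    return StemMap(trees=df, geometry=geometry, stage_breaks=stage_breaks)


@dataclass
class PresenceMatrix:
    """Species-by-quadrat occurrence matrix.

    ``matrix[i, j]`` is the 0/1 indicator (presence mode) or the tree count
    (abundance mode) of species ``i`` in quadrat ``j``.  Species that never
    occur (e.g. after a stage filter) stay as all-zero rows so that pair
    enumeration is invariant across stages; ``empty_species`` flags them.
    """

    species_labels: list[str]
    matrix: np.ndarray
    mode: Literal["presence", "abundance"]
    empty_species: list[str] = field(default_factory=list)

    @property
    def n_quadrats(self) -> int:
        return self.matrix.shape[1]

    def row(self, species: str) -> np.ndarray:
        try:
            i = self.species_labels.index(species)
        except ValueError:
            raise KeyError(f"unknown species {species!r}") from None
        return self.matrix[i]

    def to_presence(self) -> "PresenceMatrix":
        if self.mode == "presence":
            return self
        return PresenceMatrix(
            species_labels=list(self.species_labels),
            matrix=(self.matrix > 0).astype(int),
            mode="presence",
            empty_species=list(self.empty_species),
        )


def presence_matrix(
    stemmap: StemMap,
    grid: QuadratGrid,
    species: Sequence[str] | None = None,
    stage_filter: Stage | None = None,
    mode: Literal["presence", "abundance"] = "presence",
) -> PresenceMatrix:
    """Build the species x quadrat occurrence matrix.

    ``species`` fixes the row order (default: all species in the map,
    sorted); unknown labels are an error.  ``stage_filter`` restricts to one
    development stage before counting.
    """
    if species is None:
        species = stemmap.species_labels
    species = list(species)
    if not species:
        raise ValueError("species list must be non-empty")
    known = set(stemmap.trees["species"])
    unknown = [s for s in species if s not in known]
    if unknown:
        raise KeyError(f"species not present in stem map: {unknown}")

    df = stemmap.subset(stage=stage_filter)
    mat = np.zeros((len(species), grid.n_quadrats), dtype=int)
    sp_index = {s: i for i, s in enumerate(species)}
    for sp, x, y in zip(df["species"], df["x"], df["y"]):
        if sp not in sp_index:
            continue
        col, row = locate_quadrat(x, y, grid)
        mat[sp_index[sp], quadrat_index(col, row, grid)] += 1
    if mode == "presence":
        mat = (mat > 0).astype(int)
    empty = [s for s, r in zip(species, mat) if not r.any()]
    if empty:
        logger.warning(
            "presence_matrix: %d species with zero occurrences%s: %s",
            len(empty),
            f" in stage {stage_filter!r}" if stage_filter else "",
            empty,
        )
    return PresenceMatrix(
        species_labels=species, matrix=mat, mode=mode, empty_species=empty
    )


def select_dominant(iv_table: pd.DataFrame, k: int) -> list[str]:
    """Pick the top-k species by importance value.

    Ties are broken by density (descending) then species label so the
    selection is deterministic.  Also logs the cumulative density share of
    the selection, the usual justification for calling them dominant.
    """
    if k < 2:
        raise ValueError("need at least 2 species for pairwise analysis")
    if k > len(iv_table):
        raise ValueError(f"k={k} exceeds the {len(iv_table)} species available")
    ranked = iv_table.sort_values(
        ["importance_value", "density", "species"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    top = ranked.head(k)
    share = top["density"].sum() / iv_table["density"].sum() * 100
    logger.info("top %d species hold %.1f%% of total density", k, share)
    return top["species"].tolist()
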