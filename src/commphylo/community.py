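"""Community matrices with spatial grid, vertical layers, pools, and scales.

A community matrix is a quadrat × species abundance table.  Each row is one
census unit identified by ``(plot_id, grid_row, grid_col, layer)``; grid
coordinates are 0-based indices on the plot's quadrat lattice (row-major).
The paper-style design is 5 plots of 5 × 5 contiguous 10 m × 10 m quadrats
censused in two vertical layers (tree and shrub).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

META_COLUMNS = ["plot_id", "grid_row", "grid_col", "layer"]
LAYERS = ("tree", "shrub", "all")

#: quadrat cell edge in metres for area labelling (paper design: 10 m cells)
CELL_EDGE_M = 10.0


@dataclass(frozen=True)
class SpeciesPool:
    """The species set null communities are drawn from."""

    name: str  # "plot" or "regional"
    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ScaleSpec:
    """Spatial scale as the edge of an aggregation block, in lattice cells.

    With 10 m cells: 1 → 100 m², 2 → 400 m², 5 → 2500 m².
    """

    block_edge_in_cells: int

    def __post_init__(self) -> None:
        if self.block_edge_in_cells < 1:
            raise ValidationError("block edge must be a positive integer")

    @property
    def area_m2(self) -> float:
        return (self.block_edge_in_cells * CELL_EDGE_M) ** 2

    @property
    def label(self) -> str:
        return f"{self.area_m2:.0f}m2"


class CommunityMatrix:
    """Validated quadrat × species abundance table.

    Parameters
    ----------
    data : pandas.DataFrame
        Metadata columns ``plot_id, grid_row, grid_col, layer`` followed by
        one column per species holding nonnegative abundances.  Species
        columns with zero total abundance are retained (they matter for pool
        logic).
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in META_COLUMNS if c not in data.columns]
        if missing:
            raise ValidationError(f"missing metadata columns: {missing}")
        data = data.reset_index(drop=True)
        species = [c for c in data.columns if c not in META_COLUMNS]
        if not species:
            raise ValidationError("no species columns found")
        ab = data[species].to_numpy()
        if not np.issubdtype(ab.dtype, np.number):
            raise ValidationError("abundances must be numeric")
        if np.isnan(ab).any():
            raise ValidationError("abundances must not be missing")
        if (ab < 0).any():
            bad = [species[j] for j in np.where((ab < 0).any(axis=0))[0]]
            raise ValidationError(f"negative abundances in columns: {bad}")
        keys = data[META_COLUMNS]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise ValidationError(f"duplicate quadrat key: {tuple(dup)}")
        self.data = data[META_COLUMNS + species].copy()
        self.species = species

    @property
    def n_quadrats(self) -> int:
        return len(self.data)

    @property
    def layers(self) -> list[str]:
        return sorted(self.data["layer"].unique())

    @property
    def plots(self) -> list:
        return sorted(self.data["plot_id"].unique())

    def abundance_array(self) -> np.ndarray:
        """(n_quadrats, n_species) abundance array in ``self.species`` order."""
        return self.data[self.species].to_numpy(dtype=float)

    def quadrat_keys(self) -> list[tuple]:
        return [tuple(r) for r in self.data[META_COLUMNS].itertuples(index=False)]

    def richness(self) -> pd.Series:
        return (self.data[self.species] > 0).sum(axis=1)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def __repr__(self) -> str:
        return (f"CommunityMatrix({self.n_quadrats} quadrats × "
                f"{len(self.species)} species, layers={self.layers})")


def read_community(path) -> CommunityMatrix:
    """Read a community CSV (``plot_id,grid_row,grid_col,layer,<sp...>``)."""
    df = pd.read_csv(path)
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"community CSV must start with columns {META_COLUMNS}; "
            f"missing {missing}")
    return CommunityMatrix(df)


def aggregate_scale(cm: CommunityMatrix, scale: ScaleSpec) -> CommunityMatrix:
    """Sum abundances within non-overlapping blocks of cells.

    Blocks of ``block_edge × block_edge`` cells are anchored at grid origin
    (0, 0); a residual strip that does not fill a block (e.g. row/column 4 of
    a 5 × 5 lattice aggregated at block edge 2) is discarded.  Layers are
    aggregated separately; a block missing any of its cells is skipped with a
    warning.
    """
    b = scale.block_edge_in_cells
    if b == 1:
        return CommunityMatrix(cm.data)
    rows = []
    for (plot, layer), sub in cm.data.groupby(["plot_id", "layer"], sort=True):
        n_r = int(sub["grid_row"].max()) + 1
        n_c = int(sub["grid_col"].max()) + 1
        present = {(int(r), int(c)): i for r, c, i in
                   zip(sub["grid_row"], sub["grid_col"], sub.index)}
        for br in range(n_r // b):
            for bc in range(n_c // b):
                cells = [(br * b + i, bc * b + j)
                         for i in range(b) for j in range(b)]
                idx = [present.get(cell) for cell in cells]
                if any(i is None for i in idx):
                    warnings.warn(
                        f"plot {plot!r} layer {layer!r}: block ({br},{bc}) at "
                        f"edge {b} is missing cells; skipped", stacklevel=2)
                    continue
                summed = cm.data.loc[idx, cm.species].sum(axis=0)
                rows.append({"plot_id": plot, "grid_row": br, "grid_col": bc,
                             "layer": layer, **summed.to_dict()})
    if not rows:
        raise ValidationError(
            f"no complete blocks at block edge {b}; grid too small")
    return CommunityMatrix(pd.DataFrame(rows))


def stratify_layer(cm: CommunityMatrix, layer: str) -> CommunityMatrix:
    """Filter to one vertical layer, or merge layers with ``layer="all"``.

    Merging sums abundances of the same quadrat cell across layers.
    """
    if layer not in LAYERS:
        raise ValidationError(f"layer must be one of {LAYERS}, got {layer!r}")
    if layer == "all":
        merged = (cm.data.groupby(["plot_id", "grid_row", "grid_col"],
                                  sort=True, as_index=False)[cm.species].sum())
        merged.insert(3, "layer", "all")
        return CommunityMatrix(merged)
    sub = cm.data[cm.data["layer"] == layer]
    if sub.empty:
        raise ValidationError(f"no quadrats in layer {layer!r}")
    return CommunityMatrix(sub)


def build_pool(cm: CommunityMatrix,
               regional_list: Optional[Iterable[str]] = None
               ) -> dict[str, SpeciesPool]:
    """Build the plot pool (observed species) and, if given, regional pool.

    The plot pool is every species with total abundance > 0 across all
    quadrats.  ``regional_list`` must be a superset of the observed species.
    """
    totals = cm.data[cm.species].sum(axis=0)
    observed = frozenset(totals.index[totals > 0])
    pools = {"plot": SpeciesPool("plot", observed)}
    if regional_list is not None:
        regional = frozenset(regional_list)
        orphans = observed - regional
        if orphans:
            raise ValidationError(
                f"observed species missing from regional list: "
                f"{sorted(orphans)}")
        pools["regional"] = SpeciesPool("regional", regional)
    return pools


def read_species_list(path) -> list[str]:
    """One-column CSV ``species_id`` → list of species."""
    df = pd.read_csv(path)
    if list(df.columns) != ["species_id"]:
        raise FormatError(
            f"species list must have single header 'species_id', "
            f"got {list(df.columns)!r}")
    return df["species_id"].tolist()
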