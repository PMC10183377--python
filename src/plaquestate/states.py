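"""Differential cell density on a fixed 2-D embedding grid.

The embedding shared by all libraries is partitioned into a fixed grid of
sectors (50 x 50 for cell selection, 200 x 200 for visualization). Per-
library occupancy of each sector is normalized to the library total, scaled
to a common library size of 10,000 cells and log2-transformed; sectors whose
occupancy more than doubles in disease relative to control (log2 fold change
> 1) are flagged, and 8-connected flagged components restricted to their
modal cell type become candidate disease-associated cell states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import CellTable, ValidationError

LIBRARY_SCALE = 10_000.0


@dataclass(frozen=True)
class GridSpec:
    n_bins_x: int = 50
    n_bins_y: int = 50
    bounds: tuple[float, float, float, float] | None = None  # xmin, xmax, ymin, ymax
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.n_bins_x < 1 or self.n_bins_y < 1:
            raise ValidationError("grid needs at least one bin per axis")
        if self.bounds is not None:
            xmin, xmax, ymin, ymax = self.bounds
            if xmin >= xmax or ymin >= ymax:
                raise ValidationError("degenerate grid bounds")
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be non-negative")

    def resolve_bounds(self, cells: CellTable) -> tuple[float, float, float, float]:
        """Explicit bounds, or pooled min/max expanded by 0.1% so extreme
        cells stay interior."""
        if self.bounds is not None:
            return self.bounds
        x = cells.cells["x"].to_numpy(dtype=float)
        y = cells.cells["y"].to_numpy(dtype=float)
        pad_x = (x.max() - x.min()) * 1e-3 or 1e-9
        pad_y = (y.max() - y.min()) * 1e-3 or 1e-9
        return (x.min() - pad_x, x.max() + pad_x, y.min() - pad_y, y.max() + pad_y)


@dataclass
class OccupancyGrid:
    """Per-library sector counts and normalized log2 occupancy.

    ``counts`` has shape (libraries, n_bins_x, n_bins_y); ``norm_log2`` is
    ``log2(count / library_total * 10000 + pseudocount)``.
    """

    grid: GridSpec
    bounds: tuple[float, float, float, float]
    libraries: list[str]
    counts: np.ndarray
    norm_log2: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        totals = self.counts.sum(axis=(1, 2), keepdims=True).astype(float)
        norm = self.counts / totals * LIBRARY_SCALE
        self.norm_log2 = np.log2(norm + self.grid.pseudocount)

    def library_index(self, library_id: str) -> int:
        try:
            return self.libraries.index(library_id)
        except ValueError:
            raise ValidationError(f"unknown library {library_id!r}") from None


@dataclass(frozen=True)
class SectorCall:
    sector: tuple[int, int]
    log2_fc: float
    flagged: bool
    n_cells_pooled: int


@dataclass
class CellStateAssignment:
    state_id: str
    cell_ids: list[str]
    cell_type: str
    sectors: list[tuple[int, int]]


def sector_of(x: np.ndarray, y: np.ndarray, grid: GridSpec,
              bounds: tuple[float, float, float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Sector indices; bins are half-open except the last, which is closed."""
    xmin, xmax, ymin, ymax = bounds
    out = (x < xmin) | (x > xmax) | (y < ymin) | (y > ymax)
    if out.any():
        raise ValidationError(f"{int(out.sum())} cells fall outside the grid bounds "
                              f"(first indices: {np.flatnonzero(out)[:5].tolist()})")
    ix = np.floor((x - xmin) / (xmax - xmin) * grid.n_bins_x).astype(int)
    iy = np.floor((y - ymin) / (ymax - ymin) * grid.n_bins_y).astype(int)
    return np.minimum(ix, grid.n_bins_x - 1), np.minimum(iy, grid.n_bins_y - 1)


def build_occupancy(cells: CellTable, grid: GridSpec) -> OccupancyGrid:
    """Count cells from each library falling into each sector and apply the
    library-size normalization and log2 transform."""
    bounds = grid.resolve_bounds(cells)
    df = cells.cells
    ix, iy = sector_of(df["x"].to_numpy(float), df["y"].to_numpy(float), grid, bounds)
    libraries = cells.libraries
    counts = np.zeros((len(libraries), grid.n_bins_x, grid.n_bins_y), dtype=int)
    lib_codes = pd.Categorical(df["library_id"], categories=libraries).codes
    np.add.at(counts, (lib_codes, ix, iy), 1)
    return OccupancyGrid(grid, bounds, libraries, counts)


def _pooled_counts(occ: OccupancyGrid, libs: str | list[str]) -> np.ndarray:
    if isinstance(libs, str):
        libs = [libs]
    idx = [occ.library_index(l) for l in libs]
    return occ.counts[idx].sum(axis=0)


def sector_fold_change(occ: OccupancyGrid, disease_lib: str | list[str],
                       control_lib: str | list[str],
                       threshold_log2: float = 1.0,
                       min_cells: int = 5) -> list[SectorCall]:
    """Per-sector log2 fold change of normalized occupancy, disease minus
    control. Replicate libraries may be passed as a list; their counts are
    pooled (summed) before normalization. A sector is flagged when its fold
    change exceeds ``threshold_log2`` and it holds at least ``min_cells``
    cells pooled over the two compared groups."""
    d_counts = _pooled_counts(occ, disease_lib)
    c_counts = _pooled_counts(occ, control_lib)
    pc = occ.grid.pseudocount

    def norm_log2(counts: np.ndarray) -> np.ndarray:
        return np.log2(counts / counts.sum() * LIBRARY_SCALE + pc)

    fc = norm_log2(d_counts) - norm_log2(c_counts)
    pooled = d_counts + c_counts
    calls = []
    for i in range(occ.grid.n_bins_x):
        for j in range(occ.grid.n_bins_y):
            flagged = bool(fc[i, j] > threshold_log2 and pooled[i, j] >= min_cells)
            calls.append(SectorCall((i, j), float(fc[i, j]), flagged,
                                    int(pooled[i, j])))
    return calls


def assemble_states(cells: CellTable, calls: list[SectorCall], grid: GridSpec,
                    min_state_cells: int = 20,
                    merge_map: dict[str, str] | None = None,
                    bounds: tuple[float, float, float, float] | None = None,
                    ) -> list[CellStateAssignment]:
    """Group flagged sectors into 8-connected components and form one cell
    state per component from the cells of its modal cell type.

    Cells of other types inside a component stay unassigned; components with
    fewer than ``min_state_cells`` member cells are dropped. ``merge_map``
    (state_id -> state_id) reproduces manual curation and is applied last.
    """
    flag_mask = np.zeros((grid.n_bins_x, grid.n_bins_y), dtype=bool)
    for call in calls:
        if call.flagged:
            flag_mask[call.sector] = True
    if not flag_mask.any():
        return []
    labels, n_comp = ndimage.label(flag_mask, structure=np.ones((3, 3), dtype=int))

    b = bounds if bounds is not None else grid.resolve_bounds(cells)
    df = cells.cells
    ix, iy = sector_of(df["x"].to_numpy(float), df["y"].to_numpy(float), grid, b)
    cell_comp = labels[ix, iy]  # 0 = unflagged

    states = []
    for comp in range(1, n_comp + 1):
        in_comp = cell_comp == comp
        if not in_comp.any():
            continue
        types = df.loc[in_comp, "cell_type"]
        modal = types.mode().iloc[0]
        member = in_comp & (df["cell_type"] == modal).to_numpy()
        if member.sum() < min_state_cells:
            continue
        sectors = [tuple(s) for s in np.argwhere(labels == comp)]
        states.append(CellStateAssignment(
            state_id="", cell_ids=df.loc[member, "cell_id"].tolist(),
            cell_type=modal, sectors=sectors))
    states.sort(key=lambda s: -len(s.cell_ids))
    for k, st in enumerate(states, start=1):
        st.state_id = f"state{k}"

    if merge_map:
        merged: dict[str, CellStateAssignment] = {}
        for st in states:
            target = merge_map.get(st.state_id, st.state_id)
            if target in merged:
                merged[target].cell_ids.extend(st.cell_ids)
                merged[target].sectors.extend(st.sectors)
            else:
                merged[target] = CellStateAssignment(target, list(st.cell_ids),
                                                     st.cell_type, list(st.sectors))
        states = list(merged.values())
    return states


def state_fractions(cells: CellTable, states: list[CellStateAssignment]) -> pd.DataFrame:
    """Fraction of each library's cells belonging to each state.

    Returns a tidy table (state_id, library_id, condition, fraction) plus a
    ``condition_mean`` column repeating the per-condition mean fraction.
    """
    df = cells.cells
    lib_cond = cells.library_condition()
    lib_totals = df.groupby("library_id", sort=False).size()
    id_to_lib = df.set_index("cell_id")["library_id"]
    rows = []
    for st in states:
        member_libs = id_to_lib.loc[st.cell_ids].value_counts()
        for lib in cells.libraries:
            n = int(member_libs.get(lib, 0))
            rows.append((st.state_id, lib, lib_cond[lib],
                         n / float(lib_totals[lib])))
    out = pd.DataFrame(rows, columns=["state_id", "library_id", "condition",
                                      "fraction"])
    if len(out):
        means = out.groupby(["state_id", "condition"])["fraction"].transform("mean")
        out["condition_mean"] = means
    else:
        out["condition_mean"] = pd.Series(dtype=float)
    return out
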