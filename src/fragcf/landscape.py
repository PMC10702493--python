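"""Raster landscapes, habitat patches and equivalent connected area (ECA).

A landscape is a rectangular grid of integer land-cover codes.  A legend maps
each code to a (land use, intensity) class; one class is the natural-habitat
reference.  Patches are connected components of a single class.  The ECA of a
class is the area of one hypothetical patch whose probability of connectivity
equals that of the actual, possibly fragmented, patch mosaic:

    ECA = sqrt( sum_x sum_y  A_x * A_y * p_xy )

where ``p_xy`` is the probability that an individual disperses between patches
``x`` and ``y``.  With all patches perfectly connected (p = 1) the ECA equals
the total class area; with all patches isolated it falls towards the area of
the largest patch.  Dispersal probability decays with the effective distance
between patches, which a resistant matrix can lengthen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

__all__ = [
    "Legend",
    "LandscapeGrid",
    "Patch",
    "DispersalSpec",
    "extract_patches",
    "patch_distance",
    "pairwise_effective_distances",
    "dispersal_probability",
    "equivalent_connected_area",
    "class_connectivity_summary",
]

#: dispersal probabilities below this are treated as zero
P_CUTOFF = 1e-6

NATURAL = "natural"

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)
_STRUCT8 = np.ones((3, 3), bool)


class LegendError(KeyError):
    """A land-cover code has no entry in the legend."""


class Legend:
    """Mapping of integer raster codes to (land_use, intensity) classes.

    ``intensity`` is one of ``minimal``/``light``/``intense`` for anthropogenic
    classes, or ``natural`` for the natural-habitat reference class.
    """

    def __init__(self, entries: pd.DataFrame):
        required = {"code", "land_use", "intensity"}
        if not required.issubset(entries.columns):
            raise ValueError(f"legend needs columns {sorted(required)}")
        self.table = entries.reset_index(drop=True)
        self._by_code = {
            int(r.code): (str(r.land_use), str(r.intensity))
            for r in self.table.itertuples()
        }
        self._by_class = {v: k for k, v in self._by_code.items()}

    @classmethod
    def read_csv(cls, path) -> "Legend":
        return cls(pd.read_csv(path))

    def lookup(self, code: int) -> tuple[str, str]:
        try:
            return self._by_code[int(code)]
        except KeyError:
            raise LegendError(f"code {code} not in legend") from None

    def code_of(self, land_use: str, intensity: str) -> int:
        try:
            return self._by_class[(land_use, intensity)]
        except KeyError:
            raise LegendError(f"class ({land_use}, {intensity}) not in legend") from None

    @property
    def codes(self) -> list[int]:
        return sorted(self._by_code)

    @property
    def natural_code(self) -> int:
        for code, (lu, _m) in self._by_code.items():
            if lu == NATURAL:
                return code
        raise LegendError("legend has no natural-habitat class")

    def is_natural(self, code: int) -> bool:
        return self.lookup(code)[0] == NATURAL

    def anthropogenic_codes(self) -> list[int]:
        return [c for c in self.codes if not self.is_natural(c)]


@dataclass
class LandscapeGrid:
    """Categorical raster of land-cover codes for one ecoregion.

    codes      : 2-D integer array, one land-cover code per cell
    cell_size  : metres per cell edge (cells are square)
    ecoregion_id : identifier of the ecoregion the grid covers
    nodata_code  : code marking cells outside the ecoregion
    """

    codes: np.ndarray
    cell_size: float
    ecoregion_id: str | int = 0
    nodata_code: int = -9999

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D grid")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    @property
    def cell_area(self) -> float:
        return float(self.cell_size) ** 2

    def valid_mask(self) -> np.ndarray:
        return self.codes != self.nodata_code

    def area(self) -> float:
        """Total ecoregion area in m2 (non-nodata cells)."""
        return float(self.valid_mask().sum()) * self.cell_area

    def validate_against(self, legend: Legend) -> None:
        present = np.unique(self.codes[self.valid_mask()])
        unknown = [int(c) for c in present if int(c) not in set(legend.codes)]
        if unknown:
            raise LegendError(f"codes not in legend: {unknown}")

    def class_mask(self, code: int) -> np.ndarray:
        return self.codes == code


@dataclass
class Patch:
    """Connected component of one (land use, intensity) class."""

    id: int
    land_use: str
    intensity: str
    cells: np.ndarray          # (n, 2) array of (row, col)
    area: float                # m2
    boundary_cells: np.ndarray  # (k, 2) subset of cells on the patch edge

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class DispersalSpec:
    """Dispersal kernel for a species group.

    The kernel is a negative exponential parameterised by the group's median
    dispersal distance: p(d) = 2**(-d / d_med), so p(0) = 1 and p(d_med) = 0.5.
    """

    species_group: str
    d_med: float  # metres
    kernel: str = "half-distance-exponential"

    def __post_init__(self):
        if self.d_med <= 0:
            raise ValueError("median dispersal distance must be positive")


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return _STRUCT4
    if connectivity == 8:
        return _STRUCT8
    raise ValueError("connectivity must be 4 or 8")


def extract_patches(
    grid: LandscapeGrid,
    code: int,
    legend: Legend,
    connectivity: int = 8,
) -> list[Patch]:
    """Partition the cells bearing ``code`` into connected patches.

    Patch ids follow raster scan order (deterministic).  An absent class
    yields an empty list.
    """
    land_use, intensity = legend.lookup(code)  # raises LegendError if unknown
    mask = grid.class_mask(code)
    labels, n = ndimage.label(mask, structure=_structure(connectivity))
    patches: list[Patch] = []
    # a cell is on the boundary if any 8-neighbour (or grid edge) lies outside
    # the patch mosaic of this class
    interior = ndimage.binary_erosion(mask, structure=_STRUCT8, border_value=0)
    boundary_mask = mask & ~interior
    for pid in range(1, n + 1):
        cells = np.argwhere(labels == pid)
        bmask = boundary_mask[cells[:, 0], cells[:, 1]]
        patches.append(
            Patch(
                id=pid,
                land_use=land_use,
                intensity=intensity,
                cells=cells,
                area=len(cells) * grid.cell_area,
                boundary_cells=cells[bmask],
            )
        )
    return patches


def patch_distance(
    a: Patch,
    b: Patch,
    grid: LandscapeGrid,
    resistance: np.ndarray | None = None,
) -> float:
    """Effective distance (m) separating two patches.

    Without a resistance map this is the minimum edge-to-edge Euclidean
    distance between boundary-cell centres.  With a per-cell resistance map
    ``r`` in [0, 1] it is the least-cost distance over the 8-connected cell
    graph where traversing a cell costs ``cell_size * (1 + r)`` (diagonal
    steps scaled by sqrt(2)); resistance can only lengthen the separation.
    """
    if a is b or _patches_overlap(a, b):
        raise ValueError("patches must be distinct and disjoint")
    if resistance is None:
        return _euclidean_boundary_distance(a, b, grid.cell_size)
    dmat = _least_cost_distances(grid, [a, b], resistance)
    return float(dmat[0, 1])


def _patches_overlap(a: Patch, b: Patch) -> bool:
    sa = {tuple(c) for c in a.cells}
    return any(tuple(c) in sa for c in b.cells)


def _euclidean_boundary_distance(a: Patch, b: Patch, cell_size: float) -> float:
    tree = cKDTree(a.boundary_cells.astype(float))
    d, _ = tree.query(b.boundary_cells.astype(float))
    return float(d.min()) * cell_size


def pairwise_effective_distances(
    patches: list[Patch],
    grid: LandscapeGrid,
    resistance: np.ndarray | None = None,
) -> np.ndarray:
    """Symmetric matrix of effective distances between all patch pairs (m)."""
    n = len(patches)
    if resistance is None:
        out = np.zeros((n, n))
        trees = [cKDTree(p.boundary_cells.astype(float)) for p in patches]
        for i in range(n):
            for j in range(i + 1, n):
                d, _ = trees[i].query(patches[j].boundary_cells.astype(float))
                out[i, j] = out[j, i] = float(d.min()) * grid.cell_size
        return out
    return _least_cost_distances(grid, patches, resistance)


def _cell_graph(grid: LandscapeGrid, resistance: np.ndarray) -> sparse.csr_matrix:
    """8-connected cell graph; edge weight = mean endpoint cost x step length."""
    r = np.asarray(resistance, dtype=float)
    if r.shape != grid.shape:
        raise ValueError("resistance map shape must match the grid")
    if np.any((r < 0) | (r > 1)):
        raise ValueError("resistance values must lie in [0, 1]")
    nrow, ncol = grid.shape
    cost = grid.cell_size * (1.0 + r)  # m to traverse one cell
    idx = np.arange(nrow * ncol).reshape(nrow, ncol)
    rows, cols, data = [], [], []
    steps = [((0, 1), 1.0), ((1, 0), 1.0), ((1, 1), np.sqrt(2)), ((1, -1), np.sqrt(2))]
    for (dr, dc), w in steps:
        r0 = slice(max(0, -dr), nrow - max(0, dr))
        c0 = slice(max(0, -dc), ncol - max(0, dc))
        r1 = slice(max(0, dr), nrow - max(0, -dr))
        c1 = slice(max(0, dc), ncol - max(0, -dc))
        u = idx[r0, c0].ravel()
        v = idx[r1, c1].ravel()
        ew = w * 0.5 * (cost[r0, c0].ravel() + cost[r1, c1].ravel())
        rows.append(u)
        cols.append(v)
        data.append(ew)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.concatenate(data)
    g = sparse.coo_matrix((data, (rows, cols)), shape=(nrow * ncol,) * 2)
    return (g + g.T).tocsr()


def _least_cost_distances(
    grid: LandscapeGrid, patches: list[Patch], resistance: np.ndarray
) -> np.ndarray:
    graph = _cell_graph(grid, resistance)
    ncol = grid.shape[1]
    n = len(patches)
    out = np.zeros((n, n))
    flat_cells = [p.cells[:, 0] * ncol + p.cells[:, 1] for p in patches]
    for i in range(n):
        d = dijkstra(graph, indices=flat_cells[i], min_only=True)
        for j in range(n):
            if j == i:
                continue
            out[i, j] = d[flat_cells[j]].min()
    # multi-source dijkstra is symmetric here (undirected graph), but average
    # away float asymmetry from the two sweep directions
    return 0.5 * (out + out.T)


def dispersal_probability(d_eff: float | np.ndarray, spec: DispersalSpec) -> float | np.ndarray:
    """p = 2**(-d_eff / d_med): probability of dispersal across ``d_eff`` metres."""
    d = np.asarray(d_eff, dtype=float)
    if np.any(d < 0):
        raise ValueError("effective distance must be non-negative")
    p = np.exp2(-d / spec.d_med)
    return float(p) if np.isscalar(d_eff) else p


def dispersal_matrix(
    distances: np.ndarray, spec: DispersalSpec, cutoff: float = P_CUTOFF
) -> np.ndarray:
    """Pairwise dispersal-probability matrix with unit diagonal and a cutoff."""
    p = np.exp2(-np.asarray(distances, float) / spec.d_med)
    p[p < cutoff] = 0.0
    np.fill_diagonal(p, 1.0)
    return p


def equivalent_connected_area(patches: list[Patch], p: np.ndarray) -> float:
    """ECA (m2) = sqrt(sum_xy A_x A_y p_xy) over the class's patch mosaic."""
    areas = np.array([q.area for q in patches], dtype=float)
    p = np.asarray(p, dtype=float)
    if p.shape != (len(areas), len(areas)):
        raise ValueError("probability matrix does not match the patch list")
    if not np.allclose(p, p.T):
        raise ValueError("probability matrix must be symmetric")
    if not np.allclose(np.diag(p), 1.0):
        raise ValueError("probability matrix diagonal must be 1")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if len(areas) == 0:
        return 0.0
    return float(np.sqrt(areas @ p @ areas))


@dataclass
class ClassConnectivity:
    land_use: str
    intensity: str
    code: int
    total_area: float
    eca: float
    n_patches: int


def class_connectivity_summary(
    grid: LandscapeGrid,
    legend: Legend,
    dispersal: DispersalSpec,
    resistance_maps: dict[int, np.ndarray] | None = None,
    connectivity: int = 8,
    cutoff: float = P_CUTOFF,
) -> pd.DataFrame:
    """Per-class total area A and ECA for every class present in the grid.

    ``resistance_maps`` optionally maps a class code to the per-cell resistance
    map experienced by species whose habitat is that class; classes without a
    map use plain Euclidean separation (r = 0 everywhere).
    """
    grid.validate_against(legend)
    rows = []
    present = np.unique(grid.codes[grid.valid_mask()])
    for code in sorted(int(c) for c in present):
        lu, inten = legend.lookup(code)
        patches = extract_patches(grid, code, legend, connectivity)
        rmap = (resistance_maps or {}).get(code)
        if len(patches) == 1:
            eca = patches[0].area
        else:
            d = pairwise_effective_distances(patches, grid, rmap)
            p = dispersal_matrix(d, dispersal, cutoff)
            eca = equivalent_connected_area(patches, p)
        total = sum(q.area for q in patches)
        # guard against float creep: ECA can never exceed the class area
        eca = min(eca, total)
        rows.append(
            ClassConnectivity(lu, inten, code, total, eca, len(patches)).__dict__
        )
    return pd.DataFrame(rows)


def resistance_map_for_class(
    grid: LandscapeGrid,
    legend: Legend,
    habitat_code: int,
    class_resistance: dict[int, float],
) -> np.ndarray:
    """Per-cell resistance map for species inhabiting ``habitat_code``.

    ``class_resistance`` maps each surrounding class code to its resistance in
    [0, 1].  The habitat class itself and natural habitat always get r = 0.
    """
    r = np.zeros(grid.shape, dtype=float)
    for code, value in class_resistance.items():
        if code == habitat_code or legend.is_natural(code):
            continue
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"resistance for code {code} outside [0, 1]")
        r[grid.codes == code] = value
    r[grid.codes == habitat_code] = 0.0
    r[grid.codes == legend.natural_code] = 0.0
    return r
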