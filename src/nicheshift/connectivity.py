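"""Circuit-theory habitat connectivity on a resistance raster.

Habitat suitability is transformed to movement resistance on [1, 100] with a
negative-exponential curve (high suitability -> low resistance). The raster
becomes an electrical network: one vertex per cell, edges to the 8 neighbours
with conductance equal to the mean of the two cell conductances (diagonals
scaled by 1/sqrt(2)). Unit current is injected between every pair of nodes
placed on the perimeter of a buffer offset from the species' checklist range
(so node placement artefacts stay outside the range), each pair's Laplacian
system is solved, and per-cell currents are summed over all pairs. High
connectivity is the top quartile of the summed current within the range mask;
comparing two periods' binarized maps yields a four-way change category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import shapely
from scipy.sparse import coo_matrix, csc_matrix
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import splu
from shapely.geometry import Polygon

from .grid import GridSpec
from .sdm_ensemble import SuitabilityMap

SQRT2 = np.sqrt(2.0)

CONNECTIVITY_CATEGORIES = ("remained-low", "high-to-low", "low-to-high", "remained-high")


@dataclass
class ResistanceSurface:
    """Per-cell movement resistance in [1, 100] derived from suitability."""

    values: np.ndarray
    grid: GridSpec
    shape_c: float
    source_provenance: str = ""


def suitability_to_resistance(
    suitability: SuitabilityMap | np.ndarray, c: float = 8.0, grid: GridSpec | None = None
) -> ResistanceSurface:
    """R(s) = 100 - 99 * (1 - exp(-c s)) / (1 - exp(-c)).

    Strictly decreasing in s with R(0) = 100 and R(1) = 1 exactly.
    """
    if c <= 0:
        raise ValueError("shape parameter c must be > 0")
    if isinstance(suitability, SuitabilityMap):
        s = suitability.values
        grid = suitability.grid
        prov = suitability.provenance
    else:
        s = np.asarray(suitability, dtype=float)
        prov = ""
    valid = ~np.isnan(s)
    if valid.any() and ((s[valid] < 0) | (s[valid] > 1)).any():
        raise ValueError("suitability must lie in [0, 1]")
    r = 100.0 - 99.0 * (1.0 - np.exp(-c * s)) / (1.0 - np.exp(-c))
    return ResistanceSurface(values=r, grid=grid, shape_c=c, source_provenance=prov)


@dataclass
class NodeSet:
    """Random current-injection nodes on a buffer perimeter."""

    points: np.ndarray  # (n, 2) coordinates in metres
    cells: list[tuple[int, int]]
    seed: int
    buffer_km: float


def sample_buffer_nodes(
    range_polygon: Polygon,
    grid: GridSpec,
    buffer_km: float = 600.0,
    n_nodes: int = 18,
    seed: int = 0,
) -> NodeSet:
    """Draw n_nodes uniformly by arc length along the buffered range perimeter."""
    ring = range_polygon.buffer(buffer_km * 1000.0).exterior
    xmin, ymin, xmax, ymax = grid.extent
    bx0, by0, bx1, by1 = ring.bounds
    if bx0 < xmin or by0 < ymin or bx1 > xmax or by1 > ymax:
        raise ValueError(
            f"buffer of {buffer_km} km extends beyond the raster extent; reduce buffer_km"
        )
    rng = np.random.default_rng(seed)
    pts: list = []
    cells: list[tuple[int, int]] = []
    attempts = 0
    while len(pts) < n_nodes:
        attempts += 1
        if attempts > 100 * n_nodes:
            raise RuntimeError("could not place distinct nodes on the buffer perimeter")
        p = ring.interpolate(rng.uniform(0.0, ring.length))
        r, c = grid.cell_of(np.array([p.x]), np.array([p.y]))
        cell = (int(r[0]), int(c[0]))
        if cell[0] < 0 or cell in cells:
            continue
        pts.append((p.x, p.y))
        cells.append(cell)
    return NodeSet(points=np.array(pts), cells=cells, seed=seed, buffer_km=buffer_km)


@dataclass
class CurrentMap:
    """Accumulated current summed over all node pairs."""

    values: np.ndarray
    grid: GridSpec
    range_mask: np.ndarray | None = None  # cells inside the checklist range
    effective_resistances: dict = field(default_factory=dict)
    potentials: dict | None = None  # pair -> per-vertex potential (on request)
    vertex_index: np.ndarray | None = None  # cell -> vertex id (-1 = nodata)


def _grid_graph(resistance: np.ndarray, neighbours: int = 8):
    """Edge list (a, b, conductance) over valid cells of the resistance raster.

    Edge conductance is the mean of the two cell conductances; diagonal edges
    are scaled by 1/sqrt(2) for the longer step.
    """
    nr, nc = resistance.shape
    valid = ~np.isnan(resistance)
    index = -np.ones(resistance.shape, dtype=int)
    index[valid] = np.arange(valid.sum())
    cond = 1.0 / resistance
    offsets = [(0, 1, 1.0), (1, 0, 1.0)]
    if neighbours == 8:
        offsets += [(1, 1, 1.0 / SQRT2), (1, -1, 1.0 / SQRT2)]
    elif neighbours != 4:
        raise ValueError("neighbours must be 4 or 8")
    rows_a, rows_b, gs = [], [], []
    for dr, dc, w in offsets:
        r0 = slice(0, nr - dr)
        r1 = slice(dr, nr)
        c0 = slice(max(0, -dc), nc - max(0, dc))
        c1 = slice(max(0, dc), nc - max(0, -dc))
        ok = valid[r0, c0] & valid[r1, c1]
        a = index[r0, c0][ok]
        b = index[r1, c1][ok]
        g = w * (cond[r0, c0][ok] + cond[r1, c1][ok]) / 2.0
        rows_a.append(a)
        rows_b.append(b)
        gs.append(g)
    return (
        np.concatenate(rows_a),
        np.concatenate(rows_b),
        np.concatenate(gs),
        index,
        int(valid.sum()),
    )


def solve_pairwise_current(
    surface: ResistanceSurface,
    nodes: NodeSet,
    neighbours: int = 8,
    range_mask: np.ndarray | None = None,
    return_potentials: bool = False,
) -> CurrentMap:
    """Accumulated current over all node pairs on the resistance network.

    For each of the C(n, 2) pairs a unit current is injected at one node and
    withdrawn at the other; the Laplacian system is solved by sparse LU (one
    factorization, grounded at the first node, shared by all pairs). Per-cell
    current is half the sum of absolute incident edge currents, with the
    source and sink cells set to 1 exactly; pairs are summed unnormalized.
    """
    ea, eb, g, index, n_vert = _grid_graph(surface.values, neighbours)
    node_idx = []
    for (r, c) in nodes.cells:
        if index[r, c] < 0:
            raise ValueError(f"node cell {(r, c)} lies on nodata")
        node_idx.append(index[r, c])

    W = coo_matrix((g, (ea, eb)), shape=(n_vert, n_vert))
    W = W + W.T
    deg = np.asarray(W.sum(axis=1)).ravel()
    L = (coo_matrix((deg, (np.arange(n_vert), np.arange(n_vert)))) - W).tocsr()

    n_comp, labels = connected_components(W, directed=False)
    if n_comp > 1:
        comp = labels[node_idx]
        for (i, a), (j, b) in combinations(enumerate(comp), 2):
            if a != b:
                raise ValueError(f"node pair ({i}, {j}) is disconnected on the raster graph")

    ground = node_idx[0]
    keep = np.ones(n_vert, dtype=bool)
    keep[ground] = False
    red = np.flatnonzero(keep)
    pos = -np.ones(n_vert, dtype=int)
    pos[red] = np.arange(len(red))
    lu = splu(csc_matrix(L[np.ix_(red, red)]))

    accum = np.zeros(n_vert)
    eff_res: dict = {}
    potentials: dict | None = {} if return_potentials else None
    for (i, src), (j, snk) in combinations(enumerate(node_idx), 2):
        b = np.zeros(len(red))
        if src != ground:
            b[pos[src]] = 1.0
        if snk != ground:
            b[pos[snk]] = -1.0
        v_red = lu.solve(b)
        v = np.zeros(n_vert)
        v[red] = v_red
        edge_cur = g * (v[ea] - v[eb])
        contrib = np.zeros(n_vert)
        np.add.at(contrib, ea, np.abs(edge_cur) / 2.0)
        np.add.at(contrib, eb, np.abs(edge_cur) / 2.0)
        contrib[src] = 1.0
        contrib[snk] = 1.0
        accum += contrib
        eff_res[(i, j)] = float(v[src] - v[snk])
        if potentials is not None:
            potentials[(i, j)] = v.copy()

    out = np.full(surface.values.shape, np.nan)
    out[index >= 0] = accum
    return CurrentMap(
        values=out,
        grid=surface.grid,
        range_mask=range_mask,
        effective_resistances=eff_res,
        potentials=potentials,
        vertex_index=index,
    )


@dataclass
class ConnectivityChangeMap:
    """Four-way high/low connectivity transition classification."""

    categories: np.ndarray  # codes into CONNECTIVITY_CATEGORIES; -1 outside mask
    threshold1: float
    threshold2: float

    def category_counts(self) -> dict[str, int]:
        return {
            name: int((self.categories == code).sum())
            for code, name in enumerate(CONNECTIVITY_CATEGORIES)
        }


def classify_connectivity_change(
    map1: CurrentMap,
    map2: CurrentMap,
    percentile: float = 75.0,
    range_mask: np.ndarray | None = None,
) -> ConnectivityChangeMap:
    """Binarize each current map at its own percentile (computed over the
    range mask only; buffer-area cells are excluded) and classify cells."""
    if map1.values.shape != map2.values.shape:
        raise ValueError("current maps are not co-registered")
    mask = range_mask if range_mask is not None else map1.range_mask
    if mask is None:
        mask = np.ones(map1.values.shape, dtype=bool)
    valid = mask & ~np.isnan(map1.values) & ~np.isnan(map2.values)
    t1 = float(np.percentile(map1.values[valid], percentile))
    t2 = float(np.percentile(map2.values[valid], percentile))
    h1 = map1.values >= t1
    h2 = map2.values >= t2
    codes = (h1.astype(int) + 2 * h2.astype(int)).astype(int)
    codes[~valid] = -1
    return ConnectivityChangeMap(categories=codes, threshold1=t1, threshold2=t2)
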