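"""Reef-patch connectivity graphs from habitat and cost rasters.

The workflow mirrors landscape-graph practice for larval dispersal:
habitat cells are grouped into patches (8-connected components of at
least ``min_area_ha`` hectares), overwater least-cost distances are
computed between all patch pairs on the cost raster (sea cells cost 1
per km so distances are in km over open water; land cells carry a large
penalty, 10,000 by default, rather than being a hard barrier), and each
species gets a binary undirected graph whose edges join patches within
its maximum dispersal distance ``D_max = PLD × current speed`` (default
current speed 18.7 km/day).  Betweenness centrality and graph diameter
of that graph measure a focal patch's stepping-stone importance and the
number of larval-dispersal generations spanning the region.

Shortest paths and centrality go through ``scipy.sparse.csgraph`` and
``networkx``; a synthetic seascape generator provides test seascapes
with known geometry in place of digitized reef maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from stepstone._rng import child_rng
from stepstone.errors import ConfigurationError, PlacementError, UnknownPopulationError

DEFAULT_LAND_COST = 10_000.0
DEFAULT_CURRENT_SPEED_KM_PER_DAY = 18.7
DEFAULT_MIN_AREA_HA = 25.0

_EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass
class ReefRaster:
    """Habitat and traversal-cost grids on a square-cell raster.

    ``habitat`` marks reef cells; ``cost`` holds the per-cell traversal
    cost multiplier (sea 1, land ``DEFAULT_LAND_COST``).  Row 0 is the
    top of the grid; indices are 0-based.  ``metadata`` carries
    generator ground truth for synthetic seascapes.
    """

    habitat: np.ndarray
    cost: np.ndarray
    resolution_km: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.habitat = np.asarray(self.habitat, dtype=bool)
        self.cost = np.asarray(self.cost, dtype=float)
        if self.habitat.shape != self.cost.shape:
            raise ConfigurationError("habitat and cost grids differ in shape")
        if self.resolution_km <= 0:
            raise ConfigurationError("resolution must be positive")
        if np.any(self.cost < 1):
            raise ConfigurationError("cell costs must be >= 1")
        if np.any(self.habitat & (self.cost > 1)):
            raise ConfigurationError("habitat cells must not be land (cost > 1)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.habitat.shape

    def write_ascii(self, habitat_path: str | Path, cost_path: str | Path) -> None:
        """Write habitat (0/1) and cost grids as ESRI ASCII rasters."""
        for arr, path in [(self.habitat.astype(int), habitat_path),
                          (self.cost, cost_path)]:
            nrows, ncols = arr.shape
            header = (
                f"ncols {ncols}\nnrows {nrows}\nxllcorner 0\nyllcorner 0\n"
                f"cellsize {self.resolution_km * 1000}\nNODATA_value -9999\n"
            )
            with open(path, "w") as fh:
                fh.write(header)
                np.savetxt(fh, arr, fmt="%g")

    @classmethod
    def read_ascii(
        cls, habitat_path: str | Path, cost_path: str | Path
    ) -> "ReefRaster":
        def load(path):
            with open(path) as fh:
                header = {}
                pos = fh.tell()
                for _ in range(6):
                    pos = fh.tell()
                    line = fh.readline()
                    parts = line.split()
                    if len(parts) == 2 and parts[0].lower() in {
                        "ncols", "nrows", "xllcorner", "yllcorner",
                        "cellsize", "nodata_value",
                    }:
                        header[parts[0].lower()] = float(parts[1])
                    else:
                        fh.seek(pos)
                        break
                grid = np.loadtxt(fh)
            return grid, header

        hab, header = load(habitat_path)
        cost, _ = load(cost_path)
        res = header.get("cellsize", 1000.0) / 1000.0
        return cls(habitat=hab > 0, cost=cost, resolution_km=res)


@dataclass
class Patch:
    id: int
    cells: np.ndarray  # (m, 2) row/col indices
    area_ha: float
    centroid: tuple[float, float]


@dataclass
class PatchSet:
    patches: list[Patch]
    resolution_km: float

    @property
    def ids(self) -> list[int]:
        return [p.id for p in self.patches]

    def __len__(self) -> int:
        return len(self.patches)


@dataclass
class LinkSet:
    """Symmetric least-cost distances (km) between patches."""

    patch_ids: list[int]
    distances: np.ndarray


@dataclass
class SpeciesGraph:
    """Binary dispersal graph for one species' PLD."""

    graph: nx.Graph
    d_max_km: float
    pld_days: float
    current_speed: float


def extract_patches(
    rr: ReefRaster, min_area_ha: float = DEFAULT_MIN_AREA_HA
) -> PatchSet:
    """Habitat patches as 8-connected components above the area cutoff.

    Area is ``cells × resolution² × 100`` hectares (1 km² = 100 ha).
    Patch ids are assigned in order of each component's first cell in
    row-major scan, so they are stable across runs.
    """
    if not rr.habitat.any():
        warnings.warn("habitat mask is empty; no patches extracted")
        return PatchSet(patches=[], resolution_km=rr.resolution_km)
    labeled, n = ndimage.label(rr.habitat, structure=_EIGHT_CONN)
    cell_area_ha = rr.resolution_km**2 * 100.0
    comps = []
    for lab in range(1, n + 1):
        cells = np.argwhere(labeled == lab)
        area = len(cells) * cell_area_ha
        if area >= min_area_ha:
            first = cells[np.lexsort((cells[:, 1], cells[:, 0]))][0]
            comps.append((tuple(first), cells, area))
    comps.sort(key=lambda c: c[0])
    patches = [
        Patch(
            id=i,
            cells=cells,
            area_ha=area,
            centroid=(float(cells[:, 0].mean()), float(cells[:, 1].mean())),
        )
        for i, (_, cells, area) in enumerate(comps)
    ]
    return PatchSet(patches=patches, resolution_km=rr.resolution_km)


def _grid_graph(rr: ReefRaster) -> coo_matrix:
    """Sparse 8-neighbor cell graph; edge weight = step length × mean cost."""
    nrows, ncols = rr.shape
    n = nrows * ncols
    cost = rr.cost
    res = rr.resolution_km
    rows_idx, cols_idx, weights = [], [], []
    # offsets covering each undirected neighbor pair once
    for dr, dc, step in [(0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2)),
                         (1, -1, np.sqrt(2))]:
        r0 = slice(max(0, -dr), nrows - max(0, dr))
        c0 = slice(max(0, -dc), ncols - max(0, dc))
        a_r, a_c = np.mgrid[0:nrows, 0:ncols]
        src_r = a_r[r0, c0]
        src_c = a_c[r0, c0]
        dst_r = src_r + dr
        dst_c = src_c + dc
        w = step * res * 0.5 * (cost[src_r, src_c] + cost[dst_r, dst_c])
        rows_idx.append((src_r * ncols + src_c).ravel())
        cols_idx.append((dst_r * ncols + dst_c).ravel())
        weights.append(w.ravel())
    row = np.concatenate(rows_idx)
    col = np.concatenate(cols_idx)
    w = np.concatenate(weights)
    return coo_matrix(
        (np.concatenate([w, w]), (np.concatenate([row, col]),
                                  np.concatenate([col, row]))),
        shape=(n, n),
    ).tocsr()


def least_cost_linkset(ps: PatchSet, rr: ReefRaster) -> LinkSet:
    """All-pairs least-cost distances between patches over the cost raster.

    Exact multi-source Dijkstra expansion from each patch's cells over
    the 8-neighbor grid; a step costs its length (resolution, or √2 ×
    resolution diagonally) times the mean of the two cells' costs.  The
    patch-to-patch distance is the minimum over cell pairs (edge-to-edge
    rather than centroid-to-centroid).  Unreachable pairs get ``inf``.
    """
    if len(ps) == 0:
        return LinkSet(patch_ids=[], distances=np.zeros((0, 0)))
    graph = _grid_graph(rr)
    ncols = rr.shape[1]
    P = len(ps)
    dist = np.zeros((P, P))
    flat_cells = [p.cells[:, 0] * ncols + p.cells[:, 1] for p in ps.patches]
    for i, patch in enumerate(ps.patches[:-1]):
        d = dijkstra(graph, directed=False, indices=flat_cells[i], min_only=True)
        for j in range(i + 1, P):
            dist[i, j] = dist[j, i] = float(d[flat_cells[j]].min())
    return LinkSet(patch_ids=ps.ids, distances=dist)


def build_species_graph(
    ls: LinkSet,
    pld_days: float,
    current_speed: float = DEFAULT_CURRENT_SPEED_KM_PER_DAY,
) -> SpeciesGraph:
    """Threshold the linkset at ``D_max = PLD × current speed``.

    Returns the binary undirected graph with an edge wherever the
    least-cost distance is positive, finite, and at most ``D_max``.
    """
    if pld_days <= 0:
        raise ConfigurationError("pld_days must be positive")
    d_max = pld_days * current_speed
    g = nx.Graph()
    g.add_nodes_from(ls.patch_ids)
    P = len(ls.patch_ids)
    for i in range(P):
        for j in range(i + 1, P):
            d = ls.distances[i, j]
            if 0 < d <= d_max:
                g.add_edge(ls.patch_ids[i], ls.patch_ids[j], distance_km=float(d))
    return SpeciesGraph(
        graph=g, d_max_km=d_max, pld_days=pld_days, current_speed=current_speed
    )


def betweenness(sg: SpeciesGraph) -> dict[int, float]:
    """Normalized shortest-path betweenness centrality per patch.

    Unweighted shortest paths with equal splitting among ties,
    endpoints excluded, normalized by ``(n-1)(n-2)/2``; all zeros for
    graphs with fewer than three nodes.
    """
    return nx.betweenness_centrality(sg.graph, normalized=True)


@dataclass
class DiameterResult:
    steps: int
    connected: bool


def diameter(sg: SpeciesGraph) -> DiameterResult:
    """Largest shortest-path step count between connected patch pairs.

    On a disconnected graph the value is the maximum within-component
    diameter and ``connected`` is False; an edgeless graph reports 0.
    """
    g = sg.graph
    if g.number_of_nodes() == 0:
        return DiameterResult(steps=0, connected=False)
    components = list(nx.connected_components(g))
    best = 0
    for comp in components:
        if len(comp) > 1:
            best = max(best, nx.diameter(g.subgraph(comp)))
    return DiameterResult(steps=best, connected=len(components) == 1)


def rank_focal_patch(sg: SpeciesGraph, focal: int) -> int:
    """1-based betweenness rank of the focal patch (ties share best rank)."""
    if focal not in sg.graph:
        raise UnknownPopulationError(f"patch {focal} not in graph")
    bc = betweenness(sg)
    focal_bc = bc[focal]
    return 1 + sum(1 for v in bc.values() if v > focal_bc)


def generate_synthetic_seascape(
    shape: tuple[int, int] = (60, 120),
    patch_specs: list[tuple[int, int, int]] | None = None,
    n_patches: int | None = None,
    land_rects: list[tuple[int, int, int, int]] | None = None,
    resolution_km: float = 1.0,
    land_cost: float = DEFAULT_LAND_COST,
    seed: int = 0,
) -> ReefRaster:
    """Synthetic seascape of reef patches with known geometry.

    ``patch_specs`` is a list of ``(row, col, radius_cells)`` square
    blobs; alternatively ``n_patches`` patches of radius 1 are placed at
    random non-overlapping positions.  ``land_rects`` are
    ``(row0, col0, row1, col1)`` half-open rectangles of land (cost
    ``land_cost``).  Patch centers and their pairwise straight-line
    distances (km) are recorded in ``metadata`` as ground truth.
    Overlapping patches, or patches on land, raise
    :class:`PlacementError`.
    """
    nrows, ncols = shape
    habitat = np.zeros(shape, dtype=bool)
    cost = np.ones(shape)
    for r0, c0, r1, c1 in land_rects or []:
        cost[r0:r1, c0:c1] = land_cost

    if patch_specs is None:
        if n_patches is None:
            raise ConfigurationError("give patch_specs or n_patches")
        rng = child_rng(seed, "seascape")
        patch_specs = []
        attempts = 0
        while len(patch_specs) < n_patches:
            if attempts > 10_000:
                raise PlacementError("could not place patches without overlap")
            attempts += 1
            r = int(rng.integers(2, nrows - 2))
            c = int(rng.integers(2, ncols - 2))
            if cost[r - 1 : r + 2, c - 1 : c + 2].max() > 1:
                continue
            if habitat[max(0, r - 3) : r + 4, max(0, c - 3) : c + 4].any():
                continue
            patch_specs.append((r, c, 1))

    centers = []
    for r, c, radius in patch_specs:
        r0, r1 = r - radius, r + radius + 1
        c0, c1 = c - radius, c + radius + 1
        if r0 < 0 or c0 < 0 or r1 > nrows or c1 > ncols:
            raise PlacementError(f"patch at ({r}, {c}) falls off the grid")
        block = np.s_[r0:r1, c0:c1]
        if habitat[block].any():
            raise PlacementError(f"patch at ({r}, {c}) overlaps another patch")
        if cost[block].max() > 1:
            raise PlacementError(f"patch at ({r}, {c}) overlaps land")
        habitat[block] = True
        centers.append((r, c))

    centers_arr = np.asarray(centers, dtype=float)
    diff = centers_arr[:, None, :] - centers_arr[None, :, :]
    euclid_km = np.sqrt((diff**2).sum(axis=2)) * resolution_km
    return ReefRaster(
        habitat=habitat,
        cost=cost,
        resolution_km=resolution_km,
        metadata={
            "patch_centers": centers,
            "euclidean_km": euclid_km,
            "land_rects": list(land_rects or []),
        },
    )
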