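"""Candidate island grid, dispersal adjacency and reserve candidacy.

Deadwood islands are 1-ha circles whose candidate centre points lie on a
regular grid clipped to the stand map.  Two candidate points are adjacent
when their Euclidean distance does not exceed the indicator species'
dispersal distance plus two island radii, so that beetles emerging at the
edge of one island can reach the edge of the next.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import KDTree
from shapely import STRtree
from shapely.geometry import Point

from .synth import Landscape

RESERVE_CANDIDATE_SPECIES = ("beech", "silver_fir")
RESERVE_CANDIDATE_MIN_AGE = 160.0  # strict inequality


def island_radius(area_ha: float = 1.0) -> float:
    """Radius in metres of a circular island of the given area."""
    if area_ha <= 0:
        raise ValueError("island area must be positive")
    return float(np.sqrt(area_ha * 1e4 / np.pi))


def adjacency_threshold(dispersal_m: float, island_area_ha: float = 1.0) -> float:
    """Centre-to-centre adjacency distance, rounded to one decimal.

    Rounding makes the printed thresholds (162.8 m at 50 m dispersal,
    412.8 m at 300 m) attainable boundary values; adjacency uses <=.
    """
    if dispersal_m <= 0:
        raise ValueError("dispersal distance must be positive")
    return round(dispersal_m + 2.0 * island_radius(island_area_ha), 1)


@dataclass(frozen=True)
class CandidatePoint:
    id: int
    coords: tuple[float, float]
    stand_id: int
    is_root: bool


@dataclass
class CandidateGrid:
    points: list[CandidatePoint]
    spacing: float
    root_id: int

    def coords_array(self) -> np.ndarray:
        return np.array([p.coords for p in self.points])

    def by_stand(self) -> dict[int, list[int]]:
        g: dict[int, list[int]] = {}
        for p in self.points:
            g.setdefault(p.stand_id, []).append(p.id)
        return g


class RootUndefinedError(ValueError):
    pass


def build_candidate_grid(landscape: Landscape, spacing: float = 60.0) -> CandidateGrid:
    """Regular candidate-centre grid clipped to the stand polygons.

    Points are laid half a spacing in from the landscape origin; each point
    is assigned to exactly one containing stand (ties broken by lowest
    stand id).  The root is the point nearest the centroid of the largest
    existing reserve; it is an error if no grid point falls inside any
    existing reserve.
    """
    minx, miny, maxx, maxy = landscape.bounds
    xs = np.arange(minx + spacing / 2.0, maxx, spacing)
    ys = np.arange(miny + spacing / 2.0, maxy, spacing)
    stands_sorted = sorted(landscape.stands, key=lambda s: s.id)
    tree = STRtree([s.polygon for s in stands_sorted])
    points: list[CandidatePoint] = []
    pid = 0
    for y in ys:
        for x in xs:
            pt = Point(x, y)
            hits = sorted(
                stands_sorted[i].id for i in tree.query(pt, predicate="covered_by")
            )
            if not hits:
                continue
            points.append(CandidatePoint(id=pid, coords=(x, y), stand_id=hits[0], is_root=False))
            pid += 1

    reserves = [s for s in landscape.stands if s.existing_reserve]
    if not reserves:
        raise RootUndefinedError("landscape has no existing reserve to host the root point")
    reserve_ids = {s.id for s in reserves}
    in_reserve = [p for p in points if p.stand_id in reserve_ids]
    if not in_reserve:
        raise RootUndefinedError("no candidate point falls inside any existing reserve")
    largest = max(reserves, key=lambda s: s.area)
    cx, cy = largest.polygon.centroid.x, largest.polygon.centroid.y
    root = min(in_reserve, key=lambda p: (p.coords[0] - cx) ** 2 + (p.coords[1] - cy) ** 2)
    points = [
        CandidatePoint(p.id, p.coords, p.stand_id, p.id == root.id) for p in points
    ]
    return CandidateGrid(points=points, spacing=spacing, root_id=root.id)


@dataclass
class DispersalGraph:
    arcs: list[tuple[int, int]]  # ordered pairs, both directions present
    threshold: float
    dispersal_m: float

    def undirected_edges(self) -> set[tuple[int, int]]:
        return {(min(i, j), max(i, j)) for i, j in self.arcs}


def build_adjacency(grid: CandidateGrid, dispersal_m: float, island_area_ha: float = 1.0) -> DispersalGraph:
    """Dispersal arcs between candidate points within the threshold."""
    thr = adjacency_threshold(dispersal_m, island_area_ha)
    coords = grid.coords_array()
    kdt = KDTree(coords)
    pairs = kdt.query_pairs(thr + 1e-9)
    arcs: list[tuple[int, int]] = []
    ids = [p.id for p in grid.points]
    for a, b in sorted(pairs):
        d = float(np.hypot(*(coords[a] - coords[b])))
        if d <= thr + 1e-9:
            arcs.append((ids[a], ids[b]))
            arcs.append((ids[b], ids[a]))
    return DispersalGraph(arcs=arcs, threshold=thr, dispersal_m=dispersal_m)


def reserve_candidates(landscape: Landscape) -> set[int]:
    """Stands eligible as reserves: old beech/silver fir, plus existing reserves."""
    out = set()
    for s in landscape.stands:
        if s.existing_reserve:
            out.add(s.id)
        elif (
            s.dominant_species in RESERVE_CANDIDATE_SPECIES
            and s.age > RESERVE_CANDIDATE_MIN_AGE
        ):
            out.add(s.id)
    return out


def stand_neighbour_graph(landscape: Landscape, min_shared_boundary: float = 1.0) -> nx.Graph:
    """Undirected stand graph; an edge means a shared polygon boundary.

    Corner contacts (shared boundary shorter than ``min_shared_boundary``
    metres) do not count as neighbourhood.
    """
    g = nx.Graph()
    for s in landscape.stands:
        g.add_node(s.id, area=s.area)
    stands = landscape.stands
    tree = STRtree([s.polygon for s in stands])
    for i, s in enumerate(stands):
        for jj in tree.query(s.polygon, predicate="intersects"):
            t = stands[int(jj)]
            if t.id <= s.id:
                continue
            shared = s.polygon.intersection(t.polygon)
            if shared.length >= min_shared_boundary:
                g.add_edge(s.id, t.id)
    return g


def max_points_per_stand(grid: CandidateGrid) -> int:
    """Uniform bound on islands per stand: the largest per-stand point count."""
    by = grid.by_stand()
    return max((len(v) for v in by.values()), default=0)
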