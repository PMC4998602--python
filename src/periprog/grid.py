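"""24-2 visual-field test-point geometry.

The 24-2 pattern is a 54-point lattice on a 6 degree grid covering 24
degrees of eccentricity, with a nasal extension to 27 degrees and a pair
of points straddling the physiologic blind spot.  All analysis code in
this package works in *right-eye format* (temporal field positive x,
superior field positive y); left-eye fields are mirrored on input so
hemifield, sector and cluster logic never branch on laterality.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "GridLocation",
    "Grid",
    "build_grid",
    "mirror",
    "adjacent",
    "find_clusters",
]

# Row layout of the 24-2 pattern in right-eye format, superior rows first.
# x increases temporally (nasal extension at x = -27), y increases superiorly.
_ROWS: list[tuple[int, list[int]]] = [
    (21, [-9, -3, 3, 9]),
    (15, [-15, -9, -3, 3, 9, 15]),
    (9, [-21, -15, -9, -3, 3, 9, 15, 21]),
    (3, [-27, -21, -15, -9, -3, 3, 9, 15, 21]),
    (-3, [-27, -21, -15, -9, -3, 3, 9, 15, 21]),
    (-9, [-21, -15, -9, -3, 3, 9, 15, 21]),
    (-15, [-15, -9, -3, 3, 9, 15]),
    (-21, [-9, -3, 3, 9]),
]

#: Blind-spot pair in right-eye format (temporal 15 degrees, straddling midline).
BLIND_SPOT_XY: frozenset[tuple[int, int]] = frozenset({(15, 3), (15, -3)})

_SPACING = 6  # degrees between neighboring lattice points

# Supero-temporal / infero-temporal sectors: arcuate regions sweeping from the
# superior (resp. inferior) paracentral field into the temporal field, mirror
# images of each other about the horizontal midline.  The blind spot belongs to
# neither.  These are explicit, overridable lists; see ``build_grid``.
_ST_XY: frozenset[tuple[int, int]] = frozenset(
    {
        (-9, 21), (-3, 21), (3, 21), (9, 21),
        (-9, 15), (-3, 15), (3, 15), (9, 15), (15, 15),
        (3, 9), (9, 9), (15, 9), (21, 9),
        (9, 3), (21, 3),
    }
)
_IT_XY: frozenset[tuple[int, int]] = frozenset((x, -y) for x, y in _ST_XY)


@dataclass(frozen=True)
class GridLocation:
    """One test location of the 24-2 pattern (right-eye format unless mirrored)."""

    index: int
    x: int
    y: int
    is_blind_spot: bool
    is_edge: bool
    hemifield: str  # "superior" | "inferior"
    sector: str  # "ST" | "IT" | "other"; blind-spot points are "other"


@dataclass(frozen=True)
class Grid:
    """The full 24-2 lattice with adjacency over non-blind-spot locations."""

    laterality: str
    locations: tuple[GridLocation, ...]
    adjacency: dict[int, frozenset[int]] = field(repr=False)

    @property
    def n_locations(self) -> int:
        return len(self.locations)

    @property
    def blind_spot_indices(self) -> tuple[int, ...]:
        return tuple(l.index for l in self.locations if l.is_blind_spot)

    @property
    def analyzed_indices(self) -> tuple[int, ...]:
        """Indices entering any analysis: the 52 non-blind-spot locations."""
        return tuple(l.index for l in self.locations if not l.is_blind_spot)

    @property
    def edge_indices(self) -> tuple[int, ...]:
        return tuple(l.index for l in self.locations if l.is_edge)

    def sector_indices(self, sector: str) -> tuple[int, ...]:
        if sector == "global":
            return self.analyzed_indices
        return tuple(l.index for l in self.locations if l.sector == sector)

    def to_json(self) -> str:
        """Serialize geometry and flags so configs can pin a grid version."""
        payload = {
            "laterality": self.laterality,
            "locations": [
                {
                    "index": l.index,
                    "x": l.x,
                    "y": l.y,
                    "is_blind_spot": l.is_blind_spot,
                    "is_edge": l.is_edge,
                    "hemifield": l.hemifield,
                    "sector": l.sector,
                }
                for l in self.locations
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Grid":
        payload = json.loads(text)
        locs = tuple(GridLocation(**d) for d in payload["locations"])
        return cls(payload["laterality"], locs, _build_adjacency(locs))


def _build_adjacency(locations: Sequence[GridLocation]) -> dict[int, frozenset[int]]:
    """8-neighborhood on the 6-degree lattice, blind spots isolated."""
    adj: dict[int, set[int]] = {l.index: set() for l in locations}
    for a in locations:
        if a.is_blind_spot:
            continue
        for b in locations:
            if b.is_blind_spot or a.index == b.index:
                continue
            if abs(a.x - b.x) <= _SPACING and abs(a.y - b.y) <= _SPACING:
                adj[a.index].add(b.index)
    return {k: frozenset(v) for k, v in adj.items()}


def _derive_edges(coords: Sequence[tuple[int, int]]) -> set[int]:
    """Edge = missing at least one axial (N/S/E/W) lattice neighbor.

    Blind-spot points count as existing neighbors, so the two points nasal to
    the blind spot are not edge by virtue of the blind spot alone.
    """
    present = set(coords)
    edges: set[int] = set()
    for i, (x, y) in enumerate(coords):
        if (x, y) in BLIND_SPOT_XY:
            continue
        axial = [(x + _SPACING, y), (x - _SPACING, y), (x, y + _SPACING), (x, y - _SPACING)]
        if any(n not in present for n in axial):
            edges.add(i)
    return edges


def build_grid(
    laterality: str = "OD",
    *,
    edge_indices: Iterable[int] | None = None,
    st_indices: Iterable[int] | None = None,
    it_indices: Iterable[int] | None = None,
) -> Grid:
    """Construct the 24-2 grid for one eye.

    Parameters
    ----------
    laterality:
        ``"OD"`` (right eye, the analysis format) or ``"OS"``.  The OS grid is
        the mirror image (x -> -x) of the OD grid with identical indexing, so
        flags are laterality-free.
    edge_indices, st_indices, it_indices:
        Optional explicit overrides for the edge-location set and the
        supero-/infero-temporal sectors, to support alternative conventions.

    Returns
    -------
    Grid
        54 locations (row-major, superior rows first), of which 52 are
        analyzed after blind-spot exclusion.
    """
    if laterality not in ("OD", "OS"):
        raise ValueError(f"laterality must be 'OD' or 'OS', got {laterality!r}")

    coords = [(x, y) for y, xs in _ROWS for x in xs]
    edges = set(edge_indices) if edge_indices is not None else _derive_edges(coords)
    st = (
        {i for i, c in enumerate(coords) if c in _ST_XY}
        if st_indices is None
        else set(st_indices)
    )
    it = (
        {i for i, c in enumerate(coords) if c in _IT_XY}
        if it_indices is None
        else set(it_indices)
    )

    sign = 1 if laterality == "OD" else -1
    locs = []
    for i, (x, y) in enumerate(coords):
        bs = (x, y) in BLIND_SPOT_XY
        locs.append(
            GridLocation(
                index=i,
                x=sign * x,
                y=y,
                is_blind_spot=bs,
                is_edge=(i in edges) and not bs,
                hemifield="superior" if y > 0 else "inferior",
                sector="ST" if i in st else ("IT" if i in it else "other"),
            )
        )
    locations = tuple(locs)
    return Grid(laterality, locations, _build_adjacency(locations))


def mirror(grid: Grid) -> Grid:
    """Flip a grid between OD and OS format (x -> -x).  An involution."""
    flipped = tuple(
        GridLocation(
            index=l.index,
            x=-l.x,
            y=l.y,
            is_blind_spot=l.is_blind_spot,
            is_edge=l.is_edge,
            hemifield=l.hemifield,
            sector=l.sector,
        )
        for l in grid.locations
    )
    other = "OS" if grid.laterality == "OD" else "OD"
    return Grid(other, flipped, grid.adjacency)


def adjacent(grid: Grid, a: int, b: int) -> bool:
    """True iff locations ``a`` and ``b`` are 8-neighbors on the lattice.

    Blind-spot locations are adjacent to nothing.
    """
    n = grid.n_locations
    if not (0 <= a < n and 0 <= b < n):
        raise IndexError(f"location index out of range: {a}, {b}")
    return b in grid.adjacency[a]


def find_clusters(
    grid: Grid,
    flagged: Iterable[int],
    *,
    require_same_hemifield: bool = False,
) -> list[frozenset[int]]:
    """Connected components of the adjacency graph restricted to flagged points.

    With ``require_same_hemifield`` the adjacency relation is additionally
    restricted to pairs of locations in the same hemifield before components
    are taken, so clusters never span the horizontal midline.

    Returns clusters in decreasing size order, ties broken by the smallest
    member index, so output order is deterministic.
    """
    flagged = set(flagged)
    bs = set(grid.blind_spot_indices)
    if flagged & bs:
        raise ValueError("flagged set contains blind-spot locations")
    hemi = {l.index: l.hemifield for l in grid.locations}

    g = nx.Graph()
    g.add_nodes_from(flagged)
    for a in flagged:
        for b in grid.adjacency[a]:
            if b in flagged and (not require_same_hemifield or hemi[a] == hemi[b]):
                g.add_edge(a, b)
    comps = [frozenset(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))
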