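"""Hexagonal furrow-lattice geometry.

During *Drosophila* cellularization the cleavage furrows ingress along a
honeycomb array in which each hexagonal unit encloses one nucleus.  This
module builds the regular-hexagon template used both to seed the contractile
network simulation and to define the outline polygons for intensity
quantification.

Coordinates are in micrometres throughout.  The tiling is "pointy-top":
hexagon corners sit at angles 30 + 60*k degrees, so the left/right sides of
each cell are vertical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HexLattice", "build_hex_lattice", "LatticeError"]

_MERGE_DECIMALS = 9  # corners closer than 1e-9 um are the same vertex


class LatticeError(ValueError):
    """Invalid lattice construction parameters."""


@dataclass(frozen=True)
class HexLattice:
    """A rows x cols patch of regular hexagons.

    Attributes
    ----------
    vertices : (V, 2) float array
        Vertex coordinates in um.
    edges : (E, 2) int array
        Pairs of vertex indices, each pair sorted, rows lexicographically
        sorted.
    cells : list of (6,) int arrays
        Corner indices of each hexagon, in counter-clockwise order.
    edge_length : float
        Geometric length L shared by every edge.
    """

    vertices: np.ndarray
    edges: np.ndarray
    cells: list = field(default_factory=list)
    edge_length: float = 1.0

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def vertex_degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_vertices, dtype=int)
        np.add.at(deg, self.edges.ravel(), 1)
        return deg

    def boundary_vertex_mask(self) -> np.ndarray:
        """Vertices on the patch rim (degree < 3)."""
        return self.vertex_degrees() < 3

    def edge_endpoints(self) -> np.ndarray:
        """(E, 2, 2) array of edge endpoint coordinates."""
        return self.vertices[self.edges]

    def edge_midpoints(self) -> np.ndarray:
        return self.vertices[self.edges].mean(axis=1)

    def edge_unit_vectors(self) -> np.ndarray:
        v = self.vertices[self.edges[:, 1]] - self.vertices[self.edges[:, 0]]
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    def cell_polygons(self) -> list:
        """Per-cell (6, 2) corner coordinate arrays (closed implicitly)."""
        return [self.vertices[c] for c in self.cells]

    def bounds(self) -> tuple:
        """(xmin, ymin, xmax, ymax) in um."""
        lo = self.vertices.min(axis=0)
        hi = self.vertices.max(axis=0)
        return (lo[0], lo[1], hi[0], hi[1])


def _hex_corners(cx: float, cy: float, L: float) -> np.ndarray:
    ang = np.deg2rad(30.0 + 60.0 * np.arange(6))
    return np.column_stack([cx + L * np.cos(ang), cy + L * np.sin(ang)])


def build_hex_lattice(rows: int, cols: int, edge_length: float) -> HexLattice:
    """Build a rows x cols honeycomb patch of regular hexagons.

    Corner duplicates shared between neighbouring cells are merged to a
    single vertex (tolerance 1e-9 um).  Every interior vertex of the result
    has degree 3 and every edge has geometric length ``edge_length``.
    """
    if rows < 1 or cols < 1:
        raise LatticeError(f"rows and cols must be >= 1, got {rows} x {cols}")
    if not edge_length > 0:
        raise LatticeError(f"edge_length must be > 0, got {edge_length}")

    L = float(edge_length)
    dx = np.sqrt(3.0) * L
    dy = 1.5 * L

    index_of: dict = {}
    verts: list = []
    cells: list = []
    edge_set = set()

    for i in range(rows):
        for j in range(cols):
            cx = j * dx + (i % 2) * dx / 2.0
            cy = i * dy
            corners = _hex_corners(cx, cy, L)
            idx = np.empty(6, dtype=int)
            for k, (x, y) in enumerate(corners):
                key = (round(x, _MERGE_DECIMALS), round(y, _MERGE_DECIMALS))
                if key not in index_of:
                    index_of[key] = len(verts)
                    verts.append((x, y))
                idx[k] = index_of[key]
            cells.append(idx)
            for k in range(6):
                a, b = idx[k], idx[(k + 1) % 6]
                edge_set.add((min(a, b), max(a, b)))

    vertices = np.asarray(verts, dtype=float)
    edges = np.array(sorted(edge_set), dtype=int)
    return HexLattice(vertices=vertices, edges=edges, cells=cells, edge_length=L)
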