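"""Triangulated surface template geometry.

The analysis operates on per-vertex scalar maps defined on a shared
triangulated surface (in practice a registered cortical template such as
FreeSurfer's fsaverage; in the synthetic pipeline an icosphere).  The mesh
supplies the adjacency used for cluster connectivity, per-vertex areas used
for area-weighted statistics, and edge geometry used for smoothing and
smoothness estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import dijkstra


@dataclass
class SurfaceMesh:
    """A triangulated 2-manifold surface.

    Parameters
    ----------
    vertices : (V, 3) float array
        Vertex positions in mm.
    faces : (F, 3) int array
        Counter-clockwise vertex-index triples.
    mesh_id : str
        Identifier binding vertex maps to this geometry.
    """

    vertices: np.ndarray
    faces: np.ndarray
    mesh_id: str = "mesh"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (F, 3)")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of range")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    @cached_property
    def edges(self) -> np.ndarray:
        """Unique undirected edges, (E, 2), sorted pairs."""
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @cached_property
    def edge_lengths(self) -> np.ndarray:
        d = self.vertices[self.edges[:, 0]] - self.vertices[self.edges[:, 1]]
        return np.linalg.norm(d, axis=1)

    @property
    def edge_length_mean(self) -> float:
        return float(self.edge_lengths.mean())

    @cached_property
    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric vertex adjacency (1 where an edge exists)."""
        i, j = self.edges.T
        n = self.n_vertices
        a = sparse.coo_matrix(
            (np.ones(2 * len(i)), (np.r_[i, j], np.r_[j, i])), shape=(n, n)
        )
        return a.tocsr()

    @cached_property
    def weighted_adjacency(self) -> sparse.csr_matrix:
        """Adjacency weighted by Euclidean edge length (mm)."""
        i, j = self.edges.T
        w = self.edge_lengths
        n = self.n_vertices
        a = sparse.coo_matrix((np.r_[w, w], (np.r_[i, j], np.r_[j, i])), shape=(n, n))
        return a.tocsr()

    @cached_property
    def triangle_areas(self) -> np.ndarray:
        p = self.vertices[self.faces]
        cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    @cached_property
    def vertex_areas(self) -> np.ndarray:
        """One third of the incident triangle areas per vertex (mm^2)."""
        a = np.zeros(self.n_vertices)
        np.add.at(a, self.faces.ravel(), np.repeat(self.triangle_areas / 3.0, 3))
        return a

    @property
    def total_area(self) -> float:
        return float(self.triangle_areas.sum())

    @property
    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges + self.n_faces

    def vertex_neighbors(self, v: int) -> np.ndarray:
        return self.adjacency.indices[self.adjacency.indptr[v] : self.adjacency.indptr[v + 1]]

    def geodesic_distances(self, seed: int) -> np.ndarray:
        """Graph-geodesic distance (mm) from ``seed`` to every vertex.

        Dijkstra over edge lengths; clusters planted with this metric are
        guaranteed connected in mesh adjacency.
        """
        d = dijkstra(self.weighted_adjacency, directed=False, indices=seed)
        return np.asarray(d)

    def geodesic_ball(self, seed: int, radius_mm: float) -> np.ndarray:
        """Vertex indices within graph-geodesic ``radius_mm`` of ``seed``."""
        return np.flatnonzero(self.geodesic_distances(seed) <= radius_mm)

    def validate(self) -> None:
        """Raise ValueError if basic manifold invariants fail."""
        if np.any(self.vertex_areas <= 0):
            raise ValueError("degenerate vertex areas")
        total_v = self.vertex_areas.sum()
        if not np.isclose(total_v, self.total_area, rtol=1e-9):
            raise ValueError("vertex areas do not sum to triangle areas")
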