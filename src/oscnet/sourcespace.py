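"""Icosphere-based source spaces and their spatial adjacency.

Source locations are modeled as vertices of a recursively subdivided
icosahedron projected onto the unit sphere (an "icosphere"), one sphere per
hemisphere.  Subdivision depth ``k`` yields ``10 * 4**k + 2`` vertices per
hemisphere (12, 42, 162, ...).  The polyhedron's edges define the spatial
neighbor relation used by cluster statistics: two locations are immediate
neighbors iff they are directly connected in the mesh.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SourceSpace", "icosphere", "bilateral_source_space", "spatial_adjacency"]


@dataclass
class SourceSpace:
    """A bilateral (or single-hemisphere) set of source locations.

    Attributes
    ----------
    vertices : (n, 3) float array
        Unit-sphere coordinates of every location.
    edges : (m, 2) int array
        Undirected mesh edges, each stored once with ``i < j``.  Edges never
        cross hemispheres.
    hemisphere : (n,) int array
        0 for left, 1 for right.
    kept_mask : (n,) bool array
        False for locations excluded from analysis.
    """

    vertices: np.ndarray
    edges: np.ndarray
    hemisphere: np.ndarray
    kept_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.edges = np.asarray(self.edges, dtype=int)
        self.hemisphere = np.asarray(self.hemisphere, dtype=int)
        if self.kept_mask is None:
            self.kept_mask = np.ones(len(self.vertices), dtype=bool)
        else:
            self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        radii = np.linalg.norm(self.vertices, axis=1)
        if not np.allclose(radii, 1.0, atol=1e-9):
            raise ValueError("all vertices must lie on the unit sphere")

    @property
    def n_locations(self) -> int:
        return len(self.vertices)

    @property
    def n_kept(self) -> int:
        return int(self.kept_mask.sum())

    def to_json(self) -> str:
        return json.dumps(
            {
                "vertices": self.vertices.tolist(),
                "edges": self.edges.tolist(),
                "hemisphere": self.hemisphere.tolist(),
                "kept_mask": self.kept_mask.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SourceSpace":
        d = json.loads(text)
        return cls(
            vertices=np.array(d["vertices"], dtype=float),
            edges=np.array(d["edges"], dtype=int),
            hemisphere=np.array(d["hemisphere"], dtype=int),
            kept_mask=np.array(d["kept_mask"], dtype=bool),
        )


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    """Regular icosahedron: 12 unit vertices and 20 triangular faces."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=int,
    )
    return verts, faces


def _subdivide(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split every triangle into four; midpoints are projected to the sphere
    and shared between adjacent faces (duplicate midpoints merged)."""
    verts = list(map(tuple, verts))
    midpoint_cache: dict[tuple[int, int], int] = {}

    def midpoint(i: int, j: int) -> int:
        key = (min(i, j), max(i, j))
        if key not in midpoint_cache:
            m = (np.array(verts[i]) + np.array(verts[j])) / 2.0
            m /= np.linalg.norm(m)
            midpoint_cache[key] = len(verts)
            verts.append(tuple(m))
        return midpoint_cache[key]

    new_faces = []
    for a, b, c in faces:
        ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
        new_faces.extend([[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]])
    return np.array(verts, dtype=float), np.array(new_faces, dtype=int)


def _faces_to_edges(faces: np.ndarray) -> np.ndarray:
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e.sort(axis=1)
    return np.unique(e, axis=0)


def icosphere(n_subdivisions: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Subdivided icosahedron projected to the unit sphere.

    Parameters
    ----------
    n_subdivisions : int
        Recursive subdivision depth ``k >= 0``; yields ``10 * 4**k + 2``
        vertices.

    Returns
    -------
    vertices : (n, 3) float array
    edges : (m, 2) int array, each undirected edge once with ``i < j``
    faces : (f, 3) int array
    """
    if n_subdivisions < 0:
        raise ValueError("n_subdivisions must be >= 0")
    verts, faces = _icosahedron()
    for _ in range(int(n_subdivisions)):
        verts, faces = _subdivide(verts, faces)
    return verts, _faces_to_edges(faces), faces


def bilateral_source_space(
    n_subdivisions: int, exclusion_ids: list[int] | None = None
) -> SourceSpace:
    """Two mirrored hemisphere icospheres with optional location exclusions.

    The left hemisphere is the icosphere mirrored in x; the right hemisphere
    keeps the original coordinates.  Adjacency never crosses hemispheres.
    ``exclusion_ids`` index into the concatenated (left-then-right) vertex
    list; excluded locations stay in the arrays but are flagged out of
    ``kept_mask`` (at the default depth 2 this mimics reducing 324 candidate
    locations to an analysis subset, e.g. dropping midline sites).
    """
    verts, edges, _ = icosphere(n_subdivisions)
    n = len(verts)
    left = verts * np.array([-1.0, 1.0, 1.0])
    vertices = np.vstack([left, verts])
    edges_all = np.vstack([edges, edges + n])
    hemisphere = np.repeat([0, 1], n)
    kept = np.ones(2 * n, dtype=bool)
    if exclusion_ids:
        ids = np.asarray(exclusion_ids, dtype=int)
        if ids.min() < 0 or ids.max() >= 2 * n:
            raise ValueError("exclusion id outside the vertex range")
        kept[ids] = False
    return SourceSpace(vertices=vertices, edges=edges_all, hemisphere=hemisphere, kept_mask=kept)


def spatial_adjacency(space: SourceSpace) -> dict[int, set[int]]:
    """Neighbor map from the mesh edges, restricted to kept locations.

    Excluded locations appear with empty neighbor sets and are removed from
    every other location's neighbor set (the post-exclusion polyhedron).
    """
    nbrs: dict[int, set[int]] = {i: set() for i in range(space.n_locations)}
    kept = space.kept_mask
    for i, j in space.edges:
        if kept[i] and kept[j]:
            nbrs[int(i)].add(int(j))
            nbrs[int(j)].add(int(i))
    return nbrs
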