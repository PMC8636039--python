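"""Triangulated head surfaces: icosphere generation, OBJ I/O, solid angles.

Coordinates are meters in a head-centered right-handed frame
(x right, y anterior, z superior). Triangles are oriented counterclockwise
seen from outside, i.e. outward normals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "TriSurface",
    "TriSurfaceSet",
    "icosphere",
    "read_obj",
    "write_obj",
    "solid_angles",
]


@dataclass(frozen=True)
class TriSurface:
    """A closed triangulated surface with outward-oriented triangles."""

    vertices: np.ndarray  # (nv, 3) float, meters
    triangles: np.ndarray  # (nt, 3) int

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        t = np.asarray(self.triangles, dtype=int)
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "triangles", t)
        if v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices must be (nv, 3)")
        if t.ndim != 2 or t.shape[1] != 3:
            raise ValueError("triangles must be (nt, 3)")
        if t.min() < 0 or t.max() >= len(v):
            raise ValueError("triangle indices out of range")

    @property
    def centroids(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)

    @property
    def areas(self) -> np.ndarray:
        p = self.vertices[self.triangles]
        return 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )

    def validate_closed(self) -> None:
        """Check every edge is shared by exactly two triangles, opposite senses."""
        edges: dict[tuple[int, int], int] = {}
        for tri in self.triangles:
            for k in range(3):
                e = (int(tri[k]), int(tri[(k + 1) % 3]))
                edges[e] = edges.get(e, 0) + 1
        for (i, j), c in edges.items():
            if c != 1 or edges.get((j, i), 0) != 1:
                raise ValueError("surface is not closed and consistently oriented")

    def max_radius(self, center: np.ndarray) -> float:
        return float(np.linalg.norm(self.vertices - center, axis=1).max())

    def min_radius(self, center: np.ndarray) -> float:
        return float(np.linalg.norm(self.vertices - center, axis=1).min())


@dataclass(frozen=True)
class TriSurfaceSet:
    """Nested closed surfaces ordered brain, skull, scalp with conductivities.

    ``conductivities`` holds the isotropic conductivity (S/m) of the volume
    *inside* each surface: (brain, skull, scalp). Outside the scalp is air
    (zero conductivity).
    """

    surfaces: tuple[TriSurface, TriSurface, TriSurface]
    conductivities: tuple[float, float, float]
    center: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.surfaces) != 3 or len(self.conductivities) != 3:
            raise ValueError("exactly three surfaces/conductivities required")
        if any(c <= 0 for c in self.conductivities):
            raise ValueError("conductivities must be > 0")
        c = (
            np.zeros(3)
            if self.center is None
            else np.asarray(self.center, dtype=float)
        )
        object.__setattr__(self, "center", c)

    def validate(self) -> None:
        for s in self.surfaces:
            s.validate_closed()
        r_out = [s.max_radius(self.center) for s in self.surfaces]
        r_in = [s.min_radius(self.center) for s in self.surfaces]
        if not (r_out[0] <= r_in[1] + 1e-12 and r_out[1] <= r_in[2] + 1e-12):
            raise ValueError("surfaces are not nested brain < skull < scalp")


def icosphere(radius: float = 1.0, subdivisions: int = 3,
              center=(0.0, 0.0, 0.0)) -> TriSurface:
    """Geodesic sphere from recursive icosahedron subdivision.

    ``subdivisions=3`` gives 1280 triangles per surface.
    """
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
    tris = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = list(verts)
    cache: dict[tuple[int, int], int] = {}

    def midpoint(i: int, j: int) -> int:
        key = (min(i, j), max(i, j))
        if key not in cache:
            m = verts[i] + verts[j]
            verts.append(m / np.linalg.norm(m))
            cache[key] = len(verts) - 1
        return cache[key]

    for _ in range(subdivisions):
        new_tris = []
        for (a, b, c) in tris:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_tris += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        tris = new_tris
    v = np.asarray(verts) * radius + np.asarray(center, dtype=float)
    return TriSurface(v, np.asarray(tris, dtype=int))


def three_shell_mesh(
    radii=(0.087, 0.092, 0.100),
    conductivities=(0.33, 0.0042, 0.33),
    subdivisions: int = 3,
    center=(0.0, 0.0, 0.0),
) -> TriSurfaceSet:
    """Procedural spherical three-shell head mesh (brain, skull, scalp)."""
    if not (radii[0] < radii[1] < radii[2]):
        raise ValueError("radii must be strictly increasing")
    surfs = tuple(icosphere(r, subdivisions, center) for r in radii)
    return TriSurfaceSet(surfs, tuple(conductivities), np.asarray(center, float))


def write_obj(path, surface: TriSurface) -> None:
    """Write one surface as Wavefront OBJ (1-based indices)."""
    lines = [f"v {x:.9g} {y:.9g} {z:.9g}" for x, y, z in surface.vertices]
    lines += [f"f {a + 1} {b + 1} {c + 1}" for a, b, c in surface.triangles]
    Path(path).write_text("\n".join(lines) + "\n")


def read_obj(path) -> TriSurface:
    verts, tris = [], []
    for raw in Path(path).read_text().splitlines():
        parts = raw.split()
        if not parts:
            continue
        if parts[0] == "v":
            verts.append([float(x) for x in parts[1:4]])
        elif parts[0] == "f":
            idx = [int(tok.split("/")[0]) - 1 for tok in parts[1:]]
            if len(idx) != 3:
                raise ValueError("only triangular faces are supported")
            tris.append(idx)
    if not verts or not tris:
        raise ValueError(f"no mesh data found in {path}")
    return TriSurface(np.asarray(verts, float), np.asarray(tris, int))


def solid_angles(surface: TriSurface, points: np.ndarray) -> np.ndarray:
    """Signed solid angles of each triangle seen from each point.

    Returns (n_points, n_triangles). Sign convention: with outward-oriented
    triangles the angles of a closed surface sum to 4*pi for an interior
    point and 0 for an exterior one (van Oosterom & Strackee formula).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    tri = surface.vertices[surface.triangles]  # (nt, 3, 3)
    # y_k = vertex_k - observation point, per point/triangle
    y = tri[None, :, :, :] - pts[:, None, None, :]  # (np, nt, 3, 3)
    y1, y2, y3 = y[:, :, 0], y[:, :, 1], y[:, :, 2]
    n1 = np.linalg.norm(y1, axis=-1)
    n2 = np.linalg.norm(y2, axis=-1)
    n3 = np.linalg.norm(y3, axis=-1)
    num = np.einsum("pti,pti->pt", y1, np.cross(y2, y3))
    den = (
        n1 * n2 * n3
        + np.einsum("pti,pti->pt", y1, y2) * n3
        + np.einsum("pti,pti->pt", y1, y3) * n2
        + np.einsum("pti,pti->pt", y2, y3) * n1
    )
    return 2.0 * np.arctan2(num, den)
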