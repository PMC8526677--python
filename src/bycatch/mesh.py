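"""Triangular meshes with barrier flags, P1 finite elements, and projectors.

The mesh lives in planar kilometres.  Its construction is deliberately simple:
a regular fine grid of vertices over the study boundary, an optional coarser
ring of vertices extending the mesh outward (to push the larger boundary
variance of SPDE fields outside the region of interest), and a Delaunay
triangulation of the union.  Triangles whose centroid falls inside a barrier
polygon are flagged; the barrier enters the field model only through these
flags.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import shapely
from scipy.spatial import Delaunay
from shapely.geometry import Polygon

from bycatch.geometry import DomainSpec


@dataclass
class BarrierMesh:
    """Planar triangulation with per-triangle barrier flags.

    ``nodes`` are (n, 2) km coordinates; ``triangles`` are (m, 3) vertex index
    triples; ``barrier_flag[t]`` is True iff triangle t's centroid lies inside
    a barrier polygon; ``inner_flag[t]`` is True iff the centroid lies inside
    the study boundary (False for extension triangles).
    """

    nodes: np.ndarray
    triangles: np.ndarray
    barrier_flag: np.ndarray
    inner_flag: np.ndarray
    boundary_extension: float
    node_in_domain: np.ndarray = field(default=None)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        self.barrier_flag = np.asarray(self.barrier_flag, dtype=bool)
        self.inner_flag = np.asarray(self.inner_flag, dtype=bool)
        if self.triangles.size and self.triangles.max() >= len(self.nodes):
            raise ValueError("triangle refers to missing node index")
        if self.node_in_domain is None:
            self.node_in_domain = np.ones(len(self.nodes), dtype=bool)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def centroids(self) -> np.ndarray:
        return self.nodes[self.triangles].mean(axis=1)

    def triangle_areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        v1 = p[:, 1] - p[:, 0]
        v2 = p[:, 2] - p[:, 0]
        return 0.5 * np.abs(v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])

    def edge_lengths(self) -> np.ndarray:
        """(m, 3) edge lengths per triangle."""
        p = self.nodes[self.triangles]
        return np.stack([
            np.linalg.norm(p[:, 1] - p[:, 0], axis=1),
            np.linalg.norm(p[:, 2] - p[:, 1], axis=1),
            np.linalg.norm(p[:, 0] - p[:, 2], axis=1),
        ], axis=1)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "nodes": self.nodes.tolist(),
            "triangles": self.triangles.tolist(),
            "barrier_flag": self.barrier_flag.astype(int).tolist(),
            "inner_flag": self.inner_flag.astype(int).tolist(),
            "boundary_extension": self.boundary_extension,
            "node_in_domain": self.node_in_domain.astype(int).tolist(),
        }

    def write_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "BarrierMesh":
        return cls(np.asarray(d["nodes"]), np.asarray(d["triangles"]),
                   np.asarray(d["barrier_flag"], dtype=bool),
                   np.asarray(d["inner_flag"], dtype=bool),
                   d["boundary_extension"],
                   np.asarray(d["node_in_domain"], dtype=bool))

    @classmethod
    def read_json(cls, path) -> "BarrierMesh":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def _grid_points(xmin, xmax, ymin, ymax, h):
    nx = max(int(np.ceil((xmax - xmin) / h)) + 1, 2)
    ny = max(int(np.ceil((ymax - ymin) / h)) + 1, 2)
    gx = np.linspace(xmin, xmax, nx)
    gy = np.linspace(ymin, ymax, ny)
    X, Y = np.meshgrid(gx, gy)
    return np.column_stack([X.ravel(), Y.ravel()])


def build_mesh(domain: DomainSpec, max_edge_inner: float,
               max_edge_outer: float | None = None,
               extension_km: float | None = None) -> BarrierMesh:
    """Triangulate the study domain (planar km) with an optional coarse extension.

    Vertices are laid on a regular grid of spacing ``max_edge_inner / sqrt(2)``
    over the boundary's bounding box (so every inner edge is at most
    ``max_edge_inner``), plus a coarser grid ring of width ``extension_km``
    outside the boundary.  Triangles are flagged barrier/inner by centroid
    membership.
    """
    max_edge_outer = max_edge_outer if max_edge_outer is not None else max_edge_inner
    if not (0 < max_edge_inner <= max_edge_outer):
        raise ValueError("require 0 < max_edge_inner <= max_edge_outer")
    boundary_p = domain.polygon_planar(domain.boundary)
    if not boundary_p.is_valid:
        raise ValueError("boundary polygon is degenerate")
    barriers_p = []
    for b in domain.barriers:
        bp = domain.polygon_planar(b)
        if not bp.is_valid:
            raise ValueError("barrier polygon is degenerate")
        barriers_p.append(bp)

    xmin, ymin, xmax, ymax = boundary_p.bounds
    if extension_km is None:
        extension_km = 0.15 * float(np.hypot(xmax - xmin, ymax - ymin))
    h_in = max_edge_inner / np.sqrt(2.0)
    fine = _grid_points(xmin, xmax, ymin, ymax, h_in)
    keep = shapely.contains_xy(boundary_p.buffer(0.51 * h_in),
                               fine[:, 0], fine[:, 1])
    pts = [fine[keep]]

    if extension_km > 0:
        h_out = max_edge_outer / np.sqrt(2.0)
        coarse = _grid_points(xmin - extension_km, xmax + extension_km,
                              ymin - extension_km, ymax + extension_km, h_out)
        outside = ~shapely.contains_xy(boundary_p.buffer(0.51 * h_out),
                                       coarse[:, 0], coarse[:, 1])
        pts.append(coarse[outside])
    nodes = np.vstack(pts)

    tri = Delaunay(nodes)
    triangles = tri.simplices
    # drop degenerate (zero-area) triangles if any
    p = nodes[triangles]
    areas = 0.5 * np.abs((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
                         - (p[:, 1, 1] - p[:, 0, 1]) * (p[:, 2, 0] - p[:, 0, 0]))
    triangles = triangles[areas > 1e-12]

    cent = nodes[triangles].mean(axis=1)
    inner = shapely.contains_xy(boundary_p, cent[:, 0], cent[:, 1])
    barrier = np.zeros(len(triangles), dtype=bool)
    for bp in barriers_p:
        barrier |= shapely.contains_xy(bp, cent[:, 0], cent[:, 1])

    node_in = shapely.contains_xy(boundary_p, nodes[:, 0], nodes[:, 1])
    for bp in barriers_p:
        node_in &= ~shapely.contains_xy(bp, nodes[:, 0], nodes[:, 1])

    return BarrierMesh(nodes=nodes, triangles=triangles, barrier_flag=barrier,
                       inner_flag=inner, boundary_extension=float(extension_km),
                       node_in_domain=node_in)


@dataclass
class FEMOperators:
    """P1 finite-element operators: lumped mass C (diagonal) and stiffness G.

    ``c_parts``/``g_parts`` split the assembly by barrier flag so that
    non-stationary (barrier) precisions can reweight the two subdomains.
    """

    c: np.ndarray                  # diagonal of the lumped mass matrix
    G: sp.csr_matrix
    c_parts: dict                  # {False: open-water diag, True: barrier diag}
    g_parts: dict                  # {False: open-water G, True: barrier G}

    @property
    def C(self) -> sp.dia_matrix:
        return sp.diags(self.c)


def assemble_fem(mesh: BarrierMesh) -> FEMOperators:
    """Assemble lumped mass and stiffness matrices on the mesh."""
    n = mesh.n_nodes
    areas = mesh.triangle_areas()
    if np.any(areas <= 0):
        raise ValueError("mesh contains a zero-area triangle")
    p = mesh.nodes[mesh.triangles]          # (m, 3, 2)

    c_parts = {False: np.zeros(n), True: np.zeros(n)}
    rows_parts = {False: [], True: []}
    cols_parts = {False: [], True: []}
    vals_parts = {False: [], True: []}

    # P1 gradients: for vertex i of a triangle, grad phi_i = perp(edge_jk)/(2A)
    for flag in (False, True):
        sel = mesh.barrier_flag == flag
        if not sel.any():
            continue
        tri = mesh.triangles[sel]
        pts = p[sel]
        A = areas[sel]
        # edge vectors opposite each vertex
        e = np.stack([pts[:, 2] - pts[:, 1],
                      pts[:, 0] - pts[:, 2],
                      pts[:, 1] - pts[:, 0]], axis=1)   # (m,3,2)
        grads = np.stack([-e[..., 1], e[..., 0]], axis=-1) / (2 * A)[:, None, None]
        # local stiffness K_ij = A * grad_i . grad_j
        K = np.einsum("tid,tjd,t->tij", grads, grads, A)
        rows_parts[flag] = np.repeat(tri, 3, axis=1).ravel()
        cols_parts[flag] = np.tile(tri, (1, 3)).ravel()
        vals_parts[flag] = K.ravel()
        np.add.at(c_parts[flag], tri.ravel(), np.repeat(A / 3.0, 3))

    g_parts = {}
    for flag in (False, True):
        if len(vals_parts[flag]):
            g_parts[flag] = sp.csr_matrix(
                (vals_parts[flag], (rows_parts[flag], cols_parts[flag])),
                shape=(n, n))
        else:
            g_parts[flag] = sp.csr_matrix((n, n))
    c = c_parts[False] + c_parts[True]
    G = (g_parts[False] + g_parts[True]).tocsr()
    return FEMOperators(c=c, G=G, c_parts=c_parts, g_parts=g_parts)


@dataclass
class Projector:
    """Barycentric projector from mesh nodes to arbitrary planar points."""

    A: sp.csr_matrix
    valid: np.ndarray              # False for points outside the mesh

    def project(self, node_values: np.ndarray) -> np.ndarray:
        """Field values at the projector's points (NaN outside the mesh)."""
        out = self.A @ np.asarray(node_values, dtype=float).T
        out = out.T if out.ndim > 1 else out
        out[..., ~self.valid] = np.nan if np.issubdtype(out.dtype, np.floating) else 0
        return out


def make_projector(mesh: BarrierMesh, points: np.ndarray) -> Projector:
    """Rows of barycentric weights mapping node values to point values."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = Delaunay(mesh.nodes)  # same points; reuse for location queries
    # NOTE: Delaunay of the same node set may triangulate ties differently,
    # but barycentric interpolation of P1 fields only needs *a* containing
    # triangle of the same vertex set, which this provides.
    simplex = tri.find_simplex(points)
    valid = simplex >= 0
    rows, cols, vals = [], [], []
    for i in np.flatnonzero(valid):
        s = simplex[i]
        verts = tri.simplices[s]
        T = tri.transform[s]
        b = T[:2] @ (points[i] - T[2])
        w = np.append(b, 1.0 - b.sum())
        rows.extend([i] * 3)
        cols.extend(verts.tolist())
        vals.extend(w.tolist())
    A = sp.csr_matrix((vals, (rows, cols)), shape=(len(points), mesh.n_nodes))
    return Projector(A=A, valid=valid)
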