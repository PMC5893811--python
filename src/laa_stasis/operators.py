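"""Discrete operators on triangular meshes.

Two discretizations coexist and share one mesh:

* vertex-based P1 finite elements for momentum and pressure (stiffness,
  lumped mass, gradient matrices, cell-wise velocity gradients), and
* cell-centred finite volumes for the passive contrast scalar (edge
  connectivity, edge normal fluxes integrated exactly for P1 velocity).

Everything here depends only on the mesh, is assembled once per mesh and
cached by the solver workspace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from matplotlib.tri import Triangulation

from .meshing import Mesh


@dataclass
class P1Operators:
    """P1 FEM matrices and per-cell shape-function gradients."""

    stiffness: sp.csr_matrix  # K_ij = ∫ ∇φ_i · ∇φ_j
    lumped_mass: np.ndarray  # M_i = ∫ φ_i  (row-sum mass lumping)
    grad_x: sp.csr_matrix  # (Gx)_ij = ∫ φ_i ∂φ_j/∂x
    grad_y: sp.csr_matrix
    cell_bx: np.ndarray  # (M, 3) ∂φ/∂x of the three local bases per cell
    cell_by: np.ndarray
    areas: np.ndarray


def assemble_p1(mesh: Mesh) -> P1Operators:
    pts = mesh.vertices
    cells = mesh.cells
    p = pts[cells]
    x, y = p[..., 0], p[..., 1]
    # gradients of the three P1 basis functions on each triangle
    bx = np.stack(
        [y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1
    )
    by = np.stack(
        [x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1
    )
    area2 = x[:, 0] * bx[:, 0] + x[:, 1] * bx[:, 1] + x[:, 2] * bx[:, 2]
    areas = 0.5 * area2
    bx /= area2[:, None]
    by /= area2[:, None]

    n = len(pts)
    rows = np.repeat(cells, 3, axis=1).ravel()  # i index
    cols = np.tile(cells, (1, 3)).ravel()  # j index

    def _asm(vals):
        m = sp.coo_matrix((vals.ravel(), (rows, cols)), shape=(n, n))
        return m.tocsr()

    kij = (
        np.einsum("ei,ej->eij", bx, bx) + np.einsum("ei,ej->eij", by, by)
    ) * areas[:, None, None]
    stiffness = _asm(kij)

    third = areas / 3.0
    gx = np.broadcast_to(bx[:, None, :], (len(cells), 3, 3)) * third[:, None, None]
    gy = np.broadcast_to(by[:, None, :], (len(cells), 3, 3)) * third[:, None, None]
    grad_x = _asm(np.ascontiguousarray(gx))
    grad_y = _asm(np.ascontiguousarray(gy))

    lumped = np.bincount(cells.ravel(), weights=np.repeat(third, 3), minlength=n)
    return P1Operators(stiffness, lumped, grad_x, grad_y, bx, by, areas)


def cell_gradient(ops: P1Operators, mesh: Mesh, nodal: np.ndarray) -> np.ndarray:
    """(M, 2) constant gradient of a nodal scalar field on each cell."""
    v = nodal[mesh.cells]
    return np.stack(
        [(ops.cell_bx * v).sum(axis=1), (ops.cell_by * v).sum(axis=1)], axis=1
    )


def nodal_average(mesh: Mesh, cell_field: np.ndarray) -> np.ndarray:
    """Area-weighted average of a cell field onto vertices."""
    w = np.repeat(mesh.cell_areas / 3.0, 3)
    num = np.bincount(mesh.cells.ravel(), weights=w * np.repeat(cell_field, 3),
                      minlength=mesh.n_vertices)
    den = np.bincount(mesh.cells.ravel(), weights=w, minlength=mesh.n_vertices)
    return num / den


@dataclass
class FVEdges:
    """Edge connectivity for the cell-centred finite-volume scalar.

    Interior edges store (left, right) cells with the unit normal pointing
    left -> right; boundary edges store the owning cell, the outward normal
    and the index of the originating boundary facet so boundary-condition
    types can be looked up per facet label.
    """

    int_nodes: np.ndarray  # (Ei, 2) vertex pair
    int_cells: np.ndarray  # (Ei, 2) left, right cell
    int_normal: np.ndarray  # (Ei, 2) unit, left->right
    int_length: np.ndarray
    int_trans: np.ndarray  # TPFA transmissibility len/dist(centroids)
    bnd_nodes: np.ndarray  # (Eb, 2)
    bnd_cells: np.ndarray  # (Eb,)
    bnd_normal: np.ndarray  # outward unit
    bnd_length: np.ndarray
    bnd_trans: np.ndarray  # len/dist(centroid, edge midpoint)
    bnd_facet: np.ndarray  # index into mesh.boundary_edges


def build_fv_edges(mesh: Mesh) -> FVEdges:
    cells = mesh.cells
    m = len(cells)
    e = np.vstack([cells[:, [0, 1]], cells[:, [1, 2]], cells[:, [2, 0]]])
    owner = np.tile(np.arange(m), 3)
    lo = np.minimum(e[:, 0], e[:, 1])
    hi = np.maximum(e[:, 0], e[:, 1])
    key = lo.astype(np.int64) * mesh.n_vertices + hi
    order = np.argsort(key, kind="stable")
    key_s, e_s, owner_s = key[order], e[order], owner[order]
    uniq, start, counts = np.unique(key_s, return_index=True, return_counts=True)

    centroids = mesh.cell_centroids
    pts = mesh.vertices

    int_mask = counts == 2
    i0 = start[int_mask]
    left = owner_s[i0]
    right = owner_s[i0 + 1]
    nodes_i = e_s[i0]  # directed as stored by the left owner (interior on its left)
    d = pts[nodes_i[:, 1]] - pts[nodes_i[:, 0]]
    length_i = np.hypot(d[:, 0], d[:, 1])
    normal_i = np.column_stack([d[:, 1], -d[:, 0]]) / length_i[:, None]
    dist = np.linalg.norm(centroids[right] - centroids[left], axis=1)
    trans_i = length_i / np.maximum(dist, 1e-3 * length_i)

    b0 = start[~int_mask]
    nodes_b = e_s[b0]
    cells_b = owner_s[b0]
    db = pts[nodes_b[:, 1]] - pts[nodes_b[:, 0]]
    length_b = np.hypot(db[:, 0], db[:, 1])
    normal_b = np.column_stack([db[:, 1], -db[:, 0]]) / length_b[:, None]
    mid_b = 0.5 * (pts[nodes_b[:, 0]] + pts[nodes_b[:, 1]])
    dist_b = np.linalg.norm(mid_b - centroids[cells_b], axis=1)
    trans_b = length_b / np.maximum(dist_b, 1e-3 * length_b)

    # match each boundary FV edge to its mesh boundary facet
    bkey = (
        np.minimum(mesh.boundary_edges[:, 0], mesh.boundary_edges[:, 1]).astype(np.int64)
        * mesh.n_vertices
        + np.maximum(mesh.boundary_edges[:, 0], mesh.boundary_edges[:, 1])
    )
    lookup = {k: i for i, k in enumerate(bkey.tolist())}
    this_key = (
        np.minimum(nodes_b[:, 0], nodes_b[:, 1]).astype(np.int64) * mesh.n_vertices
        + np.maximum(nodes_b[:, 0], nodes_b[:, 1])
    )
    facet = np.array([lookup[k] for k in this_key.tolist()])

    return FVEdges(
        int_nodes=nodes_i,
        int_cells=np.column_stack([left, right]),
        int_normal=normal_i,
        int_length=length_i,
        int_trans=trans_i,
        bnd_nodes=nodes_b,
        bnd_cells=cells_b,
        bnd_normal=normal_b,
        bnd_length=length_b,
        bnd_trans=trans_b,
        bnd_facet=facet,
    )


def edge_fluxes(fv: FVEdges, u: np.ndarray, v: np.ndarray):
    """Normal volume fluxes through interior and boundary edges.

    Exact integrals of the P1 velocity along each straight edge
    (trapezoid = exact for a linear field).
    """
    ua = 0.5 * (u[fv.int_nodes[:, 0]] + u[fv.int_nodes[:, 1]])
    va = 0.5 * (v[fv.int_nodes[:, 0]] + v[fv.int_nodes[:, 1]])
    f_int = fv.int_length * (ua * fv.int_normal[:, 0] + va * fv.int_normal[:, 1])
    ub = 0.5 * (u[fv.bnd_nodes[:, 0]] + u[fv.bnd_nodes[:, 1]])
    vb = 0.5 * (v[fv.bnd_nodes[:, 0]] + v[fv.bnd_nodes[:, 1]])
    f_bnd = fv.bnd_length * (ub * fv.bnd_normal[:, 0] + vb * fv.bnd_normal[:, 1])
    return f_int, f_bnd


class MeshInterpolator:
    """Barycentric P1 interpolation with fast point location.

    Falls back to the nearest vertex for points outside the mesh (used by
    the semi-Lagrangian step when a departure point exits the domain
    through a no-slip wall).
    """

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        self.tri = Triangulation(mesh.vertices[:, 0], mesh.vertices[:, 1], mesh.cells)
        self.finder = self.tri.get_trifinder()
        from scipy.spatial import cKDTree

        self.kdtree = cKDTree(mesh.vertices)
        # affine maps for barycentric coordinates
        p = mesh.vertices[mesh.cells]
        self._p0 = p[:, 0]
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
        self._inv = np.empty((len(mesh.cells), 2, 2))
        self._inv[:, 0, 0] = d2[:, 1] / det
        self._inv[:, 0, 1] = -d2[:, 0] / det
        self._inv[:, 1, 0] = -d1[:, 1] / det
        self._inv[:, 1, 1] = d1[:, 0] / det

    def locate(self, x: np.ndarray, y: np.ndarray):
        """(cell index or -1, barycentric weights (n,3)) for each point."""
        tri_idx = np.asarray(self.finder(x, y))
        inside = tri_idx >= 0
        w = np.zeros((len(x), 3))
        if inside.any():
            ti = tri_idx[inside]
            d = np.column_stack([x[inside], y[inside]]) - self._p0[ti]
            lam = np.einsum("nij,nj->ni", self._inv[ti], d)
            w[inside, 1] = lam[:, 0]
            w[inside, 2] = lam[:, 1]
            w[inside, 0] = 1.0 - lam.sum(axis=1)
        return tri_idx, w

    def sample(self, fields: list[np.ndarray], x: np.ndarray, y: np.ndarray,
               return_bounds: bool = False):
        """Interpolate nodal fields at points; nearest vertex outside.

        With ``return_bounds`` also return per-point (min, max) over the
        interpolation stencil of each field, used as monotonicity clamps
        by the error-compensated advection step.
        """
        tri_idx, w = self.locate(x, y)
        inside = tri_idx >= 0
        out = []
        bounds = []
        nearest = None
        if not inside.all():
            _, nearest = self.kdtree.query(np.column_stack([x[~inside], y[~inside]]))
        conn = self.mesh.cells[tri_idx[inside]]
        for f in fields:
            vals = np.empty(len(x))
            stencil = f[conn]
            vals[inside] = (stencil * w[inside]).sum(axis=1)
            if nearest is not None:
                vals[~inside] = f[nearest]
            out.append(vals)
            if return_bounds:
                lo = np.empty(len(x))
                hi = np.empty(len(x))
                lo[inside] = stencil.min(axis=1)
                hi[inside] = stencil.max(axis=1)
                if nearest is not None:
                    lo[~inside] = f[nearest]
                    hi[~inside] = f[nearest]
                bounds.append((lo, hi))
        if return_bounds:
            return out, bounds
        return out
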