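"""Rule-based leaflet fiber architectures from harmonic scalar fields.

Two collagen fiber architectures are built by solving a surface Laplace
problem for a scalar field ``u`` and taking the normalized surface gradient
``f = grad(u) / |grad(u)|``:

* **FD1** (body-fitted): ``u`` harmonic with point Dirichlet values
  ``u(n1) = 1`` and ``u(n2) = 0`` at the two commissure corners, natural
  (zero-flux) conditions elsewhere.
* **FD2** (circumferential): ``u`` harmonic with ``u = 0`` on the attachment
  half ``tau1`` and ``u = 1`` on ``tau2``.

The discretization uses the cotangent-weight finite-element Laplacian on the
triangulated mid-surface; the gradient of the piecewise-linear field is
constant per triangle, so the fiber field lives per triangle.
"""

from __future__ import annotations

import warnings
from typing import Dict

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .meshes import LeafletMesh

__all__ = [
    "assemble_laplacian",
    "solve_harmonic",
    "solve_fd1",
    "solve_fd2",
    "fiber_directions",
]

_DEGENERATE_AREA = 1e-14


def assemble_laplacian(mesh: LeafletMesh) -> sp.csr_matrix:
    """Cotangent-weight surface Laplacian (positive semi-definite, symmetric,
    zero row sums).  Raises on zero-area triangles, naming the triangle."""
    V, T = mesh.vertices, mesh.triangles
    areas = mesh.triangle_areas()
    bad = np.nonzero(areas < _DEGENERATE_AREA)[0]
    if bad.size:
        raise ValueError(f"degenerate (zero-area) triangle at index {bad[0]}")
    rows, cols, vals = [], [], []
    for k in range(3):
        i = T[:, k]
        j = T[:, (k + 1) % 3]
        o = T[:, (k + 2) % 3]
        # cotangent of the angle at the vertex opposite edge (i, j)
        e1 = V[i] - V[o]
        e2 = V[j] - V[o]
        cross = np.linalg.norm(np.cross(e1, e2), axis=1)
        cot = np.einsum("ij,ij->i", e1, e2) / cross
        w = 0.5 * cot
        rows += [i, j, i, j]
        cols += [j, i, i, j]
        vals += [-w, -w, w, w]
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    n = mesh.n_vertices
    L = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return L


def solve_harmonic(mesh: LeafletMesh, dirichlet: Dict[int, float]) -> np.ndarray:
    """Solve L u = 0 with prescribed vertex values; residual checked < 1e-10."""
    if not dirichlet:
        raise ValueError("at least one Dirichlet constraint is required")
    L = assemble_laplacian(mesh)
    n = mesh.n_vertices
    fixed = np.array(sorted(dirichlet), dtype=int)
    if fixed.min() < 0 or fixed.max() >= n:
        raise ValueError("Dirichlet vertex index out of range")
    vals = np.array([dirichlet[i] for i in fixed], dtype=float)
    free = np.setdiff1d(np.arange(n), fixed)
    u = np.zeros(n)
    u[fixed] = vals
    if free.size:
        A = L[np.ix_(free, free)].tocsc()
        b = -L[np.ix_(free, fixed)] @ vals
        u[free] = spla.spsolve(A, b)
        res = np.abs(A @ u[free] - b).max()
        scale = max(1.0, np.abs(b).max())
        if res > 1e-10 * scale:
            raise RuntimeError(f"harmonic solve residual {res:.3e} too large")
    return u


def solve_fd1(mesh: LeafletMesh) -> np.ndarray:
    """Body-fitted architecture field: u(n1) = 1, u(n2) = 0, harmonic inside."""
    if mesh.n1 is None or mesh.n2 is None:
        raise ValueError("FD1 requires labeled corner vertices n1 and n2")
    if mesh.n1 == mesh.n2:
        raise ValueError("n1 and n2 must be distinct vertices")
    return solve_harmonic(mesh, {int(mesh.n1): 1.0, int(mesh.n2): 0.0})


def solve_fd2(mesh: LeafletMesh) -> np.ndarray:
    """Circumferential architecture field: u = 0 on tau1, u = 1 on tau2."""
    if mesh.tau1.size == 0 or mesh.tau2.size == 0:
        raise ValueError("FD2 requires non-empty attachment label sets tau1, tau2")
    if np.intersect1d(mesh.tau1, mesh.tau2).size:
        raise ValueError("tau1 and tau2 overlap")
    d = {int(i): 0.0 for i in mesh.tau1}
    d.update({int(i): 1.0 for i in mesh.tau2})
    return solve_harmonic(mesh, d)


def _triangle_gradients(mesh: LeafletMesh, u: np.ndarray) -> np.ndarray:
    """Per-triangle gradient of the piecewise-linear interpolant of u."""
    V, T = mesh.vertices, mesh.triangles
    p0, p1, p2 = V[T[:, 0]], V[T[:, 1]], V[T[:, 2]]
    n = np.cross(p1 - p0, p2 - p0)
    nn = np.linalg.norm(n, axis=1, keepdims=True)
    nhat = n / nn
    # grad u = (1 / 2A) n x (u0 (p2 - p1) + u1 (p0 - p2) + u2 (p1 - p0))
    s = (
        u[T[:, 0], None] * (p2 - p1)
        + u[T[:, 1], None] * (p0 - p2)
        + u[T[:, 2], None] * (p1 - p0)
    )
    return np.cross(nhat, s) / nn


def fiber_directions(mesh: LeafletMesh, u: np.ndarray) -> np.ndarray:
    """Unit fiber vectors f = grad(u)/|grad(u)| per triangle.

    Triangles whose gradient magnitude is below ``1e-12 * range(u) / diameter``
    (e.g. near an interior saddle of the FD1 field) inherit the area-weighted
    mean direction of their edge neighbors; if no neighbor has a valid
    direction the triangle keeps a zero vector and a warning is emitted.
    """
    g = _triangle_gradients(mesh, u)
    mag = np.linalg.norm(g, axis=1)
    diam = np.linalg.norm(mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0))
    urange = float(u.max() - u.min())
    tol = 1e-12 * urange / diam if diam > 0 else 1e-12
    good = mag > tol
    f = np.zeros_like(g)
    f[good] = g[good] / mag[good, None]
    if not np.all(good):
        areas = mesh.triangle_areas()
        neighbors = _edge_neighbors(mesh.triangles)
        for t in np.nonzero(~good)[0]:
            nb = [k for k in neighbors[t] if good[k]]
            if nb:
                avg = np.sum(f[nb] * areas[nb, None], axis=0)
                nrm = np.linalg.norm(avg)
                if nrm > 0:
                    f[t] = avg / nrm
                    continue
            warnings.warn(
                f"triangle {t}: degenerate gradient and no valid neighbor; "
                "fiber direction left as zero vector"
            )
    return f


def _edge_neighbors(T: np.ndarray):
    """Map triangle index -> list of triangles sharing an edge."""
    from collections import defaultdict

    edge_map = defaultdict(list)
    for t, tri in enumerate(T):
        for a, b in ((0, 1), (1, 2), (2, 0)):
            e = (min(tri[a], tri[b]), max(tri[a], tri[b]))
            edge_map[e].append(t)
    nb = defaultdict(set)
    for ts in edge_map.values():
        for a in ts:
            for b in ts:
                if a != b:
                    nb[a].add(b)
    return {t: sorted(s) for t, s in nb.items()} | {
        t: [] for t in range(len(T)) if t not in nb
    }
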