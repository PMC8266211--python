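"""Shared fixtures: analytic mesh builders and step-waveform construction."""

import numpy as np
import pytest

from valvemech.meshes import LeafletMesh
from valvemech.hemodynamics import Events, Waveform


def build_square_mesh(n: int, lx: float = 1.0, ly: float = 1.0) -> LeafletMesh:
    """Structured right-triangle mesh of [0,lx]x[0,ly] in the z=0 plane.

    tau1/tau2 are the x=0 and x=lx edges; corner labels n1=(0,0), n2=(lx,0).
    """
    xs = np.linspace(0.0, lx, n + 1)
    ys = np.linspace(0.0, ly, n + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    V = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
    idx = lambda i, j: i * (n + 1) + j
    tris = []
    for i in range(n):
        for j in range(n):
            a, b = idx(i, j), idx(i + 1, j)
            c, d = idx(i + 1, j + 1), idx(i, j + 1)
            tris += [(a, b, c), (a, c, d)]
    tau1 = [idx(0, j) for j in range(n + 1)]
    tau2 = [idx(n, j) for j in range(n + 1)]
    return LeafletMesh(
        V, np.array(tris), n1=idx(0, 0), n2=idx(n, 0),
        tau1=np.array(tau1), tau2=np.array(tau2),
    )


def build_annulus_sector(n: int, r0: float = 1.0, r1: float = 2.0,
                         dtheta: float = np.pi / 3) -> LeafletMesh:
    """Flat annular sector, Dirichlet labels on the two radial edges."""
    rs = np.linspace(r0, r1, n + 1)
    ths = np.linspace(0.0, dtheta, n + 1)
    R, T = np.meshgrid(rs, ths, indexing="ij")
    V = np.column_stack([(R * np.cos(T)).ravel(), (R * np.sin(T)).ravel(),
                         np.zeros(R.size)])
    idx = lambda i, j: i * (n + 1) + j
    tris = []
    for i in range(n):
        for j in range(n):
            a, b = idx(i, j), idx(i + 1, j)
            c, d = idx(i + 1, j + 1), idx(i, j + 1)
            tris += [(a, b, c), (a, c, d)]
    tau1 = [idx(i, 0) for i in range(n + 1)]
    tau2 = [idx(i, n) for i in range(n + 1)]
    return LeafletMesh(V, np.array(tris), tau1=np.array(tau1), tau2=np.array(tau2))


def build_cylinder_patch(n: int, radius: float = 1.3, height: float = 1.0,
                         sector: float = 2 * np.pi / 3) -> LeafletMesh:
    """Rectangular patch of a cylinder surface; tau1/tau2 on the two
    straight (axial) edges so the harmonic field is linear in angle."""
    ths = np.linspace(-sector / 2, sector / 2, n + 1)
    zs = np.linspace(0.0, height, n + 1)
    T, Z = np.meshgrid(ths, zs, indexing="ij")
    V = np.column_stack([
        (radius * np.cos(T)).ravel(), (radius * np.sin(T)).ravel(), Z.ravel()
    ])
    idx = lambda i, j: i * (n + 1) + j
    tris = []
    for i in range(n):
        for j in range(n):
            a, b = idx(i, j), idx(i + 1, j)
            c, d = idx(i + 1, j + 1), idx(i, j + 1)
            tris += [(a, b, c), (a, c, d)]
    tau1 = [idx(0, j) for j in range(n + 1)]
    tau2 = [idx(n, j) for j in range(n + 1)]
    return LeafletMesh(V, np.array(tris), tau1=np.array(tau1), tau2=np.array(tau2))


def step_waveform(phases, dt=1e-3, eps=1e-9, pressures=None):
    """Piecewise-constant flow waveform with near-instant (eps) jumps.

    ``phases`` is a list of (duration_s, Q_mL_per_s); event times fall on the
    phase boundaries so trapezoidal window integrals are exact to O(eps).
    Returns (t, Q, boundaries).
    """
    t_parts, q_parts = [], []
    t0 = 0.0
    bounds = [0.0]
    for k, (dur, q) in enumerate(phases):
        a = t0 if k == 0 else t0 + eps
        b = t0 + dur
        tt = np.arange(a, b - dt / 2, dt)
        tt = np.append(tt, b)
        t_parts.append(tt)
        q_parts.append(np.full(tt.size, q))
        t0 = b
        bounds.append(b)
    t = np.concatenate(t_parts)
    Q = np.concatenate(q_parts)
    return t, Q, bounds


@pytest.fixture
def square_mesh():
    return build_square_mesh


@pytest.fixture
def annulus_sector():
    return build_annulus_sector


@pytest.fixture
def cylinder_patch():
    return build_cylinder_patch
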