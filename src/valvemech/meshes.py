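"""Triangulated leaflet surface meshes with labeled boundary features.

A :class:`LeafletMesh` is an oriented triangle surface (coordinates in cm)
carrying the boundary labels needed by the rule-based fiber constructions:
the two commissure corner vertices ``n1``/``n2``, the two attachment-edge
halves ``tau1``/``tau2`` (where the leaflet joins the aortic wall), and the
free-edge vertex set.  Mesh geometry I/O goes through :mod:`trimesh`
(OFF/PLY/STL...); labels live in a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["LeafletMesh", "boundary_vertices", "write_vtk", "fibers_to_csv"]


@dataclass
class LeafletMesh:
    vertices: np.ndarray  # (nv, 3) cm
    triangles: np.ndarray  # (nt, 3) int
    n1: Optional[int] = None
    n2: Optional[int] = None
    tau1: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    tau2: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    free_edge: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (m, 3)")
        if self.triangles.size and self.triangles.max() >= len(self.vertices):
            raise ValueError("triangle index out of range")
        for name in ("tau1", "tau2", "free_edge"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=int))
        if len(np.intersect1d(self.tau1, self.tau2)):
            raise ValueError("tau1 and tau2 must be disjoint")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_areas(self) -> np.ndarray:
        p = self.vertices[self.triangles]
        return 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )

    def triangle_normals(self) -> np.ndarray:
        p = self.vertices[self.triangles]
        n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    # -- I/O ------------------------------------------------------------
    def save(self, mesh_path, labels_path=None) -> None:
        import trimesh

        trimesh.Trimesh(self.vertices, self.triangles, process=False).export(mesh_path)
        if labels_path is not None:
            with open(labels_path, "w") as fh:
                json.dump(
                    {
                        "n1": None if self.n1 is None else int(self.n1),
                        "n2": None if self.n2 is None else int(self.n2),
                        "tau1": self.tau1.tolist(),
                        "tau2": self.tau2.tolist(),
                        "free_edge": self.free_edge.tolist(),
                    },
                    fh,
                )

    @classmethod
    def load(cls, mesh_path, labels_path=None) -> "LeafletMesh":
        import trimesh

        tm = trimesh.load_mesh(mesh_path, process=False)
        labels = {}
        if labels_path is not None:
            with open(labels_path) as fh:
                labels = json.load(fh)
        return cls(
            vertices=np.asarray(tm.vertices),
            triangles=np.asarray(tm.faces),
            n1=labels.get("n1"),
            n2=labels.get("n2"),
            tau1=np.asarray(labels.get("tau1", []), dtype=int),
            tau2=np.asarray(labels.get("tau2", []), dtype=int),
            free_edge=np.asarray(labels.get("free_edge", []), dtype=int),
        )


def boundary_vertices(mesh: LeafletMesh) -> np.ndarray:
    """Indices of vertices on edges used by exactly one triangle."""
    tri = mesh.triangles
    edges = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    return np.unique(uniq[counts == 1])


def write_vtk(path, mesh: LeafletMesh, cell_vectors: Optional[np.ndarray] = None,
              point_scalars: Optional[np.ndarray] = None, name: str = "fiber") -> None:
    """Minimal legacy-VTK ASCII writer with optional per-triangle vector data."""
    nv, nt = mesh.n_vertices, mesh.n_triangles
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nleaflet surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {nv} double\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.10g} {v[1]:.10g} {v[2]:.10g}\n")
        fh.write(f"POLYGONS {nt} {4 * nt}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        if point_scalars is not None:
            fh.write(f"POINT_DATA {nv}\nSCALARS u double 1\nLOOKUP_TABLE default\n")
            for x in point_scalars:
                fh.write(f"{x:.10g}\n")
        if cell_vectors is not None:
            fh.write(f"CELL_DATA {nt}\nVECTORS {name} double\n")
            for f in cell_vectors:
                fh.write(f"{f[0]:.10g} {f[1]:.10g} {f[2]:.10g}\n")


def fibers_to_csv(path, fibers: np.ndarray) -> None:
    """Per-triangle fiber vectors as CSV triangle_id,fx,fy,fz."""
    idx = np.arange(len(fibers))
    arr = np.column_stack([idx, fibers])
    np.savetxt(path, arr, delimiter=",", comments="",
               header="triangle_id,fx,fy,fz", fmt=["%d", "%.10g", "%.10g", "%.10g"])
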